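"""Exception types shared across the package."""


class PausetrackError(Exception):
    """Base class for all package errors."""


class ParseError(PausetrackError, ValueError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(PausetrackError, ValueError):
    """Well-formed input that violates a documented invariant."""


class MissingDataError(PausetrackError, ValueError):
    """A locus or sample lacks the data required for the requested call."""
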