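"""Three-state transcriptional classification and transition accounting.

A locus is ACTIVE when it shows both transcriptional initiation (promoter
H3K4me3) and elongation (full-length transcript), PAUSED when it shows
initiation only, and SILENT when it shows neither. The fourth cell of the
truth table — transcript without H3K4me3 — falls outside the three-state
scheme; such loci are labelled DISCORDANT, tracked, and excluded from
transition tallies by default (optionally coerced to ACTIVE).

Between two cell populations the three states admit nine ordered transitions,
grouped into six classes: *stable* (A→A, P→P, S→S), *activation* (P→A, S→A),
*silencing* (A→P, A→S), *priming* (S→P) and *archiving* (P→S), with S→A and
A→S additionally flagged *direct* (no paused intermediate).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError

ACTIVE = "ACTIVE"
PAUSED = "PAUSED"
SILENT = "SILENT"
DISCORDANT = "DISCORDANT"

STATES = (ACTIVE, PAUSED, SILENT)

#: the nine ordered (from_state, to_state) pairs, row-major A, P, S
TRANSITIONS = tuple((a, b) for a in STATES for b in STATES)

CATEGORIES = ("stable", "activation", "silencing", "priming", "archiving")

_CATEGORY_OF = {
    (ACTIVE, ACTIVE): "stable",
    (PAUSED, PAUSED): "stable",
    (SILENT, SILENT): "stable",
    (PAUSED, ACTIVE): "activation",
    (SILENT, ACTIVE): "activation",
    (ACTIVE, PAUSED): "silencing",
    (ACTIVE, SILENT): "silencing",
    (SILENT, PAUSED): "priming",
    (PAUSED, SILENT): "archiving",
}

_DIRECT = {(SILENT, ACTIVE), (ACTIVE, SILENT)}


def assign_state(initiating: bool, elongating: bool) -> str:
    """Map the (initiation, elongation) call pair to a transcriptional state."""
    if initiating:
        return ACTIVE if elongating else PAUSED
    return DISCORDANT if elongating else SILENT


def combine_calls(
    binding: pd.DataFrame, transcripts: pd.DataFrame, condition: str
) -> pd.DataFrame:
    """Join one condition's binding and transcript calls into state calls.

    The analyzed locus set is the intersection of loci with a binding call
    (>=1 ChIP probe) and a transcript call (on the expression platform).
    Returns columns ``gene_id``, ``condition``, ``initiating``,
    ``elongating``, ``state``.
    """
    merged = binding[["gene_id", "bound"]].merge(
        transcripts.loc[transcripts["condition"] == condition,
                        ["gene_id", "expressed"]],
        on="gene_id", how="inner",
    )
    merged = merged.rename(columns={"bound": "initiating",
                                    "expressed": "elongating"})
    merged["condition"] = condition
    merged["state"] = [
        assign_state(i, e)
        for i, e in zip(merged["initiating"], merged["elongating"])
    ]
    return merged[["gene_id", "condition", "initiating", "elongating", "state"]]


def classify_transition(from_state: str, to_state: str):
    """Classify one ordered state pair.

    Returns ``(transition, category, direct)`` where *transition* is the
    ``"FROM->TO"`` label, or ``None`` when either state is DISCORDANT (the
    exclusion signal — such loci are reported separately, never tallied).
    """
    key = (from_state, to_state)
    if key not in _CATEGORY_OF:
        if DISCORDANT in key:
            return None
        raise ValidationError(f"unknown state pair {key}")
    return (f"{from_state}->{to_state}", _CATEGORY_OF[key], key in _DIRECT)


def transition_records(
    calls_before: pd.DataFrame,
    calls_after: pd.DataFrame,
    coerce_discordant: str = "exclude",
) -> pd.DataFrame:
    """Per-locus transition records between two conditions.

    Both inputs are state-call tables over the identical gene set. DISCORDANT
    loci are dropped (``coerce_discordant='exclude'``, the default) or
    reclassified as ACTIVE (``'active'``); the number excluded is stored in
    ``result.attrs['n_discordant']``.
    """
    if coerce_discordant not in ("exclude", "active"):
        raise ValidationError(f"coerce_discordant must be exclude/active")
    before = calls_before.set_index("gene_id")["state"]
    after = calls_after.set_index("gene_id")["state"]
    if set(before.index) != set(after.index):
        raise ValidationError("conditions cover different gene sets")
    after = after.reindex(before.index)
    if coerce_discordant == "active":
        before = before.replace(DISCORDANT, ACTIVE)
        after = after.replace(DISCORDANT, ACTIVE)
    rows, n_discordant = [], 0
    for gene_id, fr, to in zip(before.index, before, after):
        classified = classify_transition(fr, to)
        if classified is None:
            n_discordant += 1
            continue
        transition, category, direct = classified
        rows.append((gene_id, fr, to, transition, category, direct))
    records = pd.DataFrame(
        rows,
        columns=["gene_id", "from_state", "to_state",
                 "transition", "category", "direct"],
    )
    records.attrs["n_discordant"] = n_discordant
    return records


@dataclass
class TransitionTally:
    """All summary counts and percentages over one pair of conditions.

    Percentages are rounded to one decimal (round-half-to-even). Category
    shares, ``paused_intermediate_percent`` and ``direct_percent`` are
    fractions of *changing* loci and are ``None`` when nothing changes.
    """

    n_loci: int
    n_discordant: int
    transition_counts: dict = field(default_factory=dict)   # (from, to) -> n
    n_changing: int = 0
    changing_percent: float = 0.0                           # of n_loci
    category_counts: dict = field(default_factory=dict)     # 4 changing classes
    category_percents: dict | None = None                   # of n_changing
    direct_count: int = 0
    direct_percent: float | None = None
    paused_intermediate_percent: float | None = None
    state_percents_before: dict = field(default_factory=dict)
    state_percents_after: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        """JSON-serializable summary mirroring the counts and shares."""
        return {
            "n_loci": self.n_loci,
            "n_discordant": self.n_discordant,
            "transitions": {
                f"{a}->{b}": self.transition_counts[(a, b)] for a, b in TRANSITIONS
            },
            "n_changing": self.n_changing,
            "changing_percent": self.changing_percent,
            "category_counts": dict(self.category_counts),
            "category_percents": (
                dict(self.category_percents) if self.category_percents else None
            ),
            "direct_count": self.direct_count,
            "direct_percent": self.direct_percent,
            "paused_intermediate_percent": self.paused_intermediate_percent,
            "state_percents_before": dict(self.state_percents_before),
            "state_percents_after": dict(self.state_percents_after),
        }


def _round1(x: float) -> float:
    return round(float(x), 1)


def state_distribution(calls: pd.DataFrame) -> dict:
    """Fractions of ACTIVE/PAUSED/SILENT among a condition's non-discordant loci."""
    states = calls["state"]
    states = states[states != DISCORDANT]
    if len(states) == 0:
        raise ValidationError("no non-discordant loci")
    counts = states.value_counts()
    return {s: float(counts.get(s, 0)) / len(states) for s in STATES}


def tally_records(
    records: pd.DataFrame,
    calls_before: pd.DataFrame | None = None,
    calls_after: pd.DataFrame | None = None,
) -> TransitionTally:
    """Tally a transition-record table into a :class:`TransitionTally`."""
    n_loci = len(records)
    pairs = list(zip(records["from_state"], records["to_state"]))
    transition_counts = {t: 0 for t in TRANSITIONS}
    for pair in pairs:
        transition_counts[pair] += 1
    changing = records.loc[records["category"] != "stable"]
    n_changing = len(changing)
    category_counts = {
        c: int((changing["category"] == c).sum())
        for c in CATEGORIES if c != "stable"
    }
    direct_count = int(records["direct"].sum())
    tally = TransitionTally(
        n_loci=n_loci,
        n_discordant=int(records.attrs.get("n_discordant", 0)),
        transition_counts=transition_counts,
        n_changing=n_changing,
        changing_percent=_round1(100.0 * n_changing / n_loci) if n_loci else 0.0,
        category_counts=category_counts,
        direct_count=direct_count,
    )
    if n_changing > 0:
        tally.category_percents = {
            c: _round1(100.0 * n / n_changing) for c, n in category_counts.items()
        }
        tally.direct_percent = _round1(100.0 * direct_count / n_changing)
        tally.paused_intermediate_percent = _round1(
            100.0 * (n_changing - direct_count) / n_changing
        )
    for calls, attr in ((calls_before, "state_percents_before"),
                        (calls_after, "state_percents_after")):
        if calls is not None:
            dist = state_distribution(calls)
            setattr(tally, attr, {s: _round1(100.0 * f) for s, f in dist.items()})
    return tally


def tally_transitions(
    calls_before: pd.DataFrame,
    calls_after: pd.DataFrame,
    coerce_discordant: str = "exclude",
) -> TransitionTally:
    """Classify and tally all transitions between two conditions' state calls."""
    records = transition_records(calls_before, calls_after, coerce_discordant)
    return tally_records(records, calls_before, calls_after)
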