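"""Metagene profiles and the dual-threshold H3K4me3 promoter binding call.

Each protein-coding locus is summarised as a *metagene*: its promoter-array
probes arranged by signed offset from the TSS, each carrying the log2 ratio of
H3K4me3 over pan-histone-H3 signal. A locus is called H3K4me3-bound
(transcriptionally initiating) if either

* any probe's log-ratio exceeds ``global_threshold`` (default 1.5 log2), or
* any probe within ``[window_start, window_end]`` bp of the TSS (default
  -1250..+750, endpoints inclusive) exceeds ``window_threshold`` (default 0.8).

Both comparisons are strict ("over"). No smoothing or interpolation is
applied: a "point" is one probe's log-ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MissingDataError, ValidationError


@dataclass(frozen=True)
class ChipCallerConfig:
    """Thresholds and geometry of the dual-threshold binding caller.

    Parameters
    ----------
    global_threshold
        log2 enrichment any probe must exceed, anywhere in the profile.
    window_threshold
        Lower log2 enrichment sufficing within the promoter-proximal window.
    window_start, window_end
        Inclusive window bounds in bp relative to the TSS (negative =
        upstream).
    pseudocount
        Added to both channels before the ratio so zero intensities are
        well-defined.
    """

    global_threshold: float = 1.5
    window_threshold: float = 0.8
    window_start: int = -1250
    window_end: int = 750
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.window_start >= self.window_end:
            raise ValidationError("window_start must be < window_end")
        if self.global_threshold <= 0 or self.window_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        if self.pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")


@dataclass
class MetageneProfile:
    """Per-locus log2(H3K4me3/panH3) values at signed TSS offsets."""

    gene_id: str
    offsets: np.ndarray   # strictly increasing, within [-4000, +4000]
    log_ratios: np.ndarray

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets)
        self.log_ratios = np.asarray(self.log_ratios, dtype=float)
        if self.offsets.size == 0:
            raise MissingDataError(f"{self.gene_id}: empty metagene")
        if np.any(np.diff(self.offsets) <= 0):
            raise ValidationError(f"{self.gene_id}: offsets not strictly increasing")


@dataclass(frozen=True)
class BindingCall:
    """Outcome of the dual-threshold call for one locus."""

    gene_id: str
    bound: bool
    trigger: str  # 'global', 'window' or 'none'
    max_log_ratio: float
    max_window_log_ratio: float


def build_metagene(
    records: pd.DataFrame, config: ChipCallerConfig = ChipCallerConfig()
) -> MetageneProfile:
    """Build one locus's metagene from its probe-signal records.

    Replicate arrays contribute multiple rows per offset; their intensities
    are averaged probe-wise (per channel) before the log ratio is taken, so
    one metagene describes one locus in one cell population.
    """
    if len(records) == 0:
        raise MissingDataError("no probe records for locus")
    gene_ids = records["gene_id"].unique()
    if len(gene_ids) != 1:
        raise ValidationError(f"records span multiple genes: {sorted(gene_ids)}")
    by_offset = (
        records.groupby("offset", sort=True)[["h3k4me3", "panh3"]].mean()
    )
    pc = config.pseudocount
    lr = np.log2((by_offset["h3k4me3"].to_numpy() + pc)
                 / (by_offset["panh3"].to_numpy() + pc))
    return MetageneProfile(
        gene_id=str(gene_ids[0]),
        offsets=by_offset.index.to_numpy(),
        log_ratios=lr,
    )


def call_h3k4me3(
    profile: MetageneProfile, config: ChipCallerConfig = ChipCallerConfig()
) -> BindingCall:
    """Apply the dual-threshold binding call to one metagene profile."""
    lr = profile.log_ratios
    in_window = (profile.offsets >= config.window_start) & (
        profile.offsets <= config.window_end
    )
    max_lr = float(lr.max())
    max_win = float(lr[in_window].max()) if in_window.any() else float("-inf")
    if max_lr > config.global_threshold:
        trigger = "global"
    elif max_win > config.window_threshold:
        trigger = "window"
    else:
        trigger = "none"
    return BindingCall(
        gene_id=profile.gene_id,
        bound=trigger != "none",
        trigger=trigger,
        max_log_ratio=max_lr,
        max_window_log_ratio=max_win,
    )


def call_all_loci(
    records: pd.DataFrame, config: ChipCallerConfig = ChipCallerConfig()
) -> pd.DataFrame:
    """Binding calls for every locus present in a probe-signal table.

    Returns a DataFrame with columns ``gene_id``, ``bound``, ``trigger``,
    ``max_log_ratio``, ``max_window_log_ratio``. Loci with no probes simply do
    not appear (they are outside the analyzed set).
    """
    rows = []
    for _, gene_records in records.groupby("gene_id", sort=True):
        call = call_h3k4me3(build_metagene(gene_records, config), config)
        rows.append(
            (call.gene_id, call.bound, call.trigger,
             call.max_log_ratio, call.max_window_log_ratio)
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "bound", "trigger",
                 "max_log_ratio", "max_window_log_ratio"],
    )
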