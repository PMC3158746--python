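"""Detection p-values, probe filtering, quantile normalization and
gene-level full-length transcript calls for bead-array expression data.

A probe's *detection p-value* asks whether its fluorescence exceeds the
sample's negative-control background: a one-sided (signal > background)
two-sample Student's t-test with pooled variance, computed from the probe's
bead summary (mean, SD, bead count) against the sample's negative-control
intensity pool. The *detection score* is 1 - p.

Probes whose detection score falls below ``score_floor`` (default 0.99) in
*every* sample are discarded; surviving probes are quantile-normalized for
reported expression levels. A locus is called as producing full-length
transcript when the detection criterion p < ``detection_alpha`` (default
1e-3) is met under the configured probe/replicate aggregation rules
(default: any retained probe, in any replicate). Detection p-values are
computed on raw intensities, before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import ExpressionSample


@dataclass(frozen=True)
class ExprCallerConfig:
    """Constants of the transcript-detection chain.

    ``detection_alpha`` is the per-probe p-value bound for calling transcript;
    ``score_floor`` is the detection-score cutoff below which a probe is
    discarded if it fails it in every sample. ``probe_rule`` / ``replicate_rule``
    choose between requiring *any* or *all* probes / replicates to meet the
    detection criterion.
    """

    detection_alpha: float = 1e-3
    score_floor: float = 0.99
    replicate_rule: str = "any"
    probe_rule: str = "any"

    def __post_init__(self) -> None:
        if not 0 < self.detection_alpha < 1:
            raise ValidationError("detection_alpha must be in (0, 1)")
        if not 0 < self.score_floor < 1:
            raise ValidationError("score_floor must be in (0, 1)")
        for rule in (self.replicate_rule, self.probe_rule):
            if rule not in ("any", "all"):
                raise ValidationError(f"aggregation rule must be any/all, got {rule!r}")


@dataclass(frozen=True)
class TranscriptCall:
    """Gene-level full-length transcript call in one condition."""

    gene_id: str
    condition: str
    expressed: bool
    min_p: float
    flag: str = ""  # 'no_probe' when every probe was discarded


def detection_pvalue(
    mean: float, sd: float, count: int, controls: np.ndarray
) -> float:
    """One-sided pooled-variance t-test p-value of probe signal over background.

    Parameters are the probe's bead summary and the sample's negative-control
    intensity pool. Degenerate case: zero pooled variance yields p = 0.5 at
    equal means (no evidence either way), else 0 or 1 by the sign of the
    difference.
    """
    controls = np.asarray(controls, dtype=float)
    n2 = controls.size
    if n2 < 2:
        raise ValidationError("negative-control pool must have >= 2 members")
    if count < 2:
        raise ValidationError("probe bead_count must be >= 2")
    n1 = int(count)
    m2 = controls.mean()
    s2 = controls.std(ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd**2 + (n2 - 1) * s2**2) / df
    if sp2 == 0.0:
        if mean == m2:
            return 0.5
        return 0.0 if mean > m2 else 1.0
    t = (mean - m2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(stats.t.sf(t, df))


def detect_sample(sample: ExpressionSample) -> pd.DataFrame:
    """Detection results for every non-control probe of one sample.

    Returns columns ``probe_id``, ``gene_id``, ``sample_id``, ``condition``,
    ``replicate``, ``p_value``, ``detection_score``.
    """
    pool = sample.control_pool
    probes = sample.probes.loc[~sample.probes["is_control"]]
    pvals = [
        detection_pvalue(row.mean_intensity, row.bead_sd, row.bead_count, pool)
        for row in probes.itertuples()
    ]
    return pd.DataFrame(
        {
            "probe_id": probes["probe_id"].to_numpy(),
            "gene_id": probes["gene_id"].to_numpy(),
            "sample_id": sample.sample_id,
            "condition": sample.condition,
            "replicate": sample.replicate,
            "p_value": pvals,
        }
    ).assign(detection_score=lambda d: 1.0 - d["p_value"])


def score_matrix(detections: pd.DataFrame) -> pd.DataFrame:
    """Pivot long detection results to a probes x samples score matrix."""
    return detections.pivot(
        index="probe_id", columns="sample_id", values="detection_score"
    )


def filter_probes(
    scores: pd.DataFrame, config: ExprCallerConfig = ExprCallerConfig()
) -> pd.Index:
    """Retain probes that clear the detection-score floor in at least one sample.

    *scores* is a probes x samples matrix of detection scores; a probe is
    discarded iff its score is below ``score_floor`` in every sample.
    """
    if scores.shape[1] == 0:
        raise ValidationError("no samples to filter on")
    keep = (scores >= config.score_floor).any(axis=1)
    return scores.index[keep]


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common mean-of-sorted-columns distribution.

    Within-column rank order is preserved; tied values receive the mean of
    the reference quantiles they span, so the map is well-defined and
    idempotent.
    """
    if matrix.shape[1] < 1:
        raise ValidationError("need at least one sample column")
    arr = matrix.to_numpy(dtype=float)
    if np.isnan(arr).any():
        raise ValidationError("missing values are not allowed")
    ref = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        sorted_vals = np.sort(col)
        # mean reference quantile per distinct value handles ties exactly
        ref_by_value = pd.Series(ref).groupby(sorted_vals).mean()
        out[:, j] = ref_by_value.loc[col].to_numpy()
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def call_transcript(
    gene_id: str,
    condition: str,
    detections: pd.DataFrame,
    config: ExprCallerConfig = ExprCallerConfig(),
) -> TranscriptCall:
    """Aggregate one gene's retained-probe detection p-values into a call.

    *detections* holds the gene's retained probes across the condition's
    replicates (columns ``replicate`` and ``p_value``). A gene left with no
    retained probes is not expressed and flagged ``no_probe``.
    """
    if len(detections) == 0:
        return TranscriptCall(gene_id, condition, False, float("nan"), "no_probe")
    probe_agg = "any" if config.probe_rule == "any" else "all"
    per_replicate = (
        (detections["p_value"] < config.detection_alpha)
        .groupby(detections["replicate"].to_numpy())
        .agg(probe_agg)
    )
    expressed = bool(
        per_replicate.any() if config.replicate_rule == "any" else per_replicate.all()
    )
    return TranscriptCall(
        gene_id, condition, expressed, float(detections["p_value"].min())
    )


def call_transcripts(
    detections: pd.DataFrame,
    retained: pd.Index,
    config: ExprCallerConfig = ExprCallerConfig(),
) -> pd.DataFrame:
    """Gene-level transcript calls per condition from long detection results.

    Genes all of whose probes were discarded by the filter still appear, as
    not expressed with flag ``no_probe``. Returns columns ``gene_id``,
    ``condition``, ``expressed``, ``min_p``, ``flag``.
    """
    retained_set = set(retained)
    rows = []
    for (gene_id, condition), grp in detections.groupby(
        ["gene_id", "condition"], sort=True
    ):
        kept = grp.loc[grp["probe_id"].isin(retained_set)]
        call = call_transcript(gene_id, condition, kept, config)
        rows.append(
            (call.gene_id, call.condition, call.expressed, call.min_p, call.flag)
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "condition", "expressed", "min_p", "flag"]
    )
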