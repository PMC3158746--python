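"""End-to-end orchestration: platforms in, states and transitions out.

The chain is: per-condition H3K4me3 binding calls from the ChIP probe
tables; detection p-values for every expression probe against its sample's
negative controls; the all-samples detection-score filter; quantile
normalization of the retained intensity matrix (reported levels only —
calls use raw intensities); gene-level transcript calls per condition;
state assignment on the intersection of loci covered by both platforms in
both conditions; and the transition records and tally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .chip import ChipCallerConfig, call_all_loci
from .errors import ValidationError
from .expression import (
    ExprCallerConfig,
    call_transcripts,
    detect_sample,
    filter_probes,
    quantile_normalize,
    score_matrix,
)
from .io import ExpressionSample
from .states import (
    TransitionTally,
    combine_calls,
    tally_records,
    transition_records,
)


@dataclass
class PipelineResult:
    """All intermediate and final tables of one two-condition analysis."""

    conditions: tuple
    binding: dict[str, pd.DataFrame]            # per condition
    detections: pd.DataFrame = field(repr=False)
    retained_probes: pd.Index = field(repr=False)
    normalized: pd.DataFrame = field(repr=False)  # retained probes x samples
    transcripts: pd.DataFrame = field(repr=False)
    state_calls: dict[str, pd.DataFrame] = field(repr=False, default_factory=dict)
    records: pd.DataFrame = field(repr=False, default=None)
    tally: TransitionTally = None


def run_pipeline(
    chip_tables: dict[str, pd.DataFrame],
    expression_samples: list[ExpressionSample],
    chip_config: ChipCallerConfig = ChipCallerConfig(),
    expr_config: ExprCallerConfig = ExprCallerConfig(),
    coerce_discordant: str = "exclude",
) -> PipelineResult:
    """Run the full classification chain on two conditions' raw tables.

    *chip_tables* maps each of exactly two condition labels (ordered
    before, after) to its probe-signal table; *expression_samples* carry
    their own condition labels, which must match.
    """
    conditions = tuple(chip_tables)
    if len(conditions) != 2:
        raise ValidationError("exactly two conditions are required")
    expr_conditions = {s.condition for s in expression_samples}
    if expr_conditions != set(conditions):
        raise ValidationError(
            f"expression conditions {sorted(expr_conditions)} do not match "
            f"ChIP conditions {sorted(conditions)}"
        )

    binding = {
        cond: call_all_loci(table, chip_config)
        for cond, table in chip_tables.items()
    }
    detections = pd.concat(
        [detect_sample(s) for s in expression_samples], ignore_index=True
    )
    scores = score_matrix(detections)
    retained = filter_probes(scores, expr_config)

    intensities = pd.concat(
        [
            s.probes.loc[~s.probes["is_control"]]
            .set_index("probe_id")["mean_intensity"]
            .rename(s.sample_id)
            for s in expression_samples
        ],
        axis=1,
    )
    normalized = quantile_normalize(intensities.loc[retained])

    transcripts = call_transcripts(detections, retained, expr_config)

    state_calls = {
        cond: combine_calls(binding[cond], transcripts, cond)
        for cond in conditions
    }
    shared = set(state_calls[conditions[0]]["gene_id"]) & set(
        state_calls[conditions[1]]["gene_id"]
    )
    for cond in conditions:
        calls = state_calls[cond]
        state_calls[cond] = calls.loc[calls["gene_id"].isin(shared)].reset_index(
            drop=True
        )

    records = transition_records(
        state_calls[conditions[0]], state_calls[conditions[1]], coerce_discordant
    )
    tally = tally_records(
        records, state_calls[conditions[0]], state_calls[conditions[1]]
    )
    return PipelineResult(
        conditions=conditions,
        binding=binding,
        detections=detections,
        retained_probes=retained,
        normalized=normalized,
        transcripts=transcripts,
        state_calls=state_calls,
        records=records,
        tally=tally,
    )


def state_accuracy(
    calls: pd.DataFrame, truth: pd.DataFrame, truth_column: str
) -> float:
    """Fraction of loci whose called state equals the ground-truth state.

    DISCORDANT calls count as errors (they match no true state). Loci
    missing from *calls* (dropped from the analyzed set) also count against
    accuracy, so the measure is over the full truth table.
    """
    called = calls.set_index("gene_id")["state"]
    true = truth.set_index("gene_id")[truth_column]
    aligned = called.reindex(true.index)
    return float((aligned == true).mean())
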