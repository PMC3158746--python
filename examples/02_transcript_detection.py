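"""Detect full-length transcripts on a small simulated bead-array sample.

Simulates one condition's expression replicates, computes per-probe
detection p-values against the negative-control pool, applies the
detection-score filter and prints the gene-level transcript calls next to
the ground truth.
"""

import pandas as pd

import pausetrack as pt

params = pt.SimParams(n_genes=12, n_controls=200, seed=42)
study = pt.simulate_study(params)

detections = pd.concat(
    [pt.detect_sample(s) for s in study.expression], ignore_index=True
)
retained = pt.filter_probes(pt.score_matrix(detections))
calls = pt.call_transcripts(detections, retained)

cond = params.conditions[0]
table = (
    calls.loc[calls["condition"] == cond]
    .merge(study.truth[["gene_id", "state_1"]], on="gene_id")
)
print(table.to_string(index=False))
print()
print(
    f"{len(retained)} of {params.n_genes} gene probes survive the 0.99 "
    "detection-score filter.\n"
    "Expressed genes are exactly the truly ACTIVE ones: only elongating loci\n"
    "put 3' transcript on the array, so PAUSED loci look like background here\n"
    "(min_p is the smallest detection p-value over probes and replicates)."
)
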