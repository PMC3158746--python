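# pausetrack

Transcriptional pausing — initiation without productive elongation — is
widespread in mammalian genomes, and during differentiation the paused state
acts as the waypoint through which most genes change expression. `pausetrack`
implements the analysis chain for studying this with two promoter-centric
array readouts: H3K4me3 ChIP enrichment (a chromatin mark of transcriptional
initiation) and 3′ expression-array detection (evidence of full-length
transcript, i.e. elongation). It is aimed at epigenomics analysts who want
the state-calling and transition-accounting logic as a tested, reusable
library rather than a one-off script.

## The model

Each protein-coding locus *g* is summarised as a metagene: its promoter
probes at signed offsets *x* ∈ [−4000, +4000] bp from the TSS, carrying
log₂-ratios r(x) = log₂((H3K4me3 + c)/(panH3 + c)) with pseudocount c = 1.
The locus is **initiating** if

- any point r(x) > 1.5, at any offset, or
- any point r(x) > 0.8 with −1250 ≤ x ≤ +750 (endpoints inclusive; both
  comparisons strict).

The locus is **elongating** if its 3′ expression probes rise above the
array's negative-control background: a one-sided pooled-variance two-sample
Student's t-test per probe, with detection p < 10⁻³ (under configurable
any/all aggregation over probes and replicates). Probes with detection
score 1 − p < 0.99 in every sample are discarded first; retained
intensities are quantile-normalized for reported levels.

The two booleans define three states — **active** (initiating and
elongating), **paused** (initiating only), **silent** (neither); the
remaining cell of the truth table is tracked as *discordant* and excluded
from tallies. Between two cell populations the states admit nine ordered
transitions, grouped as stable (A→A, P→P, S→S), activation (P→A, S→A),
silencing (A→P, A→S), priming (S→P) and archiving (P→S), with S→A and A→S
flagged *direct*. Per-GO-term profiles then summarise how a term's paused
loci exit the paused state (archive vs activate), which reads out lineage
fate.

A synthetic-data generator emulates both platforms from a known per-gene
ground truth, so the entire chain is testable end to end without any
external downloads.

## Worked example

```python
import pausetrack as pt

study = pt.simulate_study(pt.SimParams(seed=1))      # 2000 genes, 2 conditions
result = pt.run_pipeline(study.chip, study.expression)

t = result.tally
print(t.n_loci, t.n_changing, t.changing_percent)
print(t.category_percents)
print(t.paused_intermediate_percent)
```

prints

```
1999 256 12.8
{'activation': 23.0, 'silencing': 12.9, 'priming': 31.6, 'archiving': 32.4}
98.8
```

— of 1999 analyzed loci, 256 (12.8%) changed state between the two
conditions; among the changers, priming and archiving dominate, and 98.8%
pass into or out of the paused state rather than jumping directly between
active and silent. `pt.state_accuracy(result.state_calls["pluripotent"],
study.truth, "state_1")` confirms the calls recover the generator's truth
(99.7% here; 100% when the study is simulated with
`SimParams(seed=1).zero_noise()`).

The `examples/` directory holds one short narrative script per capability
(binding calls, transcript detection, transition tallies, ontology fate
ranking, file round-trips), and the `pausetrack` CLI exposes the same
stages (`simulate`, `call-chip`, `call-expr`, `transitions`, `ontology`)
for shell use.

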