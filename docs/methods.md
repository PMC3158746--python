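# Methods

## State model

A locus's transcriptional state is the conjunction of two independent
binary measurements:

* **Initiation** — promoter H3K4me3 enrichment from a two-color tiling
  ChIP array, summarised per locus as a metagene of log₂(H3K4me3/panH3)
  ratios at probe offsets relative to the TSS. PanH3 normalisation cancels
  nucleosome-density effects so the ratio isolates the methylation mark.
* **Elongation** — 3′ expression-array detection. Because the platform is
  oligo-dT primed, signal requires a full-length transcript; a paused locus
  (initiating but not elongating) therefore shows promoter H3K4me3 with
  background-level expression probes.

States: ACTIVE = initiating ∧ elongating, PAUSED = initiating only,
SILENT = neither. The fourth combination (elongating without initiation) is
biologically anomalous under this model — it would mean transcript without
the initiation mark — and is labelled DISCORDANT. It is excluded from
transition tallies and reported as a separate count; a configuration switch
(`coerce_discordant="active"`) instead folds it into ACTIVE on the argument
that transcript evidence trumps a missed ChIP call. Exclusion is the
default because the three-state scheme's definitions are exhaustive only
over the other three cells, and at realistic error rates discordant loci
are rare (a fraction of a percent in the synthetic studies).

## Binding caller

The caller scans the metagene's points — one point per probe, no smoothing,
binning or interpolation — against two rules: a *global* threshold of 1.5
log₂ units at any offset, and a *window* threshold of 0.8 log₂ units for
offsets in [−1250, +750] bp. "Over" is strict (`>`); the window endpoints
are inclusive. The window rule exists because promoter-proximal enrichment
is informative at lower amplitude than enrichment anywhere in the ±4 kb
tile. Both thresholds, the window, and the pseudocount (1.0 intensity unit
added to both channels so zero intensities are well-defined) are
configurable (`ChipCallerConfig`).

Replicate ChIP arrays are averaged probe-wise on the intensity scale before
the ratio is taken, yielding one metagene and one call per locus per
population; per-replicate calling can be had by passing replicates as
separate tables. Loci with no probes raise a missing-data signal and fall
out of the analyzed set, mirroring the platform-intersection restriction
below.

## Detection and transcript calls

Per probe and sample, the detection p-value is a one-sided two-sample
Student's t-test (pooled variance, probe beads vs the sample's
negative-control intensity pool), computed from summary statistics (mean,
SD, count per group). Pooled rather than Welch variance is used because the
classical Student test is the stated model; with hundreds of controls the
difference is negligible. Degenerate zero-variance input returns p = 0.5
at equal means, else 0 or 1 by the sign of the difference — this makes the
noise-free limit exact rather than undefined.

Probe filtering discards a probe only when its detection score (1 − p)
falls below 0.99 in **every** sample, so a transcript present in either
condition keeps its probe alive in both. Quantile normalization (columns
mapped rank-wise onto the mean of sorted columns; ties receive the mean of
the reference quantiles they span) corrects between-sample intensity
distributions for reported levels; detection p-values are always computed
on raw intensities, upstream of normalization, matching the platform's
order of operations. A consequence of the tie rule worth knowing: with
within-column ties, re-normalizing an already-normalized matrix can shift
tie-free columns slightly, because blended tie values perturb the
reference; on tie-free data the map is exactly idempotent.

The gene-level call aggregates retained probes over a condition's
replicates: by default the locus is expressed if *any* retained probe in
*any* replicate has p < 10⁻³. Both rules flip independently to "all"
(`ExprCallerConfig`); the permissive default reflects that detection is a
sensitivity question, not a differential test. Genes whose probes were all
discarded are called not-expressed with flag `no_probe`.

## Transitions and summaries

The analyzed locus set is the intersection of loci with ≥1 ChIP probe and
a transcript call in both conditions. Each locus contributes one ordered
state pair; the nine pairs partition the set, the six non-stable pairs
partition the changers into activation / silencing / priming / archiving,
and S→A / A→S carry the *direct* flag. All percentages are reported to one
decimal using round-half-to-even, the convention of the built-in `round`.
When no locus changes, category shares are undefined and reported as
not-applicable (`None`/JSON `null`) rather than zero.

Ontology profiles restrict the genome-wide transition table to each GO
term's directly annotated genes (NCBI gene2go dialect, `NOT`-qualified rows
excluded, no propagation to ancestor terms, no enrichment statistics — the
output is descriptive). The fate report ranks terms by the share of their
paused changing loci that archive versus activate, with the two shares over
a common denominator; terms with no analyzed genes are skipped, and ties
rank by term id for determinism.

## Synthetic data generator

The generator defines the study conditions under which the pipeline is
validated. Ground truth: condition-1 states are multinomial with marginals
A/P/S = 0.47/0.48/0.05; condition-2 states follow a per-state transition
row built analytically from the summary-level parameters — changing
fraction 0.12, category shares 0.22/0.17/0.30/0.31
(activation/silencing/priming/archiving), direct share 0.01 of changers
split evenly between S→A and A→S. The construction divides each
joint-transition mass by its source-state marginal, so the expected
summaries equal the parameters by design and any feasible combination is
accepted (infeasible ones, e.g. more priming mass than silent loci, raise
a validation error).

ChIP emulation: 33 probes per gene at 250-bp spacing across ±4 kb.
Initiating loci receive a Gaussian enrichment bump centred on the TSS
(height 2.0 log₂, SD 500 bp) plus i.i.d. Gaussian probe noise (SD 0.3
log₂); silent loci receive noise only. Intensities are back-computed from
the intended log-ratio against a flat panH3 channel (100 units) with the
caller's pseudocount, so the metagene builder reproduces the intended
ratios exactly; intensities are clipped at zero, which can only affect
probes depleted beyond −6.7 log₂ and never changes a call. These shapes
and noise levels are the package's own choices, set so the margins to the
0.8/1.5 thresholds make error rates analytically boundable: a silent locus
false-positives only when one of nine window probes exceeds 0.8/0.3 ≈ 2.7
noise SDs (≈0.4% per probe), and an initiating locus essentially never
misses because its TSS probe sits 4 noise SDs above the window threshold.

Expression emulation: one probe per gene, 30 beads per probe, background
mean 100 with SD 10; ACTIVE loci shift by 10 control SDs (+100). The
negative-control pool enters at bead level — 750 single-bead control
entries — so its spread matches the bead-level variance the t-test pools
against; pooling a bead-level group against a pool of probe *means* would
inflate the statistic roughly √30-fold and break calibration. Two
replicates per condition. `zero_noise()` removes both platforms' noise,
giving a setting where the pipeline must recover truth exactly.

Ontology emulation: lineage-tagged terms of 60 genes drawing 80% of
members from P→A loci ("mesoderm-like"), P→S loci ("ectoderm-like") or
stable-active loci ("housekeeping"), plus uniformly sampled background
terms. With ~50 paused changers per lineage term, the archiving/activating
shares of the two lineage classes are separated by tens of percentage
points, far beyond sampling noise at that size.

All randomness flows from one integer seed through per-component child
seeds, so generated studies — including their written files — are
byte-identical across runs.

What the generator does **not** emulate: dye bias and spatial artifacts on
the two-color array, bead-level outliers and rank-based detection variants
on the expression platform, 3′-coverage bias within transcripts, probe
cross-hybridisation, and correlated (non-i.i.d.) probe noise. Passing
recovery tests therefore demonstrates the correctness of the calling and
accounting logic under the stated statistical model, not robustness to
platform pathologies.

## Problem sizes and numerical choices

Tests and the acceptance script use 2000-gene studies (two conditions, two
expression replicates, 750 controls), the size at which category shares of
~250 changing loci have multinomial 95% half-widths of 5–6 percentage
points; caller/oracle agreement is checked on 10⁵ random profiles. Worked
percentage arithmetic is additionally exercised at published scale
(12,867 loci) with exact integer transition counts. Detection p-values are
validated against an independent evaluation of the t CDF at the
pooled-variance statistic to 10⁻¹⁰ relative error.

## Known limitations

* Only pairwise condition comparisons; no multi-stage path inference.
* No statistical tests on distribution differences or GO enrichment —
  summaries are descriptive by design.
* Probe-to-gene assignment is taken from the input tables; overlapping
  promoters sharing probes are not modelled (nearest-TSS single assignment
  is assumed upstream).
* The detection score is 1 − p from the t-test; rank-based detection
  variants used by some vendor software are not implemented.
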