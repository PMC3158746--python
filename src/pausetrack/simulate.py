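"""Synthetic two-condition study generator with known ground truth.

The generator draws a per-gene ground truth — a transcriptional state in
condition 1 and, through a transition matrix, a state in condition 2 — and
then emulates the two array platforms the pipeline consumes:

* a tiling promoter ChIP array (33 probes per gene, -4000..+4000 bp at
  250-bp spacing) where initiating loci carry a Gaussian H3K4me3 enrichment
  bump over the TSS (height 2.0 log2, SD 500 bp) on top of Gaussian probe
  noise, and intensities are back-computed so the metagene builder recovers
  the intended log-ratios exactly;
* a bead expression array (negative-control probe pool plus one probe per
  gene) where elongating (ACTIVE) loci sit a fixed number of control SDs
  above the background mean.

Default parameters mirror the structure of an embryonic-stem-cell to
mesoderm differentiation experiment: state marginals 47/48/5% (A/P/S),
~12% of loci changing state, category shares of changing loci
activation/silencing/priming/archiving = 22/17/30/31%, and ~1% direct
(A<->S) transitions. Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import (
    ExpressionSample,
    write_expression_sample,
    write_gene2go,
    write_probe_signals,
    write_tss_annotation,
    _write_table,
)
from .ontology import GoTerm
from .states import ACTIVE, PAUSED, SILENT, STATES

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


@dataclass
class SimParams:
    """Study conditions of the synthetic experiment.

    The transition structure is parameterised the way results are reported —
    overall changing fraction, category shares of changing loci, direct
    share — and converted internally into a 3x3 stochastic matrix consistent
    with the condition-1 marginals.
    """

    n_genes: int = 2000
    state_dist: tuple = (0.47, 0.48, 0.05)          # A, P, S in condition 1
    changing_fraction: float = 0.12
    category_shares: dict = field(default_factory=lambda: {
        "activation": 0.22, "silencing": 0.17,
        "priming": 0.30, "archiving": 0.31,
    })
    direct_share: float = 0.01                      # of changing loci
    conditions: tuple = ("pluripotent", "mesoderm")

    # ChIP platform
    peak_height: float = 2.0                        # log2 units at the TSS
    peak_sd: float = 500.0                          # bp
    chip_noise_sd: float = 0.3                      # log2 units per probe
    panh3_intensity: float = 100.0
    pseudocount: float = 1.0
    probe_spacing: int = 250
    probe_span: int = 4000

    # expression platform
    control_mean: float = 100.0
    control_sd: float = 10.0                        # background scale
    shift_control_sds: float = 10.0                 # expressed-gene shift
    expr_noise_sd: float | None = None              # None -> control_sd
    n_controls: int = 750
    bead_count: int = 30
    n_replicates: int = 2

    # ontology generator
    n_lineage_terms: int = 3                        # per lineage class
    n_background_terms: int = 5
    genes_per_term: int = 60
    term_purity: float = 0.8

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if abs(sum(self.state_dist) - 1.0) > 1e-9 or min(self.state_dist) < 0:
            raise ValidationError("state_dist must be a probability vector")
        if abs(sum(self.category_shares.values()) - 1.0) > 1e-9:
            raise ValidationError("category_shares must sum to 1")
        if not 0 <= self.direct_share < 1:
            raise ValidationError("direct_share must be in [0, 1)")
        if not 0 <= self.changing_fraction <= 1:
            raise ValidationError("changing_fraction must be in [0, 1]")
        for sd in (self.peak_sd,):
            if sd <= 0:
                raise ValidationError("peak_sd must be positive")
        if self.chip_noise_sd < 0 or self.control_sd < 0:
            raise ValidationError("noise SDs must be nonnegative")
        transition_matrix(self)  # raises if the shares are infeasible

    @property
    def effective_expr_noise(self) -> float:
        return self.control_sd if self.expr_noise_sd is None else self.expr_noise_sd

    @property
    def expression_shift(self) -> float:
        return self.shift_control_sds * self.control_sd

    def zero_noise(self) -> "SimParams":
        """The same study with all measurement noise removed."""
        return replace(self, chip_noise_sd=0.0, expr_noise_sd=0.0)


def transition_matrix(params: SimParams) -> np.ndarray:
    """3x3 condition-1 -> condition-2 transition matrix, rows/cols A, P, S.

    Built so that the expected changing fraction, category shares and direct
    share match the parameters exactly given the condition-1 marginals. The
    direct mass is split evenly between S->A and A->S.
    """
    p_a, p_p, p_s = params.state_dist
    c = params.changing_fraction
    shares = params.category_shares
    act, sil = c * shares["activation"], c * shares["silencing"]
    prim, arch = c * shares["priming"], c * shares["archiving"]
    half_direct = c * params.direct_share / 2.0
    if half_direct > min(act, sil) and c > 0:
        raise ValidationError("direct share exceeds the activation/silencing mass")
    mass = np.zeros((3, 3))  # mass[i, j] = P(state_1 = i, state_2 = j)
    mass[_STATE_INDEX[PAUSED], _STATE_INDEX[ACTIVE]] = act - half_direct
    mass[_STATE_INDEX[SILENT], _STATE_INDEX[ACTIVE]] = half_direct
    mass[_STATE_INDEX[ACTIVE], _STATE_INDEX[PAUSED]] = sil - half_direct
    mass[_STATE_INDEX[ACTIVE], _STATE_INDEX[SILENT]] = half_direct
    mass[_STATE_INDEX[SILENT], _STATE_INDEX[PAUSED]] = prim
    mass[_STATE_INDEX[PAUSED], _STATE_INDEX[SILENT]] = arch
    marginals = np.array([p_a, p_p, p_s])
    for i in range(3):
        off_diag = mass[i].sum()
        if marginals[i] == 0.0:
            if off_diag > 0:
                raise ValidationError(
                    f"transitions out of {STATES[i]} but its marginal is 0"
                )
            mass[i, i] = 0.0
            continue
        if off_diag > marginals[i] + 1e-12:
            raise ValidationError(
                f"transition mass out of {STATES[i]} exceeds its marginal"
            )
        mass[i, i] = marginals[i] - off_diag
    safe = np.where(marginals > 0, marginals, 1.0)
    matrix = np.where(marginals[:, None] > 0, mass / safe[:, None], 0.0)
    for i in range(3):
        if marginals[i] == 0.0:
            matrix[i, i] = 1.0
    return matrix


# ---------------------------------------------------------------------------
# truth and annotation
# ---------------------------------------------------------------------------

def generate_truth(params: SimParams) -> pd.DataFrame:
    """Draw per-gene ground-truth states for both conditions.

    Returns columns ``gene_id``, ``state_1``, ``state_2`` and a ``lineage``
    tag: *mesoderm-like* for P->A loci, *ectoderm-like* for P->S loci,
    *housekeeping* for stably ACTIVE loci, *none* otherwise.
    """
    rng = np.random.default_rng([params.seed, 0])
    n = params.n_genes
    s1 = rng.choice(3, size=n, p=np.asarray(params.state_dist))
    matrix = transition_matrix(params)
    s2 = np.empty(n, dtype=int)
    for i in range(3):
        idx = np.flatnonzero(s1 == i)
        if idx.size:
            s2[idx] = rng.choice(3, size=idx.size, p=matrix[i])
    state_1 = np.array(STATES)[s1]
    state_2 = np.array(STATES)[s2]
    lineage = np.full(n, "none", dtype=object)
    lineage[(state_1 == PAUSED) & (state_2 == ACTIVE)] = "mesoderm-like"
    lineage[(state_1 == PAUSED) & (state_2 == SILENT)] = "ectoderm-like"
    lineage[(state_1 == ACTIVE) & (state_2 == ACTIVE)] = "housekeeping"
    width = len(str(n))
    gene_ids = [f"G{i + 1:0{width}d}" for i in range(n)]
    return pd.DataFrame(
        {"gene_id": gene_ids, "state_1": state_1, "state_2": state_2,
         "lineage": lineage}
    )


def tss_annotation(truth: pd.DataFrame) -> pd.DataFrame:
    """Deterministic TSS annotation for the synthetic genes (chr1, 10-kb grid)."""
    n = len(truth)
    return pd.DataFrame(
        {
            "chromosome": "chr1",
            "strand": np.where(np.arange(n) % 2 == 0, "+", "-"),
            "tss": 100_000 + 10_000 * np.arange(n),
        },
        index=pd.Index(truth["gene_id"], name="gene_id"),
    )


# ---------------------------------------------------------------------------
# platforms
# ---------------------------------------------------------------------------

def simulate_chip(truth: pd.DataFrame, params: SimParams) -> dict[str, pd.DataFrame]:
    """Probe-level ChIP signal tables, one per condition.

    Initiating loci (ACTIVE or PAUSED) carry the Gaussian log-ratio bump;
    SILENT loci carry noise only. The panH3 channel is flat and the H3K4me3
    channel is back-computed from the intended log-ratio, so the metagene
    builder's log2((h3k4me3+pc)/(panh3+pc)) reproduces it (up to clipping of
    intensities at zero, which only affects deeply depleted probes).
    """
    rng = np.random.default_rng([params.seed, 1])
    offsets = np.arange(-params.probe_span, params.probe_span + 1,
                        params.probe_spacing)
    bump = params.peak_height * np.exp(-offsets**2 / (2.0 * params.peak_sd**2))
    n, m = len(truth), offsets.size
    probe_ids = np.array(
        [f"{g}:{o:+d}" for g in truth["gene_id"] for o in offsets]
    )
    gene_col = np.repeat(truth["gene_id"].to_numpy(), m)
    offset_col = np.tile(offsets, n)
    out: dict[str, pd.DataFrame] = {}
    for cond, state_col in zip(params.conditions, ("state_1", "state_2")):
        initiating = truth[state_col].isin([ACTIVE, PAUSED]).to_numpy()
        mu = np.where(initiating[:, None], bump[None, :], 0.0)
        lr = mu + rng.normal(0.0, params.chip_noise_sd, size=(n, m)) \
            if params.chip_noise_sd > 0 else mu
        panh3 = np.full(n * m, params.panh3_intensity)
        h3k4me3 = (panh3 + params.pseudocount) * np.exp2(lr.ravel()) \
            - params.pseudocount
        out[cond] = pd.DataFrame(
            {
                "probe_id": probe_ids,
                "gene_id": gene_col,
                "offset": offset_col,
                "h3k4me3": np.clip(h3k4me3, 0.0, None),
                "panh3": panh3,
            }
        )
    return out


def simulate_expression(
    truth: pd.DataFrame, params: SimParams
) -> list[ExpressionSample]:
    """Bead-array expression samples: replicates per condition plus controls.

    One probe per gene. ACTIVE loci draw bead intensities around
    control mean + shift; PAUSED and SILENT loci around the control mean —
    only elongation separates signal from background, mirroring a 3'-biased
    oligo-dT platform that sees full-length transcripts only.

    Negative controls enter as a bead-level pool: each of the ``n_controls``
    control entries is a single bead intensity (bead_count 1), so the pool's
    spread matches the bead-level noise the t-test pools against.
    """
    rng = np.random.default_rng([params.seed, 2])
    noise = params.effective_expr_noise
    n = len(truth)
    gene_probe_ids = np.array([f"EP_{g}" for g in truth["gene_id"]])
    ctrl_ids = np.array([f"CTRL{i + 1:04d}" for i in range(params.n_controls)])
    samples = []
    for cond, state_col in zip(params.conditions, ("state_1", "state_2")):
        level = np.where(
            truth[state_col].to_numpy() == ACTIVE,
            params.control_mean + params.expression_shift,
            params.control_mean,
        )
        for rep in range(1, params.n_replicates + 1):
            shape = (n, params.bead_count)
            noise_mat = (
                rng.normal(0.0, noise, size=shape) if noise > 0
                else np.zeros(shape)
            )
            beads = level[:, None] + noise_mat
            ctrl_noise = (
                rng.normal(0.0, noise, size=params.n_controls) if noise > 0
                else np.zeros(params.n_controls)
            )
            ctrl_intensity = params.control_mean + ctrl_noise
            probes = pd.DataFrame(
                {
                    "probe_id": np.concatenate([gene_probe_ids, ctrl_ids]),
                    "gene_id": np.concatenate(
                        [truth["gene_id"].to_numpy(),
                         np.full(params.n_controls, "-")]
                    ),
                    "is_control": np.concatenate(
                        [np.zeros(n, bool), np.ones(params.n_controls, bool)]
                    ),
                    "mean_intensity": np.concatenate(
                        [beads.mean(axis=1), ctrl_intensity]
                    ),
                    "bead_sd": np.concatenate(
                        [beads.std(axis=1, ddof=1),
                         np.zeros(params.n_controls)]
                    ),
                    "bead_count": np.concatenate(
                        [np.full(n, params.bead_count),
                         np.ones(params.n_controls, dtype=int)]
                    ),
                }
            )
            samples.append(
                ExpressionSample(
                    sample_id=f"{cond}_rep{rep}", condition=cond,
                    replicate=rep, probes=probes,
                )
            )
    return samples


# ---------------------------------------------------------------------------
# ontology annotations
# ---------------------------------------------------------------------------

def generate_go_annotations(
    truth: pd.DataFrame, params: SimParams
) -> dict[str, GoTerm]:
    """Synthetic gene2go-style annotations tied to the lineage structure.

    *mesoderm-like* terms draw ``term_purity`` of their members from P->A
    loci, *ectoderm-like* terms from P->S loci, *housekeeping* terms from
    stably ACTIVE loci; *background* terms sample uniformly. Membership
    overlap between terms is allowed, as in real annotation sets.
    """
    rng = np.random.default_rng([params.seed, 3])
    genes = truth["gene_id"].to_numpy()
    pools = {
        "mesoderm-like": genes[truth["lineage"].to_numpy() == "mesoderm-like"],
        "ectoderm-like": genes[truth["lineage"].to_numpy() == "ectoderm-like"],
        "housekeeping": genes[truth["lineage"].to_numpy() == "housekeeping"],
    }
    terms: dict[str, GoTerm] = {}
    next_id = 9_000_001

    def _add_term(name: str, members: np.ndarray) -> None:
        nonlocal next_id
        go_id = f"GO:{next_id:07d}"
        next_id += 1
        terms[go_id] = GoTerm(
            go_id=go_id, name=name, category="Process",
            genes=frozenset(members.tolist()),
        )

    term_size = min(params.genes_per_term, genes.size)
    for lineage, pool in pools.items():
        for k in range(params.n_lineage_terms):
            n_core = min(int(round(params.term_purity * term_size)), pool.size)
            core = rng.choice(pool, size=n_core, replace=False)
            filler_pool = np.setdiff1d(genes, core)
            n_filler = min(term_size - n_core, filler_pool.size)
            filler = rng.choice(filler_pool, size=n_filler, replace=False)
            _add_term(f"{lineage}-{k + 1}", np.concatenate([core, filler]))
    for k in range(params.n_background_terms):
        members = rng.choice(genes, size=term_size, replace=False)
        _add_term(f"background-{k + 1}", members)
    return terms


# ---------------------------------------------------------------------------
# bundles and file output
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """Everything the pipeline consumes, plus the ground truth."""

    params: SimParams
    truth: pd.DataFrame
    annotation: pd.DataFrame
    chip: dict[str, pd.DataFrame]
    expression: list[ExpressionSample]
    terms: dict[str, GoTerm]


def simulate_study(params: SimParams) -> SimulatedStudy:
    """Generate a complete synthetic study (truth, both platforms, ontology)."""
    truth = generate_truth(params)
    return SimulatedStudy(
        params=params,
        truth=truth,
        annotation=tss_annotation(truth),
        chip=simulate_chip(truth, params),
        expression=simulate_expression(truth, params),
        terms=generate_go_annotations(truth, params),
    )


def write_truth(truth: pd.DataFrame, path) -> None:
    _write_table(truth[["gene_id", "state_1", "state_2", "lineage"]], path)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep="\t", skiprows=1, header=None,
        names=["gene_id", "state_1", "state_2", "lineage"], dtype=str,
    )


def write_study(study: SimulatedStudy, outdir) -> dict[str, Path]:
    """Write a simulated study to disk in the pipeline's file dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["tss"] = outdir / "tss.bed"
    write_tss_annotation(study.annotation, paths["tss"])
    for cond, table in study.chip.items():
        key = f"chip_{cond}"
        paths[key] = outdir / f"{key}.tsv"
        write_probe_signals(table, paths[key])
    for sample in study.expression:
        key = f"expr_{sample.sample_id}"
        paths[key] = outdir / f"{key}.tsv"
        write_expression_sample(sample, paths[key])
    paths["gene2go"] = outdir / "gene2go.tsv"
    write_gene2go(study.terms, paths["gene2go"])
    paths["truth"] = outdir / "truth.tsv"
    write_truth(study.truth, paths["truth"])
    return paths
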