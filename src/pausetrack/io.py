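"""Readers and writers for every external file the pipeline touches.

All tables are tab-delimited UTF-8. Package-native tables carry a single
``#``-prefixed header line naming the columns (expression samples also carry
``#key=value`` metadata lines); the TSS annotation is plain BED6 and the
ontology file follows the NCBI gene2go dialect.

Coordinate conventions: BED intervals are 0-based half-open; the TSS of a
minus-strand gene is the interval *end*. Probe offsets are stored
transcription-oriented (negative = upstream of the TSS) so no downstream code
needs strand logic.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .ontology import GoTerm

logger = logging.getLogger(__name__)

PROBE_WINDOW = 4000  # bp; promoter tiling spans [-4000, +4000] around the TSS

_GO_ID_RE = re.compile(r"^GO:\d{7}$")

STATE_COLUMNS = ["gene_id", "condition", "initiating", "elongating", "state"]
TRANSITION_COLUMNS = [
    "gene_id", "from_state", "to_state", "transition", "category", "direct",
]


# ---------------------------------------------------------------------------
# TSS annotation (BED6)
# ---------------------------------------------------------------------------

def read_tss_annotation(path) -> pd.DataFrame:
    """Read a BED6 file of gene loci into a TSS annotation.

    Returns a DataFrame indexed by ``gene_id`` with columns ``chromosome``,
    ``strand`` and ``tss``. The TSS is the interval start for ``+`` genes and
    the interval end for ``-`` genes (BED half-open semantics).

    Raises
    ------
    ParseError
        On a malformed line (wrong field count, non-integer coordinates,
        unknown strand); the message names the line number.
    ValidationError
        On a duplicate gene_id or a negative TSS.
    """
    records = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ParseError(
                    f"{path}: line {lineno}: expected >=6 BED fields, got {len(fields)}"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            if strand not in ("+", "-"):
                raise ParseError(
                    f"{path}: line {lineno}: strand must be '+' or '-', got {strand!r}"
                )
            tss = start if strand == "+" else end
            if tss < 0:
                raise ValidationError(f"{path}: line {lineno}: negative TSS {tss}")
            records.append((name, chrom, strand, tss))
    df = pd.DataFrame(records, columns=["gene_id", "chromosome", "strand", "tss"])
    dup = df["gene_id"].duplicated()
    if dup.any():
        raise ValidationError(
            f"{path}: duplicate gene_id(s): {sorted(df.loc[dup, 'gene_id'].unique())}"
        )
    return df.set_index("gene_id")


def write_tss_annotation(annotation: pd.DataFrame, path) -> None:
    """Write a TSS annotation back to BED6 (intervals of length 1000)."""
    with open(path, "w", encoding="utf-8") as fh:
        for gene_id, row in annotation.iterrows():
            tss = int(row["tss"])
            if row["strand"] == "+":
                start, end = tss, tss + 1000
            else:
                start, end = max(tss - 1000, 0), tss
            fh.write(
                f"{row['chromosome']}\t{start}\t{end}\t{gene_id}\t0\t{row['strand']}\n"
            )


# ---------------------------------------------------------------------------
# Probe-level ChIP signal
# ---------------------------------------------------------------------------

def read_probe_signals(path, annotation: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a probe-level ChIP signal table.

    Columns: ``probe_id``, ``gene_id``, ``offset`` (signed bp from the TSS,
    transcription-oriented), ``h3k4me3``, ``panh3``.

    If *annotation* is given, records whose gene_id is absent from it are
    dropped; the dropped count is logged and stored in
    ``result.attrs["n_dropped_unannotated"]``.

    Raises
    ------
    ValidationError
        On an offset outside [-4000, +4000] or a negative intensity.
    """
    df = pd.read_csv(
        path, sep="\t", comment=None, header=None, skiprows=_count_header_lines(path),
        names=["probe_id", "gene_id", "offset", "h3k4me3", "panh3"],
        dtype={"probe_id": str, "gene_id": str},
    )
    bad_window = df["offset"].abs() > PROBE_WINDOW
    if bad_window.any():
        raise ValidationError(
            f"{path}: {int(bad_window.sum())} probe(s) outside the "
            f"[-{PROBE_WINDOW}, +{PROBE_WINDOW}] bp window "
            f"(first: {df.loc[bad_window, 'probe_id'].iloc[0]})"
        )
    if (df[["h3k4me3", "panh3"]] < 0).any().any():
        raise ValidationError(f"{path}: negative intensity")
    n_dropped = 0
    if annotation is not None:
        known = df["gene_id"].isin(annotation.index)
        n_dropped = int((~known).sum())
        if n_dropped:
            logger.info(
                "%s: dropped %d probe record(s) for genes absent from the annotation",
                path, n_dropped,
            )
        df = df.loc[known].reset_index(drop=True)
    df.attrs["n_dropped_unannotated"] = n_dropped
    return df


def write_probe_signals(df: pd.DataFrame, path) -> None:
    cols = ["probe_id", "gene_id", "offset", "h3k4me3", "panh3"]
    _write_table(df[cols], path)


# ---------------------------------------------------------------------------
# Expression samples (bead-array summaries)
# ---------------------------------------------------------------------------

@dataclass
class ExpressionSample:
    """One bead-array sample: per-probe intensity summaries plus metadata.

    ``probes`` has columns ``probe_id``, ``gene_id`` ('-' for controls),
    ``is_control`` (bool), ``mean_intensity``, ``bead_sd``, ``bead_count``.
    The negative-control probes form the background pool for detection
    p-values.
    """

    sample_id: str
    condition: str
    replicate: int
    probes: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        p = self.probes
        if not p["is_control"].any():
            raise ValidationError(
                f"sample {self.sample_id}: no negative-control probes"
            )
        if (p["bead_count"] < 1).any():
            raise ValidationError(f"sample {self.sample_id}: bead_count < 1")
        noncontrol = p.loc[~p["is_control"]]
        if (noncontrol["gene_id"] == "-").any():
            raise ValidationError(
                f"sample {self.sample_id}: non-control probe without a gene_id"
            )
        multi = noncontrol.groupby("probe_id")["gene_id"].nunique()
        if (multi > 1).any():
            raise ValidationError(
                f"sample {self.sample_id}: probe mapped to multiple genes"
            )

    @property
    def control_pool(self) -> np.ndarray:
        """Intensities of the negative-control probes (the background pool)."""
        return self.probes.loc[self.probes["is_control"], "mean_intensity"].to_numpy()


def read_expression_sample(path) -> ExpressionSample:
    """Read one expression sample written by :func:`write_expression_sample`."""
    meta: dict[str, str] = {}
    n_header = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
    for key in ("sample_id", "condition", "replicate"):
        if key not in meta:
            raise ParseError(f"{path}: missing '#{key}=' metadata line")
    df = pd.read_csv(
        path, sep="\t", skiprows=n_header, header=None,
        names=["probe_id", "gene_id", "is_control", "mean_intensity",
               "bead_sd", "bead_count"],
        dtype={"probe_id": str, "gene_id": str},
    )
    df["is_control"] = df["is_control"].astype(bool)
    return ExpressionSample(
        sample_id=meta["sample_id"],
        condition=meta["condition"],
        replicate=int(meta["replicate"]),
        probes=df,
    )


def write_expression_sample(sample: ExpressionSample, path) -> None:
    cols = ["probe_id", "gene_id", "is_control", "mean_intensity",
            "bead_sd", "bead_count"]
    df = sample.probes[cols].copy()
    df["is_control"] = df["is_control"].astype(int)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"#sample_id={sample.sample_id}\n")
        fh.write(f"#condition={sample.condition}\n")
        fh.write(f"#replicate={sample.replicate}\n")
        fh.write("#" + "\t".join(cols) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# gene2go ontology annotations
# ---------------------------------------------------------------------------

def read_gene2go(path) -> dict[str, GoTerm]:
    """Parse an NCBI gene2go-format file into a term -> GoTerm mapping.

    Dialect: an optional ``#`` header line, then tab-delimited columns
    tax_id, GeneID, GO_ID, Evidence, Qualifier, GO_term, PubMed, Category.
    Rows whose Qualifier contains ``NOT`` are excluded (negated annotations);
    duplicate (gene, term) rows collapse to one membership.
    """
    genes: dict[str, set[str]] = {}
    names: dict[str, tuple[str, str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 8:
                raise ParseError(
                    f"{path}: line {lineno}: expected 8 columns, got {len(fields)}"
                )
            _tax, gene_id, go_id, _evidence, qualifier, term, _pubmed, cat = fields
            if not _GO_ID_RE.match(go_id):
                raise ParseError(
                    f"{path}: line {lineno}: malformed GO id {go_id!r}"
                )
            if "NOT" in qualifier:
                continue
            genes.setdefault(go_id, set()).add(gene_id)
            names.setdefault(go_id, (term, cat))
    return {
        go_id: GoTerm(go_id=go_id, name=names[go_id][0],
                      category=names[go_id][1], genes=frozenset(members))
        for go_id, members in genes.items()
    }


def write_gene2go(terms: dict[str, GoTerm], path, tax_id: str = "9606") -> None:
    """Write an ontology map in the NCBI gene2go dialect."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "#tax_id\tGeneID\tGO_ID\tEvidence\tQualifier\tGO_term\tPubMed\tCategory\n"
        )
        for go_id in sorted(terms):
            term = terms[go_id]
            for gene in sorted(term.genes):
                fh.write(
                    f"{tax_id}\t{gene}\t{go_id}\tIEA\t-\t{term.name}\t-\t"
                    f"{term.category}\n"
                )


# ---------------------------------------------------------------------------
# State and transition tables
# ---------------------------------------------------------------------------

def write_state_table(calls: pd.DataFrame, path) -> None:
    """Write per-locus state calls; round-trips through read_state_table."""
    df = calls[STATE_COLUMNS].copy()
    df["initiating"] = df["initiating"].astype(int)
    df["elongating"] = df["elongating"].astype(int)
    _write_table(df, path)


def read_state_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", skiprows=1, header=None, names=STATE_COLUMNS,
        dtype={"gene_id": str, "condition": str, "state": str},
    )
    df["initiating"] = df["initiating"].astype(bool)
    df["elongating"] = df["elongating"].astype(bool)
    return df


def write_transition_table(records: pd.DataFrame, path) -> None:
    df = records[TRANSITION_COLUMNS].copy()
    df["direct"] = df["direct"].astype(int)
    _write_table(df, path)


def read_transition_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", skiprows=1, header=None, names=TRANSITION_COLUMNS,
        dtype={c: str for c in TRANSITION_COLUMNS[:-1]},
    )
    df["direct"] = df["direct"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _write_table(df: pd.DataFrame, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#" + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def _count_header_lines(path) -> int:
    n = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                n += 1
            else:
                break
    return n
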