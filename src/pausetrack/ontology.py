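"""Cross-tabulation of state transitions by Gene Ontology term.

Only direct gene2go annotations are used — no propagation up the GO graph —
and no enrichment statistics are computed: the report is descriptive. For
each term, the profile counts the term's analyzed loci in each of the nine
transitions and summarises the fate of its paused loci: among changing loci
that start PAUSED, the share that *archives* (loses initiation, P→S) versus
*activates* (starts elongating, P→A). Ranking terms by these shares
separates lineages being shut down from lineages being switched on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import ValidationError
from .states import ACTIVE, PAUSED, SILENT, TRANSITIONS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GoTerm:
    """One Gene Ontology term and its directly annotated gene set."""

    go_id: str
    name: str
    category: str  # Process / Function / Component
    genes: frozenset


@dataclass
class OntologyTransitionProfile:
    """Per-term transition counts and paused-exit fate percentages.

    ``percent_archiving`` and ``percent_activating`` share a denominator:
    the term's changing loci that start PAUSED; both are ``None`` when that
    denominator is zero.
    """

    go_id: str
    name: str
    n_genes: int
    transition_counts: dict = field(default_factory=dict)  # (from, to) -> n
    n_changing: int = 0
    percent_changing: float = 0.0
    n_paused_changing: int = 0
    percent_archiving: float | None = None
    percent_activating: float | None = None


def profile_term(
    term: GoTerm, records: pd.DataFrame
) -> OntologyTransitionProfile | None:
    """Profile one term over a transition-record table.

    *records* is the genome-wide per-locus transition table; counts are
    restricted to the intersection of the term's genes with the analyzed
    loci. Returns ``None`` (with a log entry) when the intersection is
    empty — the term is skipped.
    """
    sub = records.loc[records["gene_id"].isin(term.genes)]
    if len(sub) == 0:
        logger.info("term %s has no analyzed loci; skipped", term.go_id)
        return None
    counts = {t: 0 for t in TRANSITIONS}
    for pair in zip(sub["from_state"], sub["to_state"]):
        counts[pair] += 1
    changing = sub.loc[sub["category"] != "stable"]
    paused_changing = changing.loc[changing["from_state"] == PAUSED]
    profile = OntologyTransitionProfile(
        go_id=term.go_id,
        name=term.name,
        n_genes=len(sub),
        transition_counts=counts,
        n_changing=len(changing),
        percent_changing=round(100.0 * len(changing) / len(sub), 1),
        n_paused_changing=len(paused_changing),
    )
    if len(paused_changing) > 0:
        n_arch = int((paused_changing["to_state"] == SILENT).sum())
        n_act = int((paused_changing["to_state"] == ACTIVE).sum())
        denom = len(paused_changing)
        profile.percent_archiving = round(100.0 * n_arch / denom, 1)
        profile.percent_activating = round(100.0 * n_act / denom, 1)
    return profile


def profile_terms(
    terms: dict[str, GoTerm],
    records: pd.DataFrame,
    term_ids: list[str] | None = None,
) -> list[OntologyTransitionProfile]:
    """Profile a set of terms, skipping those with no analyzed loci."""
    ids = sorted(terms) if term_ids is None else term_ids
    profiles = []
    for go_id in ids:
        if go_id not in terms:
            raise ValidationError(f"term {go_id} absent from the ontology map")
        profile = profile_term(terms[go_id], records)
        if profile is not None:
            profiles.append(profile)
    return profiles


def fate_report(
    profiles: list[OntologyTransitionProfile],
    sort_by: str = "percent_archiving",
) -> pd.DataFrame:
    """Rank terms by how their paused loci exit the paused state.

    Returns one row per term with ``percent_archiving`` and
    ``percent_activating``, sorted descending by *sort_by* (ties broken by
    term id). Terms with no paused changing loci sort last.
    """
    if not profiles:
        raise ValidationError("no profiles to report")
    if sort_by not in ("percent_archiving", "percent_activating"):
        raise ValidationError(f"cannot sort by {sort_by!r}")
    df = pd.DataFrame(
        {
            "go_id": [p.go_id for p in profiles],
            "name": [p.name for p in profiles],
            "n_genes": [p.n_genes for p in profiles],
            "n_paused_changing": [p.n_paused_changing for p in profiles],
            "percent_archiving": [p.percent_archiving for p in profiles],
            "percent_activating": [p.percent_activating for p in profiles],
        }
    )
    return (
        df.sort_values(
            [sort_by, "go_id"],
            ascending=[False, True],
            na_position="last",
        )
        .reset_index(drop=True)
    )
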