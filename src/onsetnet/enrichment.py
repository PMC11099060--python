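"""Over-representation analysis against GMT annotation collections.

For a query gene set and each annotation term, the upper-tail hypergeometric
probability P(X >= k) is computed, where k is the query/term overlap, against
the annotated-gene background (the union of all term gene sets by default,
mirroring an "only annotated genes" statistical domain scope).  Raw p-values
are corrected across tested terms with Benjamini-Hochberg; terms with no
query overlap are not tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .gene_sets import canonical_symbol

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Term:
    term_id: str
    name: str
    genes: frozenset


@dataclass(frozen=True)
class AnnotationDatabase:
    terms: dict            # term_id -> Term
    background: frozenset  # annotated-gene universe

    def __post_init__(self) -> None:
        for term in self.terms.values():
            if not term.genes:
                raise ValueError(f"term {term.term_id} has no genes")


@dataclass(frozen=True)
class EnrichmentRow:
    term_id: str
    term_name: str
    query_size: int
    term_size: int
    background_size: int
    overlap: int
    overlap_genes: frozenset
    p_raw: float
    p_adjusted: float
    significant: bool


def read_gmt(path) -> AnnotationDatabase:
    """Read a GMT file (term, description, member genes...).

    Rows with fewer than three fields are skipped with a warning; duplicate
    genes within a term collapse; a file yielding no terms is an error.
    """
    terms = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            log.warning("%s: line %d has fewer than 3 fields, skipped", path, lineno)
            continue
        term_id, name = fields[0].strip(), fields[1].strip()
        genes = frozenset(canonical_symbol(g) for g in fields[2:] if g.strip())
        if not genes:
            log.warning("%s: line %d lists no genes, skipped", path, lineno)
            continue
        terms[term_id] = Term(term_id=term_id, name=name, genes=genes)
    if not terms:
        raise ValueError(f"{path}: no annotation terms found")
    background = frozenset().union(*(t.genes for t in terms.values()))
    return AnnotationDatabase(terms=terms, background=background)


def write_gmt(db: AnnotationDatabase, path) -> None:
    lines = [
        "\t".join([t.term_id, t.name, *sorted(t.genes)])
        for t in (db.terms[tid] for tid in sorted(db.terms))
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def hypergeometric_p(overlap: int, query: int, term: int, background: int) -> float:
    """Upper-tail P(X >= overlap) with X ~ Hypergeometric(background, term, query)."""
    if not (0 <= overlap <= min(query, term) and query <= background and term <= background):
        raise ValueError(
            f"invalid hypergeometric arguments: k={overlap}, n={query}, "
            f"K={term}, N={background}"
        )
    return float(stats.hypergeom.sf(overlap - 1, background, term, query))


def enrich(
    query: Iterable[str],
    db: AnnotationDatabase,
    alpha: float = 0.05,
    correction: str = "BH",
    background: Iterable[str] = None,
) -> list:
    """Hypergeometric over-representation of ``query`` in every overlapping term.

    The query is intersected with the background before testing; only terms
    with at least one query gene are tested and corrected.  ``background``
    overrides the database's annotated-gene universe (term gene sets are then
    clipped to it).  Rows come back sorted by adjusted then raw p-value.
    """
    if correction != "BH":
        raise ValueError(f"unsupported correction {correction!r}")
    bg = frozenset(canonical_symbol(g) for g in background) if background is not None else db.background
    q = {canonical_symbol(g) for g in query} & bg
    if not q:
        log.warning("query is empty after intersection with the background")
        return []
    tested = []
    for term_id in sorted(db.terms):
        term = db.terms[term_id]
        term_genes = term.genes & bg
        hits = q & term_genes
        if not hits or not term_genes:
            continue
        p = hypergeometric_p(len(hits), len(q), len(term_genes), len(bg))
        tested.append((term, term_genes, hits, p))
    if not tested:
        return []
    _, p_adj, _, _ = multipletests([t[3] for t in tested], method="fdr_bh")
    rows = [
        EnrichmentRow(
            term_id=term.term_id,
            term_name=term.name,
            query_size=len(q),
            term_size=len(term_genes),
            background_size=len(bg),
            overlap=len(hits),
            overlap_genes=frozenset(hits),
            p_raw=p,
            p_adjusted=float(adj),
            significant=bool(adj <= alpha),
        )
        for (term, term_genes, hits, p), adj in zip(tested, p_adj)
    ]
    rows.sort(key=lambda r: (r.p_adjusted, r.p_raw, r.term_id))
    return rows


def rows_to_frame(rows: Iterable[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "query_size": r.query_size,
                "term_size": r.term_size,
                "background_size": r.background_size,
                "overlap": r.overlap,
                "overlap_genes": ",".join(sorted(r.overlap_genes)),
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
            }
            for r in rows
        ]
    )
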