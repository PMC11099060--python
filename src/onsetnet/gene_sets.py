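"""Curation of onset-associated gene lists.

Muscular-dystrophy genes are grouped by the distribution of initial muscle
weakness of the dystrophies they cause: genes mutated only in distal-onset
disease, only in proximal-onset disease, or in both.  Candidate gene lists
(one per onset) are first filtered against evidence-level classifications of
gene-disease assertions (GenCC-style), keeping genes with at least one
Moderate, Strong or Definitive assertion for the matching onset, plus an
explicit whitelist of genes retained on literature support.  The two filtered
lists are then split into three pairwise-disjoint onset groups by set algebra.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd

log = logging.getLogger(__name__)

ONSETS = ("distal", "proximal")

#: Closed vocabulary of gene-disease evidence classifications.
EVIDENCE_LEVELS = frozenset(
    {"definitive", "strong", "moderate", "limited", "disputed", "refuted", "other"}
)

#: Classifications that qualify a candidate gene for retention.
QUALIFYING_LEVELS = frozenset({"definitive", "strong", "moderate"})


def canonical_symbol(raw: str) -> str:
    """Canonicalize a gene symbol: trimmed, uppercase, no internal whitespace.

    No alias or HGNC resolution is attempted; inputs are expected to carry
    final symbols already.
    """
    symbol = str(raw).strip().upper()
    if not symbol:
        raise ValueError("empty gene symbol")
    if any(ch.isspace() for ch in symbol):
        raise ValueError(f"gene symbol contains whitespace: {raw!r}")
    return symbol


@dataclass(frozen=True)
class EvidenceRecord:
    """One gene-disease assertion: gene, disease onset, evidence classification."""

    gene: str
    onset: str
    classification: str

    @classmethod
    def parse(cls, gene: str, onset: str, classification: str) -> "EvidenceRecord":
        onset_norm = str(onset).strip().lower()
        if onset_norm not in ONSETS:
            raise ValueError(f"unknown onset {onset!r}; expected one of {ONSETS}")
        cls_norm = str(classification).strip().lower()
        if cls_norm not in EVIDENCE_LEVELS:
            raise ValueError(f"unknown evidence classification {classification!r}")
        return cls(gene=canonical_symbol(gene), onset=onset_norm, classification=cls_norm)


@dataclass(frozen=True)
class OnsetGroups:
    """The three pairwise-disjoint onset groups.

    ``dogs``: distal-only genes; ``pogs``: proximal-only genes; ``cogs``:
    genes associated with both onsets ("common" genes).
    """

    dogs: frozenset
    pogs: frozenset
    cogs: frozenset

    def __post_init__(self) -> None:
        if self.dogs & self.pogs or self.dogs & self.cogs or self.pogs & self.cogs:
            raise ValueError("onset groups must be pairwise disjoint")

    @property
    def all_genes(self) -> frozenset:
        return self.dogs | self.pogs | self.cogs

    def as_dict(self) -> dict:
        return {"DoGs": set(self.dogs), "PoGs": set(self.pogs), "CoGs": set(self.cogs)}

    def labels(self) -> dict:
        """Map gene symbol -> group label."""
        out = {}
        for label, genes in self.as_dict().items():
            for g in genes:
                out[g] = label
        return out


def filter_by_evidence(
    candidates: Iterable[str],
    onset: str,
    records: Iterable[EvidenceRecord],
    whitelist: Iterable[str] = (),
) -> set:
    """Retain candidates with a qualifying assertion for ``onset``, or whitelisted.

    A candidate is kept if at least one record matches it with the same onset
    and a Moderate/Strong/Definitive classification ("any qualifying record
    suffices"; conflicting assertions for the same gene are not reconciled).
    The result is always a subset of ``candidates``.  Idempotent.
    """
    if onset not in ONSETS:
        raise ValueError(f"unknown onset {onset!r}; expected one of {ONSETS}")
    cands = {canonical_symbol(c) for c in candidates}
    wl = {canonical_symbol(w) for w in whitelist}
    qualifying = {
        r.gene
        for r in records
        if r.onset == onset and r.classification in QUALIFYING_LEVELS
    }
    return {c for c in cands if c in qualifying or c in wl}


def assign_onset_groups(distal: Iterable[str], proximal: Iterable[str]) -> OnsetGroups:
    """Split the two onset lists into distal-only, proximal-only and common genes."""
    d = frozenset(canonical_symbol(g) for g in distal)
    p = frozenset(canonical_symbol(g) for g in proximal)
    return OnsetGroups(dogs=d - p, pogs=p - d, cogs=d & p)


# ---------------------------------------------------------------------------
# I/O

def read_gene_list(path) -> list:
    """Read a gene list (one symbol per line, first TSV column, '#' comments)."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        genes.append(canonical_symbol(line.split("\t")[0]))
    return genes


def read_evidence_table(path) -> list:
    """Read a TSV of evidence records (columns: gene, onset, classification).

    Rows with a malformed classification or onset are rejected with a warning
    rather than aborting the read.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    expected = {"gene", "onset", "classification"}
    missing = expected - set(df.columns)
    if missing:
        raise ValueError(f"evidence table {path} lacks columns: {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(EvidenceRecord.parse(row["gene"], row["onset"], row["classification"]))
        except ValueError as exc:
            log.warning("rejected evidence row %d of %s: %s", idx, path, exc)
    return records


def write_groups_tsv(groups: OnsetGroups, path) -> None:
    rows = [(g, label) for label, genes in groups.as_dict().items() for g in sorted(genes)]
    pd.DataFrame(rows, columns=["gene", "group"]).to_csv(path, sep="\t", index=False)


def write_groups_json(groups: OnsetGroups, path) -> None:
    payload = {label: sorted(genes) for label, genes in groups.as_dict().items()}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


#: Genes retained on extensive literature support despite lacking a
#: qualifying database classification at curation time.
LITERATURE_WHITELIST = frozenset({"CRYAB", "MATR3", "MYOT"})


def load_md_gene_lists() -> tuple:
    """Packaged curated distal/proximal muscular-dystrophy gene lists."""
    data = resources.files("onsetnet") / "data"
    distal = read_gene_list(data / "distal_md_genes.txt")
    proximal = read_gene_list(data / "proximal_md_genes.txt")
    return distal, proximal


def load_md_onset_groups() -> OnsetGroups:
    """Onset groups of the packaged 40 muscular-dystrophy genes (11/22/7)."""
    distal, proximal = load_md_gene_lists()
    return assign_onset_groups(distal, proximal)
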