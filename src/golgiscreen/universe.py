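"""Assembly of the Golgi-associated gene universe.

The universe is the union of two user-supplied lists: genes pulled from a
flat annotation table by term query (standing in for a Gene Ontology
"Golgi organization" search) and a curated list of known regulators from
the literature. Each member carries a provenance tag recording which
source(s) contributed it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd


class InvalidSymbolError(ValueError):
    """Raised for empty or whitespace-only gene symbols."""


def normalize_symbol(raw: str) -> str:
    """Normalize a raw gene symbol to an uppercase, trimmed HGNC-style token.

    Raises :class:`InvalidSymbolError` if the input is empty after trimming.
    """
    token = raw.strip()
    if not token:
        raise InvalidSymbolError(f"empty gene symbol: {raw!r}")
    token = token.upper()
    if any(c.isspace() for c in token):
        raise InvalidSymbolError(f"gene symbol contains internal whitespace: {raw!r}")
    return token


@dataclass(frozen=True)
class GeneUniverse:
    """Set of Golgi-associated gene symbols with per-gene source provenance.

    ``provenance`` maps each gene to ``"annotation"``, ``"curated"`` or
    ``"both"``; its key set equals ``genes``.
    """

    genes: frozenset[str]
    provenance: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.provenance) != set(self.genes):
            raise ValueError("provenance keys must equal the gene set")

    def __contains__(self, gene: str) -> bool:
        return gene in self.genes

    def __len__(self) -> int:
        return len(self.genes)


def select_by_terms(tab: pd.DataFrame, terms: Iterable[str]) -> set[str]:
    """Select distinct genes annotated with at least one query term.

    ``tab`` has columns ``gene`` and ``term``. Matching is exact on the
    case-folded term label/identifier; no ontology traversal.
    """
    query = {str(t).strip().casefold() for t in terms}
    if not query:
        raise ValueError("term query must be non-empty")
    if tab.empty:
        return set()
    hit = tab["term"].astype(str).str.strip().str.casefold().isin(query)
    return {normalize_symbol(g) for g in tab.loc[hit, "gene"]}


def build_universe(annotation_genes: Iterable[str], curated: Iterable[str]) -> GeneUniverse:
    """Union the annotation-derived and curated gene sets with provenance tags."""
    ann = {normalize_symbol(g) for g in annotation_genes}
    cur = {normalize_symbol(g) for g in curated}
    provenance = {}
    for g in ann | cur:
        if g in ann and g in cur:
            provenance[g] = "both"
        elif g in ann:
            provenance[g] = "annotation"
        else:
            provenance[g] = "curated"
    return GeneUniverse(genes=frozenset(ann | cur), provenance=provenance)
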