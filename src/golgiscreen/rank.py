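"""Combined scoring, candidate selection, ranking, and cross-cancer intersection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from golgiscreen.screen import DEGTable

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 3


@dataclass(frozen=True)
class CandidateRecord:
    gene: str
    fc: float
    direction: str
    score1: int
    score2: int
    rank: int

    @property
    def combined(self) -> int:
        return self.score1 + self.score2


@dataclass(frozen=True)
class CandidateReport:
    """Per-cancer-type candidate lists, their intersection, and the parameters used."""

    candidates: Mapping[str, tuple[CandidateRecord, ...]]
    common_genes: frozenset[str]
    parameters: Mapping[str, object] = field(default_factory=dict)


def combine_and_select(
    degs: DEGTable,
    scores1: Mapping[str, int],
    scores2: Mapping[str, int],
    cutoff: int = DEFAULT_CUTOFF,
) -> list[CandidateRecord]:
    """Select passed DEGs whose combined score meets the cutoff and rank them.

    Missing score entries are treated as 0 with a logged warning, so a
    partially curated evidence table still runs. Ordering: combined score
    descending, then fold change descending, then symbol ascending; ranks
    are assigned 1..N in that order.
    """
    rows = []
    for rec in degs.passed:
        if rec.gene not in scores1:
            logger.warning("no literature score for %s; treating as 0", rec.gene)
        if rec.gene not in scores2:
            logger.warning("no interactor score for %s; treating as 0", rec.gene)
        s1 = int(scores1.get(rec.gene, 0))
        s2 = int(scores2.get(rec.gene, 0))
        if s1 + s2 >= cutoff:
            rows.append((rec, s1, s2))
    rows.sort(key=lambda r: (-(r[1] + r[2]), -r[0].fc, r[0].gene))
    return [
        CandidateRecord(
            gene=rec.gene, fc=rec.fc, direction=rec.direction, score1=s1, score2=s2, rank=i
        )
        for i, (rec, s1, s2) in enumerate(rows, start=1)
    ]


def intersect_candidates(
    list_a: Iterable[CandidateRecord | str], list_b: Iterable[CandidateRecord | str]
) -> set[str]:
    """Gene symbols common to two candidate lists (symmetric set intersection)."""

    def genes(lst: Iterable[CandidateRecord | str]) -> set[str]:
        return {c if isinstance(c, str) else c.gene for c in lst}

    return genes(list_a) & genes(list_b)


def top_n(candidates: Sequence[CandidateRecord], n: int) -> list[CandidateRecord]:
    """First ``n`` candidates in rank order (all of them if fewer than ``n``)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(candidates, key=lambda c: c.rank)
    return list(ordered[:n])
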