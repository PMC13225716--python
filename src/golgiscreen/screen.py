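"""Fold-change screening of a cell-line pair with an adaptive top-N cap.

Per gene, the screen computes the symmetric fold change (max/min of the two
RPKM values) between the organized-Golgi and disorganized-Golgi line of a
cancer-type pair. Genes at or above a base threshold pass; if more pass
than the cap allows (default 50), the effective threshold is tightened to
keep only the cap highest-fold-change genes. The symmetric ratio is used
because a regulator may be higher in either line of a pair; direction is
retained as metadata and feeds the concordance scoring later.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from golgiscreen.universe import GeneUniverse

HIGHER_IN_ORGANIZED = "higher_in_organized"
HIGHER_IN_DISORGANIZED = "higher_in_disorganized"
EQUAL = "equal"

# relative tolerance for calling the two RPKM values equal
_EQUAL_RTOL = 1e-9


class UndefinedRatioError(ValueError):
    """Both values zero with a zero pseudocount: the ratio is undefined."""


@dataclass(frozen=True)
class CellLinePair:
    """One cancer type's organized/disorganized cell-line pair and its screen settings."""

    cancer_type: str
    organized_line: str
    disorganized_line: str
    base_threshold: float
    cap: int = 50

    def __post_init__(self) -> None:
        if self.organized_line == self.disorganized_line:
            raise ValueError("organized and disorganized lines must differ")
        if self.base_threshold < 1:
            raise ValueError("base_threshold must be >= 1")
        if self.cap < 1:
            raise ValueError("cap must be >= 1")


@dataclass(frozen=True)
class DEGRecord:
    gene: str
    fc: float
    direction: str
    passed: bool


@dataclass(frozen=True)
class DEGTable:
    """Screen result: records sorted by fold change descending, then symbol."""

    pair: CellLinePair
    records: tuple[DEGRecord, ...]
    effective_threshold: float

    @property
    def passed(self) -> tuple[DEGRecord, ...]:
        return tuple(r for r in self.records if r.passed)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": [r.gene for r in self.records],
                "fc": [r.fc for r in self.records],
                "direction": [r.direction for r in self.records],
                "passed": [r.passed for r in self.records],
            }
        )


def fold_change(a: float, b: float, pseudocount: float = 0.01) -> tuple[float, str]:
    """Symmetric fold change between two RPKM values.

    Returns ``(fc, direction)`` with ``fc >= 1`` and direction one of
    ``"first"``, ``"second"``, ``"equal"``. When the smaller value is zero the
    ratio is stabilized as ``(max + pseudocount) / pseudocount``; nonzero
    ratios are left exact.
    """
    if a < 0 or b < 0:
        raise ValueError("RPKM values must be nonnegative")
    hi, lo = (a, b) if a >= b else (b, a)
    if hi == 0 and lo == 0:
        if pseudocount <= 0:
            raise UndefinedRatioError("both values zero with zero pseudocount")
        return 1.0, "equal"
    if math.isclose(a, b, rel_tol=_EQUAL_RTOL, abs_tol=0.0):
        return 1.0, "equal"
    if lo > 0:
        fc = hi / lo
    else:
        if pseudocount <= 0:
            raise UndefinedRatioError("min value zero with zero pseudocount")
        fc = (hi + pseudocount) / pseudocount
    direction = "first" if a > b else "second"
    return fc, direction


def screen_degs(
    expr: pd.DataFrame,
    universe: GeneUniverse,
    pair: CellLinePair,
    pseudocount: float = 0.01,
) -> DEGTable:
    """Screen the universe genes of an expression matrix for DEGs in one pair.

    ``expr`` is a genes x cell-lines DataFrame (index: gene symbols). The
    candidate set is the intersection of the universe with the matrix rows.
    A gene passes when its symmetric fold change between the pair's two
    lines meets ``pair.base_threshold``; if more than ``pair.cap`` genes
    pass, the effective threshold is raised so that exactly the cap
    highest-fold-change genes remain (boundary ties broken by ascending
    symbol).
    """
    for line in (pair.organized_line, pair.disorganized_line):
        if line not in expr.columns:
            raise KeyError(f"cell line {line!r} not found in expression matrix")

    candidates = sorted(set(universe.genes) & set(expr.index))
    rows: list[tuple[str, float, str]] = []
    for gene in candidates:
        a = float(expr.at[gene, pair.organized_line])
        b = float(expr.at[gene, pair.disorganized_line])
        fc, d = fold_change(a, b, pseudocount)
        direction = {"first": HIGHER_IN_ORGANIZED, "second": HIGHER_IN_DISORGANIZED, "equal": EQUAL}[d]
        rows.append((gene, fc, direction))

    # fc descending, symbol ascending — deterministic
    rows.sort(key=lambda r: (-r[1], r[0]))

    passed_mask = [fc >= pair.base_threshold for _, fc, _ in rows]
    effective = float(pair.base_threshold)
    n_passed = sum(passed_mask)
    if n_passed > pair.cap:
        # keep the cap best under the sort order; raise the effective threshold
        keep = {rows[i][0] for i in range(pair.cap)}
        effective = rows[pair.cap - 1][1]
        passed_mask = [gene in keep for gene, _, _ in rows]

    records = tuple(
        DEGRecord(gene=g, fc=fc, direction=d, passed=p)
        for (g, fc, d), p in zip(rows, passed_mask)
    )
    return DEGTable(pair=pair, records=records, effective_threshold=effective)
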