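import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from golgiscreen.screen import (
    EQUAL,
    HIGHER_IN_DISORGANIZED,
    HIGHER_IN_ORGANIZED,
    CellLinePair,
    UndefinedRatioError,
    fold_change,
    screen_degs,
)
from golgiscreen.universe import build_universe

PAIR = CellLinePair(
    cancer_type="test", organized_line="ORG", disorganized_line="DIS", base_threshold=5.0, cap=50
)


def make_expr(values: dict[str, tuple[float, float]]) -> pd.DataFrame:
    return pd.DataFrame(
        {"ORG": [v[0] for v in values.values()], "DIS": [v[1] for v in values.values()]},
        index=list(values),
    )


class TestFoldChange:
    def test_exact_ratio_pseudocount_unused_when_min_positive(self):
        assert fold_change(30, 3, pseudocount=0.01) == (10.0, "first")

    def test_identical_values_are_equal(self):
        assert fold_change(7, 7) == (1.0, "equal")

    def test_zero_min_stabilized_by_pseudocount(self):
        # (5 + 0.01) / 0.01 = 501
        fc, d = fold_change(5, 0, pseudocount=0.01)
        assert fc == pytest.approx(501.0)
        assert d == "first"

    def test_both_zero_with_zero_pseudocount_is_undefined(self):
        with pytest.raises(UndefinedRatioError):
            fold_change(0, 0, pseudocount=0.0)

    def test_both_zero_with_pseudocount_is_equal(self):
        assert fold_change(0, 0, pseudocount=0.01) == (1.0, "equal")

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            fold_change(-1, 2)

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.floats(min_value=0, max_value=1e6, allow_nan=False),
        b=st.floats(min_value=0, max_value=1e6, allow_nan=False),
    )
    def test_symmetry_and_bounds(self, a, b):
        fc1, d1 = fold_change(a, b, pseudocount=0.01)
        fc2, d2 = fold_change(b, a, pseudocount=0.01)
        assert fc1 == fc2 >= 1.0
        if d1 == "equal":
            assert d2 == "equal"
        else:
            assert {d1, d2} == {"first", "second"}


class TestScreenDegs:
    def test_toy_universe_threshold_filter(self):
        # fc values {12, 8, 5, 4.9, 2, 1}; threshold 5 keeps the first three
        expr = make_expr(
            {"A": (12, 1), "B": (1, 8), "C": (5, 1), "D": (4.9, 1), "E": (2, 1), "F": (3, 3)}
        )
        uni = build_universe(set(expr.index), set())
        table = screen_degs(expr, uni, PAIR)
        assert {r.gene for r in table.passed} == {"A", "B", "C"}
        assert [r.gene for r in table.records[:3]] == ["A", "B", "C"]  # fc desc
        assert table.effective_threshold == 5.0

    def test_direction_metadata(self):
        expr = make_expr({"A": (12, 1), "B": (1, 8), "F": (3, 3)})
        uni = build_universe(set(expr.index), set())
        by_gene = {r.gene: r for r in screen_degs(expr, uni, PAIR).records}
        assert by_gene["A"].direction == HIGHER_IN_ORGANIZED
        assert by_gene["B"].direction == HIGHER_IN_DISORGANIZED
        assert by_gene["F"].direction == EQUAL

    def test_cap_tightens_effective_threshold(self):
        # 120 genes above base threshold, cap 50 -> exactly 50 pass
        genes = {f"G{i:03d}": (float(6 + i), 1.0) for i in range(120)}
        expr = make_expr(genes)
        uni = build_universe(set(expr.index), set())
        table = screen_degs(expr, uni, PAIR)
        assert len(table.passed) == PAIR.cap == 50
        assert all(r.fc >= table.effective_threshold for r in table.passed)
        assert table.effective_threshold >= PAIR.base_threshold
        # the kept genes are exactly the top 50 by fold change
        top = sorted(genes, key=lambda g: -genes[g][0])[:50]
        assert {r.gene for r in table.passed} == set(top)

    def test_boundary_ties_at_cap_broken_by_symbol(self):
        pair = CellLinePair("t", "ORG", "DIS", base_threshold=2.0, cap=2)
        expr = make_expr({"B": (6, 1), "C": (6, 1), "A": (8, 1)})
        uni = build_universe(set(expr.index), set())
        table = screen_degs(expr, uni, pair)
        assert [r.gene for r in table.passed] == ["A", "B"]

    def test_universe_disjoint_from_matrix_gives_empty_table(self):
        expr = make_expr({"A": (12, 1)})
        uni = build_universe({"ZZZ"}, set())
        assert screen_degs(expr, uni, PAIR).records == ()

    def test_missing_cell_line_is_configuration_error(self):
        expr = make_expr({"A": (12, 1)}).rename(columns={"DIS": "OTHER"})
        uni = build_universe({"A"}, set())
        with pytest.raises(KeyError):
            screen_degs(expr, uni, PAIR)

    def test_row_order_invariance_and_line_swap_symmetry(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i}" for i in range(30)]
        expr = pd.DataFrame(rng.lognormal(1, 1, size=(30, 2)), index=genes, columns=["ORG", "DIS"])
        uni = build_universe(set(genes), set())
        shuffled = expr.sample(frac=1, random_state=0)
        t1 = screen_degs(expr, uni, PAIR)
        t2 = screen_degs(shuffled, uni, PAIR)
        assert t1.records == t2.records

        swapped = CellLinePair("test", "DIS", "ORG", base_threshold=5.0, cap=50)
        t3 = screen_degs(expr, uni, swapped)
        fc1 = {r.gene: (r.fc, r.direction) for r in t1.records}
        for r in t3.records:
            fc, d = fc1[r.gene]
            assert r.fc == fc
            flip = {HIGHER_IN_ORGANIZED: HIGHER_IN_DISORGANIZED, HIGHER_IN_DISORGANIZED: HIGHER_IN_ORGANIZED, EQUAL: EQUAL}
            assert r.direction == flip[d]

    @pytest.mark.parametrize("thr_lo,thr_hi", [(2.0, 5.0), (5.0, 10.0)])
    def test_raising_threshold_never_adds_genes(self, thr_lo, thr_hi):
        rng = np.random.default_rng(11)
        genes = [f"G{i}" for i in range(40)]
        expr = pd.DataFrame(rng.lognormal(1, 1.5, size=(40, 2)), index=genes, columns=["ORG", "DIS"])
        uni = build_universe(set(genes), set())
        lo = screen_degs(expr, uni, CellLinePair("t", "ORG", "DIS", base_threshold=thr_lo))
        hi = screen_degs(expr, uni, CellLinePair("t", "ORG", "DIS", base_threshold=thr_hi))
        assert {r.gene for r in hi.passed} <= {r.gene for r in lo.passed}
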