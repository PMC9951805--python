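"""Dietary niche statistics: worked examples, invariants, brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from civetniche.core_io import CompositionTable, DataError
from civetniche.diet_metrics import (
    ProportionVector,
    diet_report,
    evenness,
    levins_breadth,
    pianka_overlap,
    relative_frequency,
    richness,
    shannon_diversity,
    species_metrics,
    standardized_breadth,
)

counts_strategy = st.lists(st.integers(0, 10), min_size=2, max_size=6).filter(
    lambda c: sum(c) > 0
)


def series(counts):
    return pd.Series(counts, index=[f"item{i}" for i in range(len(counts))])


class TestRelativeFrequency:
    def test_single_item_is_100_percent(self):
        pv = relative_frequency(series([7]))
        assert pv.rfo.iloc[0] == pytest.approx(100.0)

    def test_equal_counts_split_evenly(self):
        pv = relative_frequency(series([2, 2]))
        assert list(pv.rfo) == pytest.approx([50.0, 50.0])

    def test_all_zero_column_errors(self):
        with pytest.raises(DataError):
            relative_frequency(series([0, 0]))


@pytest.mark.parametrize(
    "p, expected_L",
    [
        ([0.2] * 5, 5.0),  # uniform -> L = n
        ([1.0], 1.0),  # degenerate -> L = 1
        ([0.5, 0.25, 0.25], 1 / 0.375),  # direct evaluation: 2.666...
    ],
)
def test_levins_breadth_examples(p, expected_L):
    assert levins_breadth(np.array(p)) == pytest.approx(expected_L, abs=1e-12)


@pytest.mark.parametrize(
    "L, n, expected",
    [(3.0, 3, 1.0), (1.0, 7, 0.0), (1 / 0.375, 3, (1 / 0.375 - 1) / 2)],
)
def test_standardized_breadth_examples(L, n, expected):
    assert standardized_breadth(L, n) == pytest.approx(expected, abs=1e-12)
    # the derived case evaluates to 0.8333 at 4 d.p.
    assert round(standardized_breadth(1 / 0.375, 3), 4) == 0.8333


def test_standardized_breadth_needs_two_items():
    with pytest.raises(DataError):
        standardized_breadth(1.0, 1)


@pytest.mark.parametrize(
    "p, expected_H",
    [([1.0], 0.0), ([0.25] * 4, np.log(4))],
)
def test_shannon_examples(p, expected_H):
    assert shannon_diversity(np.array(p)) == pytest.approx(expected_H, abs=1e-12)


def test_evenness_closed_forms():
    assert evenness(np.log(6), 6) == pytest.approx(1.0)
    assert evenness(1.0, 9) == pytest.approx(1.0 / np.log(9), abs=1e-12)
    with pytest.raises(DataError):
        evenness(0.0, 1)


def test_richness_counts_used_categories():
    assert richness(series([0, 0, 3])) == 1
    assert richness(series([1, 2, 3])) == 3


class TestPianka:
    def test_identical_vectors_give_one(self):
        p = series([3, 1, 6])
        assert pianka_overlap(p, p) == pytest.approx(1.0)

    def test_disjoint_supports_give_zero(self):
        assert pianka_overlap(series([1, 0]), series([0, 1])) == pytest.approx(0.0)

    def test_label_alignment_over_union(self):
        a = pd.Series({"pear": 2, "gerbil": 1})
        b = pd.Series({"pear": 2, "chicken": 5})
        # union universe: chicken 0 for a, gerbil 0 for b
        expected = 4 / np.sqrt(5 * 29)
        assert pianka_overlap(a, b) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_vector_errors(self):
        with pytest.raises(DataError):
            pianka_overlap(series([0, 0]), series([1, 1]))

    @given(a=counts_strategy, b=counts_strategy, scale=st.integers(1, 50))
    @settings(max_examples=150, deadline=None)
    def test_bounds_symmetry_scale_invariance(self, a, b, scale):
        n = max(len(a), len(b))
        a = a + [0] * (n - len(a))
        b = b + [0] * (n - len(b))
        u, v = np.array(a, float), np.array(b, float)
        o = pianka_overlap(u, v)
        assert -1e-12 <= o <= 1 + 1e-12
        assert o == pytest.approx(pianka_overlap(v, u), abs=1e-12)
        assert o == pytest.approx(pianka_overlap(u * scale, v), abs=1e-12)
        # equality with 1 iff proportional
        if abs(o - 1) < 1e-12:
            ratios = {u[i] / v[i] for i in range(n) if v[i] > 0}
            assert len(ratios) == 1 and not any(v[i] == 0 and u[i] > 0 for i in range(n))
        assert pianka_overlap(u, u * scale) == pytest.approx(1.0, abs=1e-12)


@given(counts=counts_strategy)
@settings(max_examples=150, deadline=None)
def test_metrics_match_bruteforce_formula_evaluation(counts):
    """Independent direct evaluation of the printed formulas, term by term."""
    fo = series(counts)
    used = [c for c in counts if c > 0]
    total = sum(used)
    p = [c / total for c in used]
    L_direct = 1.0 / sum(pi * pi for pi in p)
    H_direct = -sum(pi * np.log(pi) for pi in p)
    S_direct = len(used)

    m = species_metrics(fo)
    assert m.L == pytest.approx(L_direct, abs=1e-12)
    assert m.H == pytest.approx(H_direct, abs=1e-12)
    assert m.S == S_direct
    if S_direct >= 2:
        assert m.Lst == pytest.approx((L_direct - 1) / (S_direct - 1), abs=1e-12)
        assert m.E == pytest.approx(H_direct / np.log(S_direct), abs=1e-12)
        assert 0 <= m.Lst <= 1
        assert m.E <= 1 + 1e-12
    assert 1 - 1e-12 <= m.L <= m.S + 1e-12
    assert m.H <= np.log(max(S_direct, 1)) + 1e-12


class TestDietReport:
    def _table(self, fo_a, fo_b, groups=None):
        items = [f"i{k}" for k in range(len(fo_a))]
        df = pd.DataFrame(
            {
                "item": items,
                "group": groups or ["plant"] * len(items),
                "fo_a": fo_a,
                "fo_b": fo_b,
            }
        )
        return CompositionTable(df)

    def test_duplicated_species_column_overlaps_fully(self):
        report = diet_report(self._table([3, 1, 4], [3, 1, 4]))
        assert report["overlap"]["a|b"] == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        t1 = self._table([3, 1, 4], [1, 1, 2])
        t2 = CompositionTable(t1.df.iloc[::-1])
        r1, r2 = diet_report(t1), diet_report(t2)
        assert r1["species"] == r2["species"]
        assert r1["overlap"] == pytest.approx(r2["overlap"])

    def test_zero_padding_leaves_metrics_unchanged(self):
        base = diet_report(self._table([3, 1, 4], [1, 1, 2]))
        padded = diet_report(self._table([3, 1, 4, 0], [1, 1, 2, 0]))
        assert base["species"] == padded["species"]
        assert base["overlap"]["a|b"] == pytest.approx(padded["overlap"]["a|b"])

    def test_subtotals_derived_from_rows(self):
        report = diet_report(
            self._table([3, 1, 4], [1, 1, 2], groups=["plant", "plant", "wild animal"])
        )
        assert report["subtotals"]["a"]["plant"] == pytest.approx(100 * 4 / 8)
        assert report["subtotals"]["a"]["wild animal"] == pytest.approx(50.0)

    def test_exclude_nonfood_drops_other_group(self):
        report = diet_report(
            self._table([3, 1, 4], [1, 1, 2], groups=["plant", "other", "wild animal"]),
            exclude_nonfood=True,
        )
        assert report["species"]["a"]["S"] == 2
        assert "other" not in report["subtotals"]["a"]

    def test_single_species_rejected(self):
        df = pd.DataFrame({"item": ["x"], "group": ["plant"], "fo_a": [1]})
        with pytest.raises(DataError):
            diet_report(CompositionTable(df))


def test_proportion_vector_invariants():
    with pytest.raises(DataError):
        ProportionVector(labels=("a", "b"), p=np.array([0.6, 0.6]))
    with pytest.raises(DataError):
        ProportionVector(labels=("a",), p=np.array([-0.2]))
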