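"""Spearman statistic, per-cancer screen and top-K list construction."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from mutcorr import (CancerType, CohortSpec, ExpressionMatrix, PlantedGene,
                     compute_loads, screen_cancer, simulate_cohort, spearman,
                     top_k)


def oracle_rho(x, y):
    """Independent oracle: explicit average ranks then the Pearson formula."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def oracle_exact_p(x, y):
    """Brute-force two-sided permutation p over all n! orderings."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    n_ge = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        n_ge += abs(r) >= obs - 1e-12
        total += 1
    return n_ge / total


class TestSpearman:
    def test_monotone_pairs(self):
        assert spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50]).rho == 1.0
        assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]).rho == -1.0

    def test_no_ties_closed_form(self):
        # sum of squared rank differences = 6 => 1 - 6*6/(6*35)
        r = spearman([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5])
        assert r.rho == pytest.approx(1 - 36 / 210, abs=1e-15)

    def test_ties_equal_pearson_on_average_ranks(self):
        x, y = [1, 1, 2, 3], [3, 4, 5, 5]
        assert spearman(x, y).rho == pytest.approx(oracle_rho(x, y), abs=1e-15)

    def test_matches_scipy_spearmanr(self, rng):
        for _ in range(50):
            x = rng.integers(0, 6, size=15).astype(float)
            y = rng.integers(0, 6, size=15).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            ours = spearman(x, y)
            ref = stats.spearmanr(x, y)
            assert ours.rho == pytest.approx(ref.statistic, abs=1e-12)
            # same t-approximation for n > 10
            assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_constant_input_is_explicit_na(self):
        r = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert math.isnan(r.rho) and math.isnan(r.p_value)
        assert "constant" in r.note

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            spearman([1, 2, 3], [1, 2, 3])

    def test_nan_pairs_dropped_then_length_checked(self):
        with pytest.raises(ValueError):
            spearman([1, 2, np.nan, 4], [1, 2, 3, np.nan])
        r = spearman([1, 2, np.nan, 4, 5, 6], [6, 5, 4, 3, 2, 1])
        assert r.n == 5 and r.rho == -1.0

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for n in (5, 6, 7):
            for _ in range(5):
                x = rng.integers(0, 5, size=n).astype(float)
                y = rng.integers(0, 5, size=n).astype(float)
                if len(set(x)) < 2 or len(set(y)) < 2:
                    continue
                ours = spearman(x, y)
                assert ours.method in ("exact", "exact-monotone")
                assert ours.p_value <= oracle_exact_p(x, y) + 1e-12
                if ours.method == "exact":
                    assert ours.p_value == pytest.approx(oracle_exact_p(x, y),
                                                         abs=1e-12)

    def test_perfect_monotone_p_is_permutation_probability(self):
        r = spearman(list(range(1, 9)), list(range(2, 10)))
        assert r.p_value == pytest.approx(2 / math.factorial(8), rel=1e-12)

    @given(st.lists(st.integers(-50, 50), min_size=5, max_size=12,
                    unique=True).map(sorted),
           st.sampled_from([math.exp, lambda v: v ** 3, lambda v: 5 * v - 2]))
    def test_invariant_under_strictly_increasing_transform(self, xs, f):
        y = np.linspace(0, 1, len(xs)) ** 2
        base = spearman(xs, y, p_mode="asymptotic" if len(xs) > 10 else "auto")
        trans = spearman([f(v) for v in xs], y,
                         p_mode="asymptotic" if len(xs) > 10 else "auto")
        assert trans.rho == pytest.approx(base.rho, abs=1e-12)


def _mini_cohort(n=30, n_genes=20, planted=(), seed=11):
    spec = CohortSpec(cancer_types=[CancerType("T", n)], n_genes=n_genes,
                      planted=list(planted), seed=seed)
    mut, expr, _ = simulate_cohort(spec)
    loads = compute_loads(mut["T"], "T", roster=list(expr["T"].samples))
    return expr["T"], loads


class TestScreen:
    def test_monotone_gene_gets_rank_one(self):
        expr, loads = _mini_cohort()
        values = expr.values.copy()
        values.loc["MONO"] = loads.loc[values.columns, "load_all"].to_numpy() * 1.0
        expr2 = ExpressionMatrix(values, is_zscore=True)
        res = screen_cancer(expr2, loads)
        row = res.set_index("gene").loc["MONO"]
        assert row.rho == 1.0 and row.rank_positive == 1

    def test_planted_gene_recovered_at_rank_one(self):
        expr, loads = _mini_cohort(n=300, n_genes=500,
                                   planted=[PlantedGene("HIT", "T", 0.9)],
                                   seed=5)
        res = screen_cancer(expr, loads)
        assert res.set_index("gene").loc["HIT", "rank_positive"] == 1

    def test_sample_column_order_irrelevant(self):
        expr, loads = _mini_cohort(seed=3)
        shuffled = ExpressionMatrix(
            expr.values.sample(frac=1, axis=1, random_state=9),
            is_zscore=True)
        a = screen_cancer(expr, loads)
        b = screen_cancer(shuffled, loads)
        pd.testing.assert_frame_equal(a, b)

    def test_vectorized_rho_matches_scalar_spearman(self):
        expr, loads = _mini_cohort(n=40, n_genes=30, seed=8)
        res = screen_cancer(expr, loads).set_index("gene")
        load_vec = loads.loc[expr.samples, "load_all"].to_numpy(float)
        for g in list(expr.genes)[:10]:
            scalar = spearman(expr.values.loc[g].to_numpy(), load_vec,
                              p_mode="asymptotic")
            assert res.loc[g, "rho"] == pytest.approx(scalar.rho, abs=1e-12)
            assert res.loc[g, "p_value"] == pytest.approx(scalar.p_value,
                                                          rel=1e-9)

    def test_empty_intersection_is_hard_error(self):
        expr, loads = _mini_cohort()
        renamed = ExpressionMatrix(
            expr.values.rename(columns=lambda s: "X" + s), is_zscore=True)
        with pytest.raises(ValueError, match="no shared samples"):
            screen_cancer(renamed, loads)

    def test_min_samples_enforced(self):
        expr, loads = _mini_cohort(n=12)
        with pytest.raises(ValueError, match="min_samples"):
            screen_cancer(expr, loads, min_samples=20)


def _results(rhos, genes=None, ps=None):
    genes = genes or [f"g{i}" for i in range(len(rhos))]
    ps = ps if ps is not None else np.linspace(0.01, 0.5, len(rhos))
    return pd.DataFrame({"gene": genes, "cancer_type": "T", "rho": rhos,
                         "p_value": ps, "n": 50})


class TestTopK:
    def test_top_three_by_rho(self):
        res = _results([0.9, 0.5, 0.4, 0.1, -0.2, -0.6])
        lists = top_k(res, 3)
        assert lists.positive_genes == ["g0", "g1", "g2"]
        assert lists.negative_genes == ["g5", "g4"]

    def test_truncation_when_few_positive(self):
        res = _results([0.3, 0.1, -0.5, -0.4])
        lists = top_k(res, 400)
        assert len(lists.positive_genes) == 2
        assert set(lists.positive_genes).isdisjoint(lists.negative_genes)

    def test_k_must_be_positive(self):
        with pytest.raises(ValueError):
            top_k(_results([0.5]), 0)

    def test_boundary_tie_break_deterministic(self):
        # two genes tied in rho at the K boundary: smaller p wins, then symbol
        res = _results([0.9, 0.5, 0.5, 0.5],
                       genes=["a", "zz", "mm", "bb"],
                       ps=[0.001, 0.02, 0.02, 0.01])
        for perm in itertools.permutations(range(4)):
            shuffled = res.iloc[list(perm)].reset_index(drop=True)
            lists = top_k(shuffled, 2)
            assert lists.positive_genes == ["a", "bb"]
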