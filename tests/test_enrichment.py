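"""Enrichment statistics: size factors, dispersions, the exact NB test
against its binomial oracle, BH adjustment, capping and calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binomtest

import dipseq as d
from dipseq.counting import CountTable, ROW_NAMES
from dipseq.enrichment import (
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    log2_fold_change,
    nb_test,
)
from dipseq.workflows import make_null_count_table


def _table(k, samples_ends, round_labels=None):
    """CountTable from a plain array and ('sample','end') column tuples."""
    k = np.asarray(k)
    idx = pd.MultiIndex.from_arrays(
        [["dna"] * len(k), range(1, len(k) + 1), ["forward"] * len(k), [0] * len(k)],
        names=ROW_NAMES,
    )
    cols = pd.MultiIndex.from_tuples(samples_ends, names=["sample", "end"])
    return CountTable(pd.DataFrame(k, index=idx, columns=cols), round_labels or {})


class TestSizeFactors:
    def test_hand_fixture(self):
        """Columns at exactly half and double the geometric mean."""
        k = np.array([[10, 20], [30, 60], [50, 100]])
        sf = estimate_size_factors(k)
        assert np.allclose(sf, [1 / np.sqrt(2), np.sqrt(2)])

    def test_equal_columns_give_unit_factors(self):
        k = np.array([[5, 5, 5], [9, 9, 9]])
        assert np.allclose(estimate_size_factors(k), 1.0)

    def test_scaling_one_column_scales_its_factor(self):
        rng = np.random.default_rng(3)
        k = rng.poisson(50, size=(400, 3)).astype(float)
        sf = estimate_size_factors(k)
        k2 = k.copy()
        k2[:, 1] *= 4
        sf2 = estimate_size_factors(k2)
        assert np.allclose(sf2[1] / sf[1], 4 * (sf2[0] / sf[0]), rtol=1e-6)

    def test_all_rows_contain_zero_raises_with_hint(self):
        k = np.array([[0, 5], [7, 0]])
        with pytest.raises(ValueError, match="pseudocount"):
            estimate_size_factors(k)
        sf = estimate_size_factors(k, pseudocount=0.5)
        assert np.all(sf > 0)

    def test_matches_pydeseq2(self):
        """Cross-check the median-of-ratios implementation."""
        from pydeseq2.preprocessing import deseq2_norm

        rng = np.random.default_rng(11)
        k = rng.negative_binomial(5, 0.1, size=(300, 4)).astype(float)
        k[k.sum(axis=1) == 0] += 1
        ours = estimate_size_factors(k)
        _, theirs = deseq2_norm(pd.DataFrame(k.T))  # pydeseq2: samples x genes
        assert np.allclose(ours, np.asarray(theirs), rtol=1e-8)


class TestDispersions:
    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(5)
        mu = rng.uniform(50, 500, 800)
        k = rng.poisson(mu[:, None], size=(800, 6)).astype(float)
        sf = estimate_size_factors(k)
        a = estimate_dispersions(k, sf, conditions=["a"] * 3 + ["b"] * 3)
        assert 0 <= np.median(a) <= 0.05

    def test_nb_data_recovers_alpha(self):
        """Median estimate over replicated runs brackets the true alpha 0.5."""
        true_alpha = 0.5
        med = []
        rng = np.random.default_rng(6)
        for _ in range(50):
            mu = rng.uniform(100, 1000, 300)
            r = 1 / true_alpha
            p = r / (r + mu)
            k = rng.negative_binomial(r, p[:, None], size=(300, 6)).astype(float)
            sf = estimate_size_factors(k)
            a = estimate_dispersions(k, sf, conditions=["a"] * 3 + ["b"] * 3)
            med.append(np.median(a))
        assert 0.35 <= np.mean(med) <= 0.65

    def test_constant_rows_get_zero_raw_dispersion(self):
        k = np.full((50, 4), 40.0)
        a = estimate_dispersions(k, np.ones(4), conditions=["a", "a", "b", "b"])
        assert np.allclose(a, 0.0, atol=1e-12)

    def test_unreplicated_conditions_require_pooled_mode(self):
        k = np.array([[10.0, 20.0], [30.0, 10.0]])
        with pytest.raises(ValueError, match="pooled"):
            estimate_dispersions(k, np.ones(2), conditions=["a", "b"])
        a = estimate_dispersions(k, np.ones(2), mode="pooled")
        assert np.all(a >= 0)


class TestNbTest:
    def test_alpha_zero_equals_exact_binomial_up_to_30(self):
        """With no overdispersion and equal size factors the test IS the
        two-sided exact binomial test, to 1e-9, for every split of N <= 30."""
        worst = 0.0
        for N in range(1, 31):
            for a in range(N + 1):
                ours = nb_test(
                    np.array([a]), np.array([N - a]), np.ones(1), np.ones(1), 0.0
                )
                oracle = binomtest(a, N, 0.5).pvalue
                worst = max(worst, abs(ours - oracle))
        assert worst < 1e-9

    def test_known_binomial_value(self):
        # P(two-sided | 2 of 10, p=1/2) = 112/1024
        p = nb_test(np.array([2]), np.array([8]), np.ones(1), np.ones(1), 0.0)
        assert abs(p - 112 / 1024) < 1e-12

    def test_unequal_size_factors_shift_the_null(self):
        """A 2:1 sequencing-depth imbalance makes a 2:1 count split the null
        expectation (p = 1), not evidence of change."""
        p_unbal = nb_test(np.array([40]), np.array([20]), np.array([2.0]), np.array([1.0]), 0.0)
        p_bal = nb_test(np.array([40]), np.array([20]), np.ones(1), np.ones(1), 0.0)
        assert p_unbal > 0.5 > p_bal

    def test_dispersion_inflates_pvalue(self):
        args = (np.array([10, 12]), np.array([40, 38]), np.ones(2), np.ones(2))
        assert nb_test(*args, 0.5) > nb_test(*args, 0.0)

    def test_zero_total_is_p_one(self):
        assert nb_test(np.array([0]), np.array([0]), np.ones(1), np.ones(1), 0.1) == 1.0

    def test_symmetry_in_conditions(self):
        a = nb_test(np.array([7]), np.array([21]), np.ones(1), np.ones(1), 0.2)
        b = nb_test(np.array([21]), np.array([7]), np.ones(1), np.ones(1), 0.2)
        assert abs(a - b) < 1e-12

    @settings(max_examples=50, deadline=None)
    @given(a=st.integers(0, 60), b=st.integers(0, 60), alpha=st.floats(0, 2))
    def test_pvalue_is_a_probability(self, a, b, alpha):
        p = nb_test(np.array([a]), np.array([b]), np.ones(1), np.ones(1), alpha)
        assert 0.0 <= p <= 1.0


class TestLog2FoldChange:
    def test_antisymmetric_without_pseudocount(self):
        args = (np.array([10.0]), np.array([40.0]), np.ones(1), np.ones(1))
        fwd = log2_fold_change(*args, pseudocount=0.0)
        rev = log2_fold_change(np.array([40.0]), np.array([10.0]), np.ones(1), np.ones(1), 0.0)
        assert fwd == 2.0 and rev == -2.0

    def test_zero_counts_nan_without_pseudocount(self):
        v = log2_fold_change(np.array([0.0]), np.array([5.0]), np.ones(1), np.ones(1), 0.0)
        assert np.isnan(v)

    def test_size_factors_normalize(self):
        v = log2_fold_change(
            np.array([20.0]), np.array([20.0]), np.array([2.0]), np.array([0.5]), 0.0
        )
        assert v == 2.0  # 20/0.5 vs 20/2


class TestBhAdjust:
    def test_hand_fixture(self):
        p = [0.01, 0.02, 0.03, 0.04]
        # step-up: p_i * n / rank, enforced monotone from the largest
        assert np.allclose(bh_adjust(p), [0.04, 0.04, 0.04, 0.04])

    def test_single_smallest_survives(self):
        p = [0.001, 0.5, 0.9]
        adj = bh_adjust(p)
        assert np.allclose(adj, [0.003, 0.75, 0.9])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([0.5, np.nan])

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_adjusted_at_least_raw_and_bounded(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0)
        # adjustment preserves the p-value ordering
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestComputeEnrichment:
    def test_cleared_and_appeared_capped(self):
        t = _table(
            [[50, 50, 0, 0], [0, 0, 30, 30], [20, 20, 40, 40]],
            [("ini", "N"), ("ini", "C"), ("fin", "N"), ("fin", "C")],
        )
        res = {r.site[1]: r for r in d.compute_enrichment(t, ["ini"], ["fin"], sf_pseudocount=0.5)}
        assert res[1].cap == "cleared" and res[1].log2fc == -6.0
        assert res[2].cap == "appeared" and res[2].log2fc == 6.0
        assert res[3].cap == "none"

    def test_overlapping_sample_sets_rejected(self):
        t = _table([[1, 1]], [("s1", "N"), ("s1", "C")])
        with pytest.raises(ValueError, match="overlap"):
            d.compute_enrichment(t, ["s1"], ["s1"])

    def test_missing_sample_rejected(self):
        t = _table([[1, 1]], [("s1", "N"), ("s1", "C")])
        with pytest.raises(ValueError, match="not in table"):
            d.compute_enrichment(t, ["s1"], ["nope"])

    def test_all_zero_rows_dropped(self):
        t = _table(
            [[0, 0, 0, 0], [10, 10, 10, 10]],
            [("a", "N"), ("a", "C"), ("b", "N"), ("b", "C")],
        )
        res = d.compute_enrichment(t, ["a"], ["b"], sf_pseudocount=0.5)
        assert [r.site[1] for r in res] == [2]

    def test_strong_true_change_detected_null_rows_not(self):
        rng = np.random.default_rng(8)
        base = rng.poisson(200, size=(300, 4)).astype(int)
        base[0, 2:] *= 16  # one 16-fold enriched site
        t = _table(base, [("a", "N"), ("a", "C"), ("b", "N"), ("b", "C")])
        res = d.compute_enrichment(t, ["a"], ["b"])
        assert res[0].significant and res[0].log2fc > 3
        assert np.mean([r.significant for r in res[1:]]) < 0.1

    def test_null_table_raw_p_calibrated(self):
        """Resequencing the same library: raw p<0.05 in [0.03, 0.07] and the
        BH-significant fraction at 0.1 stays below 0.12."""
        table, ini, fin = make_null_count_table(seed=42)
        res = d.compute_enrichment(table, ini, fin)
        p = np.array([r.pvalue for r in res])
        assert len(res) == 2000
        assert 0.03 <= np.mean(p < 0.05) <= 0.07
        assert np.mean([r.significant for r in res]) <= 0.12

    def test_use_raw_p_flag(self):
        table, ini, fin = make_null_count_table(seed=7, n_rows=400)
        raw = d.compute_enrichment(table, ini, fin, use_raw_p=True, alpha=0.5)
        adj = d.compute_enrichment(table, ini, fin, alpha=0.5)
        assert sum(r.significant for r in raw) >= sum(r.significant for r in adj)

    def test_productive_only_recomputes_normalization(self):
        idx = pd.MultiIndex.from_tuples(
            [("dna", 3, "forward", 0), ("dna", 4, "forward", 1),
             ("dna", 5, "reverse", -1), ("dna", 6, "forward", 0)],
            names=ROW_NAMES,
        )
        cols = pd.MultiIndex.from_tuples(
            [("a", "N"), ("a", "C"), ("b", "N"), ("b", "C")], names=["sample", "end"]
        )
        k = pd.DataFrame(
            [[100, 100, 100, 100], [900, 900, 100, 100],
             [900, 900, 100, 100], [50, 50, 200, 200]],
            index=idx, columns=cols,
        )
        t = CountTable(k)
        full = {r.site: r for r in d.compute_enrichment(t, ["a"], ["b"])}
        prod = {r.site: r for r in d.compute_enrichment(t, ["a"], ["b"], productive_only=True)}
        assert set(prod) == {("dna", 3, "forward", 0), ("dna", 6, "forward", 0)}
        # dropping the skewed unproductive rows changes the size factors,
        # hence the fold change of the shared rows
        assert prod[("dna", 3, "forward", 0)].log2fc != pytest.approx(
            full[("dna", 3, "forward", 0)].log2fc
        )

    def test_collapse_ends_sums_technical_replicates(self):
        t = _table(
            [[10, 30, 20, 60]],
            [("a", "N"), ("a", "C"), ("b", "N"), ("b", "C")],
        )
        res = d.compute_enrichment(t, ["a"], ["b"], collapse_ends=True, sf_pseudocount=0.5)
        assert len(res) == 1
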