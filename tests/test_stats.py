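"""Statistical primitives against hand computations and independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import assume, given
from hypothesis import strategies as st
from scipy import stats as sps

from _oracles import bh_step_up, hypergeom_tail_brute
from megpipe.stats import (HypergeomParams, bh_adjust, fold_enrichment,
                           hypergeom_upper_tail, welch_t_matrix, welch_t_test)

finite_floats = st.floats(-50, 50, allow_nan=False)
sample = st.lists(finite_floats, min_size=2, max_size=12)


class TestWelch:
    def test_identical_groups_give_null_result(self):
        r = welch_t_test([0.5, 0.5, 0.5], [0.5, 0.5, 0.5])
        assert (r.t_stat, r.p_value, r.delta) == (0.0, 1.0, 0.0)
        assert r.degenerate

    def test_hand_computed_example(self):
        # sa^2 = sb^2 = 0.01, se = sqrt(0.02/3), t = -0.4/se, Welch df = 4
        r = welch_t_test([0.1, 0.2, 0.3], [0.5, 0.6, 0.7])
        assert r.t_stat == pytest.approx(-4.898979485566356, rel=1e-12)
        assert r.df == pytest.approx(4.0, rel=1e-12)
        assert r.p_value == pytest.approx(0.00804989310083772, rel=1e-9)
        assert r.delta == pytest.approx(-0.4)

    def test_matches_reference_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            na, nb = rng.integers(2, 25, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nb)
            ref = sps.ttest_ind(a, b, equal_var=False)
            r = welch_t_test(a, b)
            assert r.t_stat == pytest.approx(ref.statistic, rel=1e-10)
            assert r.df == pytest.approx(ref.df, rel=1e-10)
            assert r.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    @given(a=sample, b=sample)
    def test_swapping_groups_negates_t_and_delta(self, a, b):
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.delta == pytest.approx(-r2.delta, abs=1e-12)
        if math.isfinite(r1.t_stat):
            assert r1.t_stat == pytest.approx(-r2.t_stat, abs=1e-9)
        assert r1.p_value == pytest.approx(r2.p_value, abs=1e-12)
        assert 0.0 <= r1.p_value <= 1.0

    def test_reduces_to_student_t_with_equal_n_and_variance(self):
        # constant shift keeps variances identical, where Welch == pooled t
        rng = np.random.default_rng(3)
        a = rng.normal(size=8)
        b = a + 1.7
        pooled = sps.ttest_ind(a, b, equal_var=True)
        r = welch_t_test(a, b)
        assert r.t_stat == pytest.approx(pooled.statistic, rel=1e-12)
        assert r.p_value == pytest.approx(pooled.pvalue, rel=1e-12)

    def test_zero_variance_unequal_means_is_flagged_zero_limit(self):
        r = welch_t_test([1.0, 1.0], [2.0, 2.0])
        assert r.p_value == 0.0 and r.t_stat == -math.inf and r.degenerate
        assert not math.isnan(r.delta)

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])

    def test_matrix_matches_scalar_row_by_row(self):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(40, 5))
        b = rng.normal(size=(40, 7))
        a[3, :] = 2.0  # degenerate rows exercise both zero-variance contracts
        b[3, :] = 2.0
        a[4, :] = 1.0
        b[4, :] = 3.0
        res = welch_t_matrix(a, b)
        for i in range(a.shape[0]):
            r = welch_t_test(a[i], b[i])
            assert res["t"][i] == pytest.approx(r.t_stat, rel=1e-12, abs=1e-12)
            assert res["p"][i] == pytest.approx(r.p_value, rel=1e-12, abs=1e-12)
            assert res["df"][i] == pytest.approx(r.df, rel=1e-12)


class TestBHAdjust:
    @pytest.mark.parametrize("p, expected", [
        ([0.05], [0.05]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0, 1.0], [1.0, 1.0]),
    ])
    def test_hand_computed_step_up(self, p, expected):
        assert bh_adjust(p) == pytest.approx(expected)

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=30))
    def test_matches_textbook_step_up_and_permutation_equivariant(self, p):
        q = bh_adjust(p)
        assert q == pytest.approx(bh_step_up(p), abs=1e-12)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(p))
        assert bh_adjust(np.asarray(p)[perm]) == pytest.approx(q[perm], abs=1e-12)
        assert np.all((q >= 0) & (q <= 1))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])


class TestHypergeom:
    def test_tail_from_zero_is_one(self):
        assert hypergeom_upper_tail(HypergeomParams(10, 5, 5, 0)) == 1.0

    def test_full_overlap_counting_oracle(self):
        # C(5,5)*C(5,0)/C(10,5) = 1/252
        p = hypergeom_upper_tail(HypergeomParams(10, 5, 5, 5))
        assert p == pytest.approx(1 / 252, rel=1e-12)

    def test_matches_bruteforce_enumeration(self):
        for N in (5, 9, 13, 18, 24, 30):
            for K in range(N + 1):
                for m in range(0, N + 1, 3):
                    for k in range(0, min(K, m) + 1, 2):
                        got = hypergeom_upper_tail(HypergeomParams(N, K, m, k))
                        assert got == pytest.approx(
                            hypergeom_tail_brute(N, K, m, k), abs=1e-12)

    def test_tail_strictly_decreasing_in_k(self):
        p7 = hypergeom_upper_tail(HypergeomParams(17450, 89, 366, 7))
        p6 = hypergeom_upper_tail(HypergeomParams(17450, 89, 366, 6))
        assert 0.0 < p7 < p6 < 1.0

    @pytest.mark.parametrize("bad", [(10, 11, 5, 0), (10, 5, 5, 6), (-1, 0, 0, 0)])
    def test_invalid_counts_rejected(self, bad):
        with pytest.raises(ValueError):
            HypergeomParams(*bad)


class TestFoldEnrichment:
    def test_no_enrichment_is_one(self):
        assert fold_enrichment(HypergeomParams(100, 10, 50, 5)) == pytest.approx(1.0)

    def test_reported_pathway_rows_cross_consistent(self):
        # background solved from the disease-pathway row (7/89 at 3.75-fold)
        n_bg = round(3.75 * 89 * 366 / 7)
        assert n_bg == 17450
        assert fold_enrichment(HypergeomParams(n_bg, 129, 366, 13)) == pytest.approx(4.80, abs=5e-3)
        # and solving from the adhesion row instead recovers 3.75
        n_bg2 = round(4.80 * 129 * 366 / 13)
        assert fold_enrichment(HypergeomParams(n_bg2, 89, 366, 7)) == pytest.approx(3.75, abs=5e-3)

    def test_zero_sizes_rejected(self):
        with pytest.raises(ValueError):
            fold_enrichment(HypergeomParams(10, 0, 5, 0))
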