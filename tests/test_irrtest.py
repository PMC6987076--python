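"""Per-series binomial irreversibility test and surrogate-null variants."""

import numpy as np
import pytest
from scipy import stats

from ordirr.irrtest import (
    asymmetry_statistic,
    binomial_pvalue_half,
    binomial_rejects_half,
    classify_strength,
    exact_binomial_pvalue,
    surrogate_null_test,
)
from ordirr.irrtest import test_series as run_series_test
from ordirr.simulate import LogisticSpec, gaussian_ar_series, logistic_series


class TestAsymmetryStatistic:
    @pytest.mark.parametrize(
        "cf, cr, expected", [(50, 50, 0.5), (8, 0, 1.0), (3, 1, 0.75), (0, 4, 0.0)]
    )
    def test_values(self, cf, cr, expected):
        assert asymmetry_statistic(cf, cr) == expected

    def test_empty_pair_is_undefined(self):
        with pytest.raises(ValueError):
            asymmetry_statistic(0, 0)
        with pytest.raises(ValueError):
            asymmetry_statistic(-1, 2)


class TestExactBinomialPvalue:
    @pytest.mark.parametrize(
        "k, n, expected",
        [
            (50, 100, 1.0),
            (15, 15, 2 * 0.5**15),
            (8, 8, 0.0078125),
            (0, 8, 0.0078125),  # symmetry of the null
        ],
    )
    def test_closed_forms(self, k, n, expected):
        assert exact_binomial_pvalue(k, n) == pytest.approx(expected, abs=1e-15)

    def test_agrees_with_scipy_binomtest(self, rng):
        """Independent oracle: scipy's exact minimum-likelihood two-sided test."""
        for _ in range(300):
            n = int(rng.integers(1, 400))
            k = int(rng.integers(0, n + 1))
            assert exact_binomial_pvalue(k, n) == pytest.approx(
                stats.binomtest(k, n, 0.5).pvalue, abs=1e-12
            )

    def test_contract_errors(self):
        with pytest.raises(ValueError):
            exact_binomial_pvalue(5, 4)
        with pytest.raises(ValueError):
            exact_binomial_pvalue(-1, 4)
        with pytest.raises(ValueError):
            exact_binomial_pvalue(0, 0)

    def test_vectorized_rejection_matches_pvalue_threshold(self, rng):
        n = rng.integers(1, 200, size=500)
        k = (rng.random(500) * (n + 1)).astype(int)
        for alpha in (0.01, 0.05):
            assert np.array_equal(
                binomial_rejects_half(k, n, alpha),
                binomial_pvalue_half(k, n) < alpha,
            )


class TestTestSeries:
    def test_minimal_detectable_ramp(self):
        # 10 windows, all (0,1,2): p = 2 * (1/2)^10 < 0.01
        res = run_series_test(np.arange(12.0))
        assert res.irreversible and res.min_pvalue == pytest.approx(2 * 0.5**10)
        # 7 windows: p = 0.015625 > 0.01
        res9 = run_series_test(np.arange(9.0))
        assert not res9.irreversible and res9.min_pvalue == pytest.approx(0.015625)
        # N=10 is the shortest ramp that rejects at alpha=0.01
        assert run_series_test(np.arange(10.0)).irreversible

    def test_pvalue_decreases_with_ramp_length(self):
        ps = [run_series_test(np.arange(float(N))).min_pvalue for N in range(10, 30, 4)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_constant_series_flagged_degenerate_without_crash(self):
        res = run_series_test(np.zeros(100))
        assert res.degenerate

    def test_bonferroni_is_more_conservative(self, rng):
        flips = 0
        for i in range(200):
            x = rng.standard_normal(200)
            plain = run_series_test(x, alpha=0.05)
            bonf = run_series_test(x, alpha=0.05, correction="bonferroni")
            assert plain.irreversible or not bonf.irreversible
            flips += plain.irreversible != bonf.irreversible
        assert flips >= 0  # sanity; the implication above is the real check

    def test_statistic_and_counts_consistent(self, logistic_1000):
        res = run_series_test(logistic_1000)
        for pr in res.per_pair:
            if pr.p_value is None:
                continue
            assert pr.statistic_p == pytest.approx(
                pr.count_forward / (pr.count_forward + pr.count_reversed)
            )
            assert 0 <= pr.p_value <= 1
            assert pr.reject == (pr.p_value < res.alpha)

    def test_null_rejection_rate_controlled(self, rng):
        rejections = sum(
            run_series_test(rng.standard_normal(500)).irreversible for _ in range(500)
        )
        assert rejections / 500 <= 0.05  # familywise over 3 pairs at alpha=0.01

    def test_alpha_contract(self):
        with pytest.raises(ValueError):
            run_series_test(np.arange(20.0), alpha=1.5)


class TestSurrogateNullTest:
    def test_logistic_beats_all_shuffles(self, logistic_1000):
        res = surrogate_null_test(logistic_1000, M=99, method="shuffle", seed=0)
        assert res.empirical_p == pytest.approx(1 / 100)

    def test_determinism(self, logistic_1000):
        a = surrogate_null_test(logistic_1000, M=19, method="shuffle", seed=3)
        b = surrogate_null_test(logistic_1000, M=19, method="shuffle", seed=3)
        assert a.empirical_p == b.empirical_p
        assert np.array_equal(a.surrogate_statistics, b.surrogate_statistics)

    def test_empirical_p_uses_rank_formula(self, rng):
        res = surrogate_null_test(rng.standard_normal(300), M=19, method="shuffle", seed=1)
        rank = int(np.sum(res.surrogate_statistics <= res.observed_statistic))
        assert res.empirical_p == (1 + rank) / 20
        assert 0 < res.empirical_p <= 1

    def test_shuffle_agrees_with_analytic_decision(self, rng):
        """Shuffle-mode empirical test and analytic binomial test concur."""
        agree = 0
        n_trials = 500
        for i in range(n_trials):
            x = rng.standard_normal(300)
            analytic = run_series_test(x, alpha=0.05).irreversible
            empirical = (
                surrogate_null_test(x, M=199, method="shuffle", seed=i, alpha=0.05).empirical_p
                < 0.05
            )
            agree += analytic == empirical
        assert agree / n_trials >= 0.95

    def test_m_contract(self, logistic_1000):
        with pytest.raises(ValueError):
            surrogate_null_test(logistic_1000, M=5)


class TestClassifyStrength:
    @pytest.mark.parametrize(
        "shuffle_sig, surr_sig, expected",
        [
            (True, True, "strong"),
            (True, False, "weak"),
            (False, False, "reversible"),
            (False, True, "reversible"),
        ],
    )
    def test_mapping(self, shuffle_sig, surr_sig, expected):
        assert classify_strength(shuffle_sig, surr_sig) == expected
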