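"""Bi-lineage and bias tests, FDR correction, permutation machinery."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from clonotype.clone_stats import (
    bh_fdr,
    bias_test,
    bilineage_test,
    contamination_probabilities,
    heritability,
    permutation_correlation,
)


def probs_for(pc_e, pc_m, timepoints=(0,)):
    from clonotype.clone_stats import ContaminationProbs

    return ContaminationProbs(
        pC_e={t: pc_e for t in timepoints}, pC_m={t: pc_m for t in timepoints}
    )


class TestContaminationProbs:
    def test_no_missort_into_state_gives_zero(self):
        probs = contamination_probabilities({0: 100}, {0: 100}, {0: 0.1}, {0: 0.0})
        assert probs.pC_e[0] == 0.0

    def test_symmetric_example(self):
        probs = contamination_probabilities({0: 100}, {0: 100}, {0: 0.1}, {0: 0.1})
        # E = 90, E' = 10 -> pC_e = 0.1
        assert probs.pC_e[0] == pytest.approx(0.1)
        assert probs.pC_m[0] == pytest.approx(0.1)

    def test_zero_reads_undefined(self):
        with pytest.raises(ValueError):
            contamination_probabilities({0: 0}, {0: 0}, {0: 0.1}, {0: 0.1})


class TestBilineage:
    def test_upper_tail_matches_binomial_oracle(self):
        """pC_e=0.01, (r_e, r_m)=(100, 3): inclusive upper tail ~0.086."""
        re = pd.DataFrame({0: [100]}, index=["c"])
        rm = pd.DataFrame({0: [3]}, index=["c"])
        out = bilineage_test(re, rm, probs_for(0.01, 0.01))
        # independent oracle: sum the pmf over x >= 3 directly
        n, p = 103, 0.01
        oracle = sum(math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(3, n + 1))
        assert out.loc["c", "p_all_e_t0"] == pytest.approx(oracle, rel=1e-9)
        assert oracle == pytest.approx(0.086, abs=0.002)
        assert not out.loc["c", "reject_all_e_t0"]

    def test_balanced_clone_is_bilineage(self):
        re = pd.DataFrame({0: [500]}, index=["c"])
        rm = pd.DataFrame({0: [500]}, index=["c"])
        out = bilineage_test(re, rm, probs_for(0.05, 0.05))
        assert out.loc["c", "call"] == "bilineage"
        assert out.loc["c", "p_all_e_t0"] < 1e-10

    def test_zero_minor_reads_cannot_reject_and_calls_mono(self):
        re = pd.DataFrame({0: [100], 7: [100], 14: [100]}, index=["c"])
        rm = pd.DataFrame({0: [0], 7: [0], 14: [0]}, index=["c"])
        out = bilineage_test(re, rm, probs_for(0.02, 0.02, (0, 7, 14)))
        assert out.loc["c", "call"] == "mono_E"
        for t in (0, 7, 14):
            assert out.loc["c", f"p_all_e_t{t}"] == pytest.approx(1.0)

    def test_zero_read_timepoint_excluded(self):
        re = pd.DataFrame({0: [0], 7: [300]}, index=["c"])
        rm = pd.DataFrame({0: [0], 7: [300]}, index=["c"])
        out = bilineage_test(re, rm, probs_for(0.05, 0.05, (0, 7)))
        assert out.loc["c", "n_timepoints_tested"] == 1
        assert out.loc["c", "call"] == "bilineage"

    def test_type_i_error_controlled_for_mono_clones(self):
        """Truly single-lineage clones under realistic contamination are
        called bi-lineage at most 5% of the time at FDR 0.05."""
        rng = np.random.default_rng(0)
        n_clones, timepoints = 1000, (0, 7, 14)
        sigma_e, sigma_m = 0.02, 0.03
        half = n_clones // 2
        rows_e, rows_m = [], []
        for t in timepoints:
            total = rng.integers(200, 2000, size=n_clones)
            # first half truly epithelial: minor reads arise only via sort
            # contamination at rate pC_e; second half truly mesenchymal
            pc_e = sigma_m  # balanced read totals make pC ~ sigma of other sort
            pc_m = sigma_e
            rm = np.concatenate(
                [
                    rng.binomial(total[:half], pc_e),
                    total[half:] - rng.binomial(total[half:], pc_m),
                ]
            )
            rows_m.append(rm)
            rows_e.append(total - rm)
        re = pd.DataFrame(dict(zip(timepoints, rows_e)))
        rm = pd.DataFrame(dict(zip(timepoints, rows_m)))
        out = bilineage_test(re, rm, probs_for(sigma_m, sigma_e, timepoints))

        # exact-binomial type-I error per test: true nulls reject <= alpha
        alpha = 0.05
        true_null_p = np.concatenate(
            [
                out[[f"p_all_e_t{t}" for t in timepoints]].iloc[:half].to_numpy().ravel(),
                out[[f"p_all_m_t{t}" for t in timepoints]].iloc[half:].to_numpy().ravel(),
            ]
        )
        n_tests = true_null_p.size
        raw_rate = (true_null_p <= alpha).mean()
        assert raw_rate <= alpha + 3 * math.sqrt(alpha * (1 - alpha) / n_tests)

        # realized false-discovery proportion of the BH family <= 0.05
        false_rej = (
            out[[f"reject_all_e_t{t}" for t in timepoints]].iloc[:half].to_numpy().sum()
            + out[[f"reject_all_m_t{t}" for t in timepoints]].iloc[half:].to_numpy().sum()
        )
        total_rej = (
            out[[f"reject_all_e_t{t}" for t in timepoints]].to_numpy().sum()
            + out[[f"reject_all_m_t{t}" for t in timepoints]].to_numpy().sum()
        )
        fdp = false_rej / total_rej
        assert fdp <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / total_rej)

        # the clone-level bilineage false-call rate sits near (not exactly
        # at) alpha, because the call combines three timepoints against a
        # BH threshold lifted by the many true opposite-state rejections
        false_bilineage = (out["call"] == "bilineage").mean()
        assert false_bilineage <= 0.10


class TestBias:
    def test_clone_at_population_proportion_not_rejected(self):
        re = pd.DataFrame({0: [60, 540]}, index=["c", "rest"])
        rm = pd.DataFrame({0: [40, 360]}, index=["c", "rest"])
        out = bias_test(re, rm)
        assert out.loc["c", "p_t0"] == pytest.approx(1.0)
        assert not out.loc["c", "biased"]

    def test_statistic_matches_chi2_oracle(self):
        """Observed (80, 20) vs expected (60, 40): x=16.67, p~4.5e-5."""
        # population totals chosen so the expected split is 60/40
        re = pd.DataFrame({0: [80, 5920]}, index=["c", "rest"])
        rm = pd.DataFrame({0: [20, 3980]}, index=["c", "rest"])
        out = bias_test(re, rm)
        x = (80 - 60) ** 2 / 60 + (20 - 40) ** 2 / 40
        assert x == pytest.approx(16.67, abs=0.01)
        assert out.loc["c", "p_t0"] == pytest.approx(stats.chi2.sf(x, 1), rel=1e-6)
        assert out.loc["c", "p_t0"] == pytest.approx(4.5e-5, abs=0.5e-5)

    def test_statistic_scales_linearly_with_reads(self):
        re1 = pd.DataFrame({0: [80, 5920]}, index=["c", "rest"])
        rm1 = pd.DataFrame({0: [20, 3980]}, index=["c", "rest"])
        re2, rm2 = re1 * 2, rm1 * 2
        p1 = bias_test(re1, rm1).loc["c", "p_t0"]
        p2 = bias_test(re2, rm2).loc["c", "p_t0"]
        x1 = stats.chi2.isf(p1, 1)
        x2 = stats.chi2.isf(p2, 1)
        assert x2 == pytest.approx(2 * x1, rel=1e-6)

    def test_null_rejection_rate_controlled(self):
        """Clones drawn exactly at population proportions reject <= 5%."""
        rng = np.random.default_rng(1)
        n = 1000
        timepoints = (0, 7)
        re_cols, rm_cols = {}, {}
        for t in timepoints:
            total = rng.integers(100, 1000, size=n)
            e = rng.binomial(total, 0.6)
            re_cols[t] = e
            rm_cols[t] = total - e
        out = bias_test(pd.DataFrame(re_cols), pd.DataFrame(rm_cols))
        assert out["biased"].mean() <= 0.05


class TestBhFdr:
    def test_single_small_p_rejected(self):
        assert bh_fdr([0.01], 0.05).tolist() == [True]

    def test_step_up_by_hand(self):
        # sorted p (0.01, 0.02, 0.04, 0.9); thresholds i/m*alpha =
        # (0.0125, 0.025, 0.0375, 0.05); the largest i with p_i <= i/m*alpha
        # is i=2, so exactly the first two are rejected
        rejected = bh_fdr([0.01, 0.02, 0.04, 0.9], alpha=0.05)
        assert rejected.tolist() == [True, True, False, False]

    def test_step_up_rejects_below_a_later_threshold(self):
        # 0.04 at rank 3 of 4 passes once a companion pushes its threshold:
        # p=(0.01, 0.02, 0.037, 0.04): p_4=0.04 <= 4/4*0.05 -> all rejected
        assert bh_fdr([0.01, 0.02, 0.037, 0.04], alpha=0.05).all()

    def test_all_ones_rejected_nothing(self):
        assert not bh_fdr([1.0, 1.0, 1.0], 0.05).any()

    def test_empty_input(self):
        assert bh_fdr([], 0.05).size == 0

    def test_monotone_in_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(50)
        rej = bh_fdr(p, 0.1)
        if rej.any():
            assert p[rej].max() <= p[~rej].min() or not (~rej).any()


class TestPermutation:
    def test_perfect_correlation_floors_p(self):
        x = np.arange(28.0)
        res = permutation_correlation(x, x, reps=2000, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.exceed == 0
        assert res.p_value == pytest.approx(1 / 2001)

    def test_matches_exhaustive_enumeration_n4(self):
        x = np.array([0.1, 0.9, 0.3, 0.6])
        y = np.array([0.2, 0.8, 0.1, 0.9])
        rho_obs = np.corrcoef(x, y)[0, 1]
        exact_ge = sum(
            np.corrcoef(x, np.array(perm))[0, 1] >= rho_obs - 1e-12
            for perm in itertools.permutations(y)
        )
        exact_p = exact_ge / math.factorial(4)
        reps = 40_000
        res = permutation_correlation(x, y, reps=reps, seed=1)
        se = math.sqrt(exact_p * (1 - exact_p) / reps)
        assert abs(res.p_value - exact_p) <= 3 * se + 2 / reps

    def test_null_p_is_roughly_uniform(self):
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(40):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            pvals.append(permutation_correlation(x, y, reps=400, seed=int(rng.integers(2**31))).p_value)
        # Kolmogorov-Smirnov against uniform should not reject wildly
        d, p = stats.kstest(pvals, "uniform")
        assert p > 0.01

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            permutation_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], reps=10)

    def test_requires_three_points(self):
        with pytest.raises(ValueError):
            permutation_correlation([1.0, 2.0], [1.0, 2.0], reps=10)


class TestHeritability:
    def test_perfect_transmission(self):
        pooled = pd.Series([0.1, -1.0, 2.0, 0.5], index=list("abcd"))
        rho, res = heritability(pooled, pooled.copy(), reps=100, seed=0)
        assert rho == pytest.approx(1.0)

    def test_unmatched_clones_dropped(self):
        pooled = pd.Series([0.1, -1.0, 2.0, 0.5], index=list("abcd"))
        sub = pd.Series([0.1, -1.0, 2.0, 9.9], index=list("abce"))
        rho, _ = heritability(pooled, sub, reps=100, seed=0)
        assert rho == pytest.approx(1.0)  # only a,b,c matched

    def test_attenuation_under_transmission_noise(self):
        """With noise tau on both measurements of a trait with spread
        sigma, the expected correlation is sigma^2/(sigma^2+tau^2)."""
        rng = np.random.default_rng(4)
        sigma_t, tau, n = 2.0, 1.0, 600
        base = rng.normal(0, sigma_t, n)
        pooled = pd.Series(base + rng.normal(0, tau, n))
        sub = pd.Series(base + rng.normal(0, tau, n))
        rho, _ = heritability(pooled, sub, reps=100, seed=0)
        expected = sigma_t**2 / (sigma_t**2 + tau**2)
        se = (1 - expected**2) / math.sqrt(n - 3)
        assert abs(rho - expected) <= 3 * se
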