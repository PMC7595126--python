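"""Comparison statistics against brute-force enumeration oracles."""

import numpy as np
import pytest
import scipy.stats as sps

from maculamap import (fit_tilt_model, friedman_across_sizes,
                       median_ci, run_comparison, spearman_vs_tilt,
                       wilcoxon_one_sample)
from maculamap.extraction import MeasurementSet
from oracles import friedman_enumeration_p, wilcoxon_enumeration_p


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------

class TestWilcoxon:
    def test_all_positive_five(self):
        """{+1..+5}: only one of 32 sign assignments reaches W+=15, so the
        exact two-sided p is 2/32 = 0.0625."""
        res = wilcoxon_one_sample([1, 2, 3, 4, 5])
        assert res.p == pytest.approx(0.0625)
        assert res.median == 3.0

    def test_symmetric_differences(self):
        res = wilcoxon_one_sample([-2, -1, 1, 2])
        assert res.median == 0.0
        assert res.p == 1.0

    def test_all_zero(self):
        res = wilcoxon_one_sample([0.0, 0.0, 0.0])
        assert res.p == 1.0 and res.median == 0.0 and res.ci95 == (0.0, 0.0)
        assert res.n_used == 0

    @pytest.mark.parametrize("seed", range(40))
    def test_exact_p_matches_enumeration(self, seed):
        """Random vectors (ties and zeros included) up to n=10: the
        convolution-based exact p equals the 2^n enumeration oracle."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 11))
        # half-integer values induce frequent ties and occasional zeros
        d = rng.integers(-4, 5, n) / 2.0
        res = wilcoxon_one_sample(d)
        assert res.p == pytest.approx(wilcoxon_enumeration_p(d), abs=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(5)
        d = rng.normal(0.3, 1.0, 60)
        res = wilcoxon_one_sample(d)
        ref = sps.wilcoxon(d, correction=True, method="approx").pvalue
        assert res.p == pytest.approx(float(ref), rel=1e-10)

    def test_median_ci_contains_median_with_coverage(self):
        rng = np.random.default_rng(11)
        x = rng.normal(2.0, 1.0, 35)
        lo, hi = median_ci(x)
        assert lo <= np.median(x) <= hi
        # binomial order-statistic coverage at n=35: k such that the
        # interval has >= 95% nominal coverage
        n = 35
        k = int(sps.binom.ppf(0.025, n, 0.5))
        while sps.binom.cdf(k - 1, n, 0.5) > 0.025:
            k -= 1
        xs = np.sort(x)
        assert (lo, hi) == (xs[k - 1], xs[n - k])


class TestSpearman:
    def test_perfect_monotone(self):
        t = np.arange(10.0)
        up = spearman_vs_tilt(t, t ** 2)
        down = spearman_vs_tilt(t, -t)
        assert up.rho == pytest.approx(1.0)
        assert down.rho == pytest.approx(-1.0)

    def test_tied_data_matches_midrank_formula(self):
        t = np.array([1, 1, 2, 3, 3, 4, 5, 5], float)
        d = np.array([2, 3, 3, 5, 4, 4, 7, 7], float)
        res = spearman_vs_tilt(t, d)
        rt, rd = sps.rankdata(t), sps.rankdata(d)
        expected = np.corrcoef(rt, rd)[0, 1]  # Pearson on midranks
        assert res.rho == pytest.approx(expected, abs=1e-12)

    def test_constant_tilts_flagged_undefined(self):
        res = spearman_vs_tilt([3, 3, 3, 3], [1, 2, 3, 4])
        assert not res.defined and np.isnan(res.rho)

    def test_ci_brackets_rho(self):
        rng = np.random.default_rng(2)
        t = rng.normal(6, 3, 40)
        d = 0.5 * t + rng.normal(0, 2, 40)
        res = spearman_vs_tilt(t, d)
        assert res.ci95[0] < res.rho < res.ci95[1]


class TestTiltModel:
    def test_exact_line_selects_linear(self):
        t = np.array([0, 2, 5, 9, 12.0])
        fit = fit_tilt_model(t, 1.5 - 0.8 * t)
        assert fit.model == "linear"
        assert fit.coef_quadratic[2] == pytest.approx(0.0, abs=1e-9)
        assert fit.delta_15_0 == pytest.approx(-0.8 * 15)

    def test_exact_parabola_selects_quadratic(self):
        t = np.array([0, 1, 3, 7, 10.0])
        fit = fit_tilt_model(t, 2 - t + 0.3 * t ** 2)
        assert fit.model == "quadratic"
        assert fit.rss_quadratic == pytest.approx(0.0, abs=1e-9)
        assert np.isinf(fit.f_stat)
        assert fit.delta_15_0 == pytest.approx(-15 + 0.3 * 225)

    @pytest.mark.parametrize("seed", range(10))
    def test_f_statistic_matches_rss_arithmetic(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        t = rng.normal(6, 4, n)
        d = rng.normal(0, 3, n)
        fit = fit_tilt_model(t, d)
        # direct RSS oracle via polynomial fits
        r1 = float(np.sum((d - np.polyval(np.polyfit(t, d, 1), t)) ** 2))
        r2 = float(np.sum((d - np.polyval(np.polyfit(t, d, 2), t)) ** 2))
        f_expected = ((r1 - r2) / 1) / (r2 / (n - 3))
        assert fit.f_stat == pytest.approx(f_expected, rel=1e-9, abs=1e-9)

    def test_null_quadratic_selection_rate_near_alpha(self):
        """Under a linear truth the F test picks the quadratic at ~ the 5%
        nominal rate."""
        rng = np.random.default_rng(123)
        picks = 0
        reps = 500
        for _ in range(reps):
            t = rng.normal(6, 3.3, 40)
            d = 1.0 + 0.5 * t + rng.normal(0, 2, 40)
            picks += fit_tilt_model(t, d).model == "quadratic"
        assert 0.02 < picks / reps < 0.08


class TestFriedman:
    def test_identical_columns(self):
        v = np.tile(np.arange(5.0)[:, None], (1, 3))
        res = friedman_across_sizes(v)
        assert res.chi2 == 0.0 and res.p == 1.0

    @pytest.mark.parametrize("seed", range(12))
    def test_exact_p_matches_permutation_oracle(self, seed):
        """n ≤ 5 matrices (ties included): the DP-exact p equals the full
        (3!)^n permutation enumeration."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        v = rng.integers(0, 4, (n, 3)).astype(float)
        res = friedman_across_sizes(v)
        assert res.computable
        if res.chi2 == 0.0 and res.p == 1.0:
            assert friedman_enumeration_p(v) == pytest.approx(1.0)
        else:
            assert res.p == pytest.approx(friedman_enumeration_p(v), abs=1e-12)

    def test_chi2_path_matches_scipy(self):
        rng = np.random.default_rng(3)
        v = rng.normal(60, 5, (30, 3))
        res = friedman_across_sizes(v)
        ref = sps.friedmanchisquare(v[:, 0], v[:, 1], v[:, 2])
        assert res.chi2 == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_shifted_column_flagged_in_posthoc(self):
        rng = np.random.default_rng(9)
        v = rng.normal(70, 1.0, (30, 3))
        v[:, 2] += 10.0
        res = friedman_across_sizes(v)
        assert res.p < 0.05
        assert res.posthoc[("GII", "GV")] < 0.05
        assert res.posthoc[("GIII", "GV")] < 0.05
        assert res.posthoc[("GII", "GIII")] > 0.05

    def test_rows_with_exclusions_dropped(self):
        v = np.array([[1, 2, 3], [np.nan, 2, 3], [2, 3, 1], [3, 1, 2.0]])
        res = friedman_across_sizes(v)
        assert res.n == 3

    def test_too_few_rows_not_computable(self):
        res = friedman_across_sizes(np.array([[1.0, 2.0, 3.0]]))
        assert not res.computable


def _mset(values, paradigm="GIII"):
    vals = np.asarray(values, float)
    return MeasurementSet(paradigm, vals, [None] * len(vals), 0.0)


class TestRunComparison:
    def test_identical_cohorts_all_null(self):
        rng = np.random.default_rng(4)
        grid_vals = rng.uniform(50, 90, (6, 64))
        vf_sets, grid_sets, assignments = [], [], []
        for p in range(6):
            gs = _mset(grid_vals[p], "grid8x8")
            asg = [int(i % 64) for i in range(80)]
            vf_sets.append(_mset(grid_vals[p][asg]))
            grid_sets.append(gs)
            assignments.append(asg)
        table = run_comparison(vf_sets, grid_sets, assignments).table
        assert len(table) == 80
        assert (table["median_diff_um"] == 0).all()
        assert not table["significant"].any()

    def test_unassigned_location_not_computable(self):
        vf = [_mset(np.full(80, 70.0)) for _ in range(5)]
        gr = [_mset(np.full(64, 60.0), "grid8x8") for _ in range(5)]
        asg = [[None] * 80 for _ in range(5)]
        table = run_comparison(vf, gr, asg).table
        assert (~table["computable"]).all()

    def test_systematic_offset_detected(self):
        rng = np.random.default_rng(8)
        vf_sets, grid_sets, assignments = [], [], []
        for p in range(20):
            base = rng.uniform(60, 80, 64)
            asg = list(np.arange(80) % 64)
            vf_sets.append(_mset(base[asg] + 5 + rng.normal(0, 1, 80)))
            grid_sets.append(_mset(base, "grid8x8"))
            assignments.append([int(a) for a in asg])
        ct = run_comparison(vf_sets, grid_sets, assignments)
        assert ct.table["significant"].all()
        s = ct.summary(3.9)
        assert s["n_abs_median_gt_threshold"] == 80
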