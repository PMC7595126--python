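"""Cohort-level comparison statistics.

The pointwise battery mirrors common practice for non-normal paired
structural data:

* one-sample Wilcoxon signed-rank tests on per-location paired differences
  (VF-paradigm value minus its greatest-shared-area 8×8 square), with exact
  null distributions at small n;
* Spearman rank correlation of differences against fovea-to-disc tilt;
* nested linear-vs-quadratic least squares with the extra-sum-of-squares
  F test, the better model then predicting the difference between 0° and
  15° tilt;
* Friedman tests (with Dunn post-hoc) across the three stimulus sizes.

Exact small-sample null distributions are computed by dynamic programming
over sign assignments (Wilcoxon) and within-row label permutations
(Friedman); both handle ties through midranks and agree with brute-force
enumeration.  Large-sample paths use the standard tie-corrected normal /
chi-square approximations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import ValidationError

__all__ = [
    "WilcoxonResult",
    "wilcoxon_one_sample",
    "median_ci",
    "SpearmanResult",
    "spearman_vs_tilt",
    "TiltModelFit",
    "fit_tilt_model",
    "FriedmanResult",
    "friedman_across_sizes",
    "ComparisonTable",
    "run_comparison",
    "compare_stimulus_sizes",
    "WILCOXON_EXACT_MAX_N",
    "FRIEDMAN_EXACT_MAX_N",
]

#: Largest n for which the exact signed-rank null distribution is used.
WILCOXON_EXACT_MAX_N = 25
#: Largest row count for which the exact Friedman null is used.
FRIEDMAN_EXACT_MAX_N = 12


# ---------------------------------------------------------------------------
# one-sample Wilcoxon
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WilcoxonResult:
    median: float
    ci95: tuple[float, float]
    p: float
    n: int          # differences supplied (incl. zeros)
    n_used: int     # after zero drop
    statistic: float  # W+ (sum of positive ranks)


def _midranks(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


def _signed_rank_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p for W+ given |difference| midranks.

    Convolves the null distribution of 2·W+ (doubled ranks are integers even
    with .5 midranks) over all 2^n sign assignments; two-sided p is twice
    the smaller tail, capped at 1.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts = counts + shifted
    counts /= counts.sum()
    w2 = int(np.rint(2 * w_plus))
    lo = counts[: w2 + 1].sum()
    hi = counts[w2:].sum()
    return float(min(1.0, 2.0 * min(lo, hi)))


def median_ci(x, level: float = 0.95) -> tuple[float, float]:
    """Distribution-free CI for the median from binomial order statistics.

    The widest symmetric pair of order statistics with ≥ ``level`` coverage;
    degenerates to the sample range when n is too small for the nominal
    level.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if n == 0:
        raise ValidationError("median_ci needs at least one value")
    alpha = 1.0 - level
    # largest k with P(Bin(n, 1/2) < k) <= alpha/2
    k = int(sps.binom.ppf(alpha / 2, n, 0.5))
    if sps.binom.cdf(k - 1, n, 0.5) > alpha / 2:
        k -= 1
    k = max(k, 1)
    if sps.binom.cdf(k - 1, n, 0.5) > alpha / 2:
        return float(x[0]), float(x[-1])
    return float(x[k - 1]), float(x[n - k])


def wilcoxon_one_sample(diffs, exact_max_n: int = WILCOXON_EXACT_MAX_N) -> WilcoxonResult:
    """Two-sided one-sample Wilcoxon signed-rank test against zero.

    Zeros are dropped before ranking (Wilcoxon's original rule).  The null
    distribution is exact (tie-safe) for ≤ ``exact_max_n`` non-zero
    differences, a tie-corrected normal approximation with continuity
    correction beyond.  The median and its 95% CI are computed from *all*
    supplied differences.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0 or not np.isfinite(d).all():
        raise ValidationError("diffs must be non-empty and finite")
    med = float(np.median(d))
    ci = median_ci(d)
    nz = d[d != 0]
    if nz.size == 0:
        return WilcoxonResult(med, ci, 1.0, d.size, 0, 0.0)
    ranks = _midranks(np.abs(nz))
    w_plus = float(ranks[nz > 0].sum())
    if nz.size <= exact_max_n:
        p = _signed_rank_exact_p(ranks, w_plus)
    else:
        p = float(sps.wilcoxon(nz, alternative="two-sided",
                               correction=True, method="approx").pvalue)
    return WilcoxonResult(med, ci, p, d.size, int(nz.size), w_plus)


# ---------------------------------------------------------------------------
# Spearman vs tilt
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    ci95: tuple[float, float]
    p: float
    n: int
    defined: bool = True


def spearman_vs_tilt(tilts, diffs) -> SpearmanResult:
    """Tie-corrected Spearman rank correlation with a 95% CI.

    The CI uses the Fisher z transform with the Bonett–Wright standard
    error ``sqrt((1 + rho²/2)/(n − 3))``.  Constant tilts (or differences)
    leave rho undefined; the result is flagged rather than raised.
    """
    t = np.asarray(tilts, dtype=float)
    d = np.asarray(diffs, dtype=float)
    if t.size != d.size or t.size < 4:
        raise ValidationError("need >= 4 paired observations")
    if np.ptp(t) == 0 or np.ptp(d) == 0:
        return SpearmanResult(np.nan, (np.nan, np.nan), np.nan, t.size, defined=False)
    rho, p = sps.spearmanr(t, d)
    n = t.size
    if abs(rho) >= 1.0:
        return SpearmanResult(float(rho), (float(rho), float(rho)), float(p), n)
    z = np.arctanh(rho)
    se = np.sqrt((1 + rho ** 2 / 2) / (n - 3))
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return SpearmanResult(float(rho), (float(lo), float(hi)), float(p), n)


# ---------------------------------------------------------------------------
# linear vs quadratic tilt model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TiltModelFit:
    model: str  # "linear" | "quadratic"
    coef_linear: tuple      # (intercept, slope)
    coef_quadratic: tuple   # (intercept, slope, curvature)
    rss_linear: float
    rss_quadratic: float
    f_stat: float
    f_p: float
    delta_15_0: float       # predicted diff(15°) − diff(0°) under chosen model

    def predict(self, tilt):
        tilt = np.asarray(tilt, dtype=float)
        if self.model == "linear":
            b0, b1 = self.coef_linear
            return b0 + b1 * tilt
        b0, b1, b2 = self.coef_quadratic
        return b0 + b1 * tilt + b2 * tilt ** 2


def fit_tilt_model(tilts, diffs) -> TiltModelFit:
    """Nested linear/quadratic least squares with the extra-SS F test.

    ``F = ((RSS_lin − RSS_quad)/1) / (RSS_quad/(n − 3))``; the quadratic is
    chosen iff its F-test p < 0.05.  A perfect quadratic fit (RSS 0) selects
    the quadratic with F reported as +inf.
    """
    t = np.asarray(tilts, dtype=float)
    d = np.asarray(diffs, dtype=float)
    n = t.size
    if n < 4 or d.size != n:
        raise ValidationError("need >= 4 paired observations")

    X1 = np.column_stack([np.ones(n), t])
    X2 = np.column_stack([np.ones(n), t, t ** 2])
    b1, *_ = np.linalg.lstsq(X1, d, rcond=None)
    b2, *_ = np.linalg.lstsq(X2, d, rcond=None)
    rss1 = float(np.sum((d - X1 @ b1) ** 2))
    rss2 = float(np.sum((d - X2 @ b2) ** 2))

    scale = max(1.0, float(np.sum(d ** 2)))
    if rss1 <= 1e-12 * scale:
        # the line already fits perfectly; the extra parameter adds nothing
        f_stat, f_p = 0.0, 1.0
    elif rss2 <= 1e-12 * scale:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = (rss1 - rss2) / (rss2 / (n - 3))
        f_stat = max(f_stat, 0.0)
        f_p = float(sps.f.sf(f_stat, 1, n - 3))
    model = "quadratic" if f_p < 0.05 else "linear"
    fit = TiltModelFit(model, tuple(b1), tuple(b2), rss1, rss2,
                       float(f_stat), float(f_p), 0.0)
    delta = float(fit.predict(15.0) - fit.predict(0.0))
    return TiltModelFit(model, tuple(b1), tuple(b2), rss1, rss2,
                        float(f_stat), float(f_p), delta)


# ---------------------------------------------------------------------------
# Friedman across stimulus sizes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FriedmanResult:
    chi2: float
    p: float
    n: int  # complete rows used
    posthoc: dict = field(default_factory=dict)  # (i, j) -> adjusted p
    computable: bool = True


def _row_ranks(values: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(_midranks, 1, values)


def _friedman_T(col_rank_sums: np.ndarray, n: int, k: int) -> float:
    return float(np.sum((col_rank_sums - n * (k + 1) / 2.0) ** 2))


def _friedman_exact_p(ranks: np.ndarray, t_obs: float) -> float:
    """Exact P(T >= t_obs) over within-row label permutations (k = 3).

    DP over the joint distribution of the first two doubled column rank
    sums; each row contributes its 3! label permutations uniformly (tied
    patterns appear with multiplicity).
    """
    from itertools import permutations

    n, k = ranks.shape
    states: dict[tuple[int, int], float] = {(0, 0): 1.0}
    for row in ranks:
        r2 = np.rint(2 * row).astype(int)
        perms = [tuple(p) for p in permutations(r2)]
        new: dict[tuple[int, int], float] = {}
        for (a, b), cnt in states.items():
            for p in perms:
                key = (a + p[0], b + p[1])
                new[key] = new.get(key, 0.0) + cnt
        states = new
    total = sum(states.values())
    row_sum2 = int(np.rint(2 * ranks.sum()))
    hit = 0.0
    for (a2, b2), cnt in states.items():
        sums = np.array([a2, b2, row_sum2 - a2 - b2]) / 2.0
        if _friedman_T(sums, n, k) >= t_obs - 1e-9:
            hit += cnt
    return float(hit / total)


def friedman_across_sizes(values, exact_max_n: int = FRIEDMAN_EXACT_MAX_N,
                          labels=("GII", "GIII", "GV")) -> FriedmanResult:
    """Friedman test across the three matched stimulus-size paradigms.

    ``values`` is n_subjects × 3; rows containing NaN (any exclusion) are
    dropped.  Tie correction uses midranks.  The null is exact for
    ≤ ``exact_max_n`` complete rows, chi-square beyond.  Post-hoc: Dunn
    pairwise z tests on mean ranks, Bonferroni-adjusted over the 3 pairs.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] != 3:
        raise ValidationError("values must be n_subjects x 3")
    complete = ~np.isnan(v).any(axis=1)
    v = v[complete]
    n, k = v.shape
    if n < 2:
        return FriedmanResult(np.nan, np.nan, n, {}, computable=False)

    ranks = _row_ranks(v)
    col_sums = ranks.sum(axis=0)
    T = _friedman_T(col_sums, n, k)
    denom = float(np.sum(ranks ** 2) - n * k * (k + 1) ** 2 / 4.0)
    if denom <= 0:  # every row completely tied
        chi2, p = 0.0, 1.0
    else:
        chi2 = (k - 1) * T / denom
        if n <= exact_max_n:
            p = _friedman_exact_p(ranks, T)
        else:
            p = float(sps.chi2.sf(chi2, k - 1))

    mean_ranks = col_sums / n
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    posthoc = {}
    for i in range(k):
        for j in range(i + 1, k):
            z = abs(mean_ranks[i] - mean_ranks[j]) / se
            posthoc[(labels[i], labels[j])] = float(min(1.0, 3 * 2 * sps.norm.sf(z)))
    return FriedmanResult(float(chi2), float(p), n, posthoc)


# ---------------------------------------------------------------------------
# cohort comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonTable:
    """Per-location cohort statistics; ``table`` is a pandas DataFrame."""

    table: pd.DataFrame
    paradigm: str
    alpha: float = 0.05

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def summary(self, threshold_um: float = 3.9) -> dict:
        """Counts of computable / significant locations and of locations
        whose |median difference| exceeds the axial-resolution threshold."""
        t = self.table
        comp = t[t["computable"]]
        return {
            "paradigm": self.paradigm,
            "n_locations": int(len(t)),
            "n_computable": int(len(comp)),
            "n_significant": int(comp["significant"].sum()),
            "n_abs_median_gt_threshold":
                int((comp["median_diff_um"].abs() > threshold_um).sum()),
            "threshold_um": threshold_um,
        }


def paired_differences(vf_sets, grid_sets, assignments) -> np.ndarray:
    """Participant × location matrix of (VF − assigned-square) differences.

    NaN where the VF location or its assigned square is excluded, or the
    location is unassigned for that participant.
    """
    n_part = len(vf_sets)
    n_loc = len(vf_sets[0])
    out = np.full((n_part, n_loc), np.nan)
    for p in range(n_part):
        vf, gr, asg = vf_sets[p], grid_sets[p], assignments[p]
        if len(vf) != n_loc:
            raise ValidationError("measurement sets are not aligned across participants")
        for i in range(n_loc):
            sq = asg[i]
            if sq is None or vf.excluded[i] is not None or gr.excluded[sq] is not None:
                continue
            out[p, i] = vf.values_um[i] - gr.values_um[sq]
    return out


def run_comparison(vf_sets, grid_sets, assignments, tilts=None,
                   alpha: float = 0.05) -> ComparisonTable:
    """Pointwise cohort comparison of a VF paradigm against the 8×8 grid.

    ``assignments[p][i]`` is the grid-square index assigned to location
    ``i`` for participant ``p`` under their individual tilt (None when
    unassigned).  When ``tilts`` is given, the Spearman-vs-tilt and
    linear/quadratic tilt-model statistics are added per location.
    """
    diffs = paired_differences(vf_sets, grid_sets, assignments)
    tilts = None if tilts is None else np.asarray(tilts, dtype=float)
    rows = []
    for i in range(diffs.shape[1]):
        d = diffs[:, i]
        ok = np.isfinite(d)
        row = {"location_id": i, "n": int(ok.sum())}
        if ok.sum() == 0:
            row.update(computable=False, median_diff_um=np.nan, ci_lo_um=np.nan,
                       ci_hi_um=np.nan, p=np.nan, significant=False)
        else:
            res = wilcoxon_one_sample(d[ok])
            row.update(computable=True, median_diff_um=res.median,
                       ci_lo_um=res.ci95[0], ci_hi_um=res.ci95[1], p=res.p,
                       significant=bool(res.p < alpha))
        if tilts is not None:
            if ok.sum() >= 4:
                sp = spearman_vs_tilt(tilts[ok], d[ok])
                fit = fit_tilt_model(tilts[ok], d[ok])
                row.update(rho=sp.rho, rho_ci_lo=sp.ci95[0], rho_ci_hi=sp.ci95[1],
                           rho_p=sp.p,
                           rho_significant=bool(sp.defined and sp.p < alpha),
                           model=fit.model, f_stat=fit.f_stat, f_p=fit.f_p,
                           delta_15_0_um=fit.delta_15_0)
            else:
                row.update(rho=np.nan, rho_ci_lo=np.nan, rho_ci_hi=np.nan,
                           rho_p=np.nan, rho_significant=False, model="",
                           f_stat=np.nan, f_p=np.nan, delta_15_0_um=np.nan)
        rows.append(row)
    paradigm = vf_sets[0].paradigm if vf_sets else ""
    return ComparisonTable(pd.DataFrame(rows), paradigm, alpha)


def compare_stimulus_sizes(sets_by_size: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Pointwise Friedman tests across GII/GIII/GV measurement sets.

    ``sets_by_size`` maps paradigm name to a list of per-participant
    MeasurementSets (aligned).  Returns one row per location with the
    Friedman statistic, p, and the three Dunn-adjusted pairwise p-values.
    """
    labels = tuple(sets_by_size.keys())
    if len(labels) != 3:
        raise ValidationError("exactly 3 paradigms required")
    per = {lab: np.array([[np.nan if s.excluded[i] is not None else s.values_um[i]
                           for i in range(len(s))] for s in sets_
                          ]) for lab, sets_ in sets_by_size.items()}
    n_loc = next(iter(per.values())).shape[1]
    rows = []
    for i in range(n_loc):
        mat = np.column_stack([per[lab][:, i] for lab in labels])
        res = friedman_across_sizes(mat, labels=labels)
        row = {"location_id": i, "n": res.n, "chi2": res.chi2, "p": res.p,
               "computable": res.computable,
               "significant": bool(res.computable and res.p < alpha)}
        for pair, pv in res.posthoc.items():
            row[f"p_{pair[0]}_vs_{pair[1]}"] = pv
        rows.append(row)
    return pd.DataFrame(rows)
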