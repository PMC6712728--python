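"""Validation statistics: regressions, correlations, agreement, power.

Reproduces the analysis framework used to validate the automatic B-line
score against extravascular lung water (EVLW):

- simple linear regression (OLS) of EVLW on each score;
- robust linear regression: Huber M, least median of squares (LMS), least
  trimmed squares (LTS), least absolute deviation (LAD), S and MM
  estimators;
- tie-corrected Spearman rank correlations between scores;
- comparison of dependent overlapping correlations (Dunn & Clark's z with
  Hittner, May and Silver's backtransformed-average modification);
- two-way absolute-agreement intraclass correlation (single measure by
  default) with F-based 95% confidence intervals and categorical strength
  labels;
- analytic power of the two-sided test of zero correlation (Fisher-z
  approximation with small-sample bias term and t-based critical value).

R-squared conventions for robust fits differ by estimator family and are
always surfaced in the fit metadata; see the individual functions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import atanh, sqrt, tanh

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError

ESTIMATORS = ("ols", "huber", "lms", "lts", "lad", "s", "mm")

#: Tukey-biweight tuning constant for 50% breakdown (S-estimator) and the
#: matching consistency constant b = E[rho_c(Z)] under the standard normal.
_TUKEY_C_S = 1.547645
_TUKEY_B_S = 0.1995
#: Tukey-biweight constant for 85% Gaussian efficiency (MM final M-step).
_TUKEY_C_MM = 3.443689
#: Huber tuning constant (95% Gaussian efficiency).
_HUBER_K = 1.345


# ---------------------------------------------------------------------------
# result containers


@dataclass
class RegressionFit:
    estimator: str
    slope: float
    intercept: float
    r_squared: float
    n: int
    p_value: float | None = None  # OLS slope test only
    subset_size: int | None = None  # LTS/LMS retained h
    metadata: dict = field(default_factory=dict)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    tie_corrected: bool = True


@dataclass
class CorrelationComparison:
    r12: float
    r13: float
    r23: float
    n: int
    z_statistic: float
    p_value: float


@dataclass
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    model: str
    strength_label: str
    mean_squares: dict = field(default_factory=dict)


@dataclass
class PowerResult:
    r: float
    n: int
    alpha: float
    power: float


@dataclass
class RaterTable:
    """Complete subjects x raters score matrix."""

    scores: np.ndarray
    rater_names: tuple[str, ...] | None = None
    true_icc: float | None = None  # attached by simulators

    def __post_init__(self) -> None:
        sc = np.asarray(self.scores, dtype=float)
        if sc.ndim != 2:
            raise AnalysisError("rater table must be 2-D (subjects x raters)")
        if np.isnan(sc).any():
            raise AnalysisError("rater table has missing cells; no imputation is done")
        self.scores = sc

    @property
    def n_subjects(self) -> int:
        return self.scores.shape[0]

    @property
    def n_raters(self) -> int:
        return self.scores.shape[1]


# ---------------------------------------------------------------------------
# regression


def _as_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("x and y must be 1-D vectors of equal length")
    if x.size < 3:
        raise AnalysisError(f"need n >= 3 observations, got {x.size}")
    if np.ptp(x) == 0:
        raise AnalysisError("design is singular: predictor is constant")
    return x, y


def fit_slr(x, y) -> RegressionFit:
    """Ordinary least squares of y on x.

    ``r_squared`` is 1 - SS_res/SS_tot; the slope p-value comes from the t
    distribution with n - 2 degrees of freedom.
    """
    x, y = _as_xy(x, y)
    res = sps.linregress(x, y)
    return RegressionFit(
        estimator="ols",
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        n=x.size,
        metadata={"r_squared_definition": "1 - SS_res/SS_tot on all observations"},
    )


def _ols_line(x, y):
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    return slope, ym - slope * xm


def _trimmed_r2(x, y, slope, intercept, h):
    """R^2 on the h observations best fitted by the line.

    SS_tot is taken about the mean of the retained responses; emitted in
    metadata by the trimmed estimators.
    """
    res2 = (y - intercept - slope * x) ** 2
    keep = np.argsort(res2, kind="stable")[:h]
    yk = y[keep]
    ss_res = float(res2[keep].sum())
    ss_tot = float(np.sum((yk - yk.mean()) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0, keep
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot)), keep


def _r2_all(x, y, slope, intercept):
    ss_res = float(np.sum((y - intercept - slope * x) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


def lts_subset_size(n: int, p: int = 2) -> int:
    """Default LTS coverage h = floor((n + p + 1) / 2) (50% breakdown)."""
    return (n + p + 1) // 2


def _fit_lts(x, y, seed):
    n = x.size
    h = lts_subset_size(n)
    best = (np.inf, 0.0, 0.0)
    if n <= 20:
        # the LTS minimizer is the OLS fit of the h-subset with smallest own
        # RSS, so exhaustive enumeration of h-subsets is exact
        for idx in combinations(range(n), h):
            idx = np.asarray(idx)
            slope, intercept = _ols_line(x[idx], y[idx])
            rss = float(np.sum((y[idx] - intercept - slope * x[idx]) ** 2))
            if rss < best[0]:
                best = (rss, slope, intercept)
        method = "exhaustive"
    else:
        # FAST-LTS style: random elemental starts + C-steps to convergence
        rng = np.random.default_rng(seed)
        for _ in range(500):
            i, j = rng.choice(n, size=2, replace=False)
            if x[i] == x[j]:
                continue
            slope = (y[j] - y[i]) / (x[j] - x[i])
            intercept = y[i] - slope * x[i]
            prev = None
            for _ in range(50):
                res2 = (y - intercept - slope * x) ** 2
                keep = np.argsort(res2, kind="stable")[:h]
                if prev is not None and np.array_equal(keep, prev):
                    break
                prev = keep
                slope, intercept = _ols_line(x[keep], y[keep])
            rss = float(np.sum((y[keep] - intercept - slope * x[keep]) ** 2))
            if rss < best[0]:
                best = (rss, slope, intercept)
        method = "random-cstep"
    _, slope, intercept = best
    r2, keep = _trimmed_r2(x, y, slope, intercept, h)
    return slope, intercept, r2, h, keep, method


def _fit_lms(x, y, seed):
    """Least median of squares via elemental-pair search.

    Minimizes the h-th smallest squared residual with h = floor(n/2) +
    floor((p+1)/2), the standard finite-sample definition of the median for
    this estimator.
    """
    n = x.size
    h = n // 2 + 1  # floor(n/2) + floor((p+1)/2) with p = 2
    pairs = combinations(range(n), 2)
    if n > 20:
        rng = np.random.default_rng(seed)
        pairs = (tuple(rng.choice(n, 2, replace=False)) for _ in range(1000))
    best = (np.inf, 0.0, 0.0)
    for i, j in pairs:
        if x[i] == x[j]:
            continue
        slope = (y[j] - y[i]) / (x[j] - x[i])
        intercept = y[i] - slope * x[i]
        res2 = np.sort((y - intercept - slope * x) ** 2, kind="stable")
        obj = float(res2[h - 1])
        if obj < best[0]:
            best = (obj, slope, intercept)
    _, slope, intercept = best
    r2, keep = _trimmed_r2(x, y, slope, intercept, h)
    return slope, intercept, r2, h, keep


def _tukey_rho(u, c):
    v = np.clip(u / c, -1, 1)
    return (c**2 / 6) * (1 - (1 - v**2) ** 3)


def _tukey_weight(u, c):
    w = (1 - (u / c) ** 2) ** 2
    return np.where(np.abs(u) <= c, w, 0.0)


def _m_scale(res, c=_TUKEY_C_S, b=_TUKEY_B_S):
    s = np.median(np.abs(res)) / 0.6745
    if s == 0:
        return 0.0
    for _ in range(100):
        new = s * sqrt(float(np.mean(_tukey_rho(res / s, c))) / b)
        if abs(new - s) <= 1e-12 * s:
            return new
        s = new
    return s


def _irwls(x, y, slope, intercept, scale, c, max_iter=100):
    for _ in range(max_iter):
        res = y - intercept - slope * x
        w = _tukey_weight(res / scale, c)
        if w.sum() == 0:
            break
        sw = np.sqrt(w)
        X = np.column_stack([np.ones_like(x), x]) * sw[:, None]
        beta, *_ = np.linalg.lstsq(X, y * sw, rcond=None)
        new_i, new_s = float(beta[0]), float(beta[1])
        if abs(new_s - slope) < 1e-10 and abs(new_i - intercept) < 1e-10:
            slope, intercept = new_s, new_i
            break
        slope, intercept = new_s, new_i
    return slope, intercept


def _fit_s(x, y, seed):
    """S-estimator: minimize the Tukey M-scale of residuals (50% breakdown).

    Candidate lines come from elemental pairs (exhaustive for n <= 20, else
    a seeded random sample), followed by IRWLS refinement at the best
    candidate's scale.
    """
    n = x.size
    pairs = combinations(range(n), 2)
    if n > 20:
        rng = np.random.default_rng(seed)
        pairs = (tuple(rng.choice(n, 2, replace=False)) for _ in range(500))
    best = (np.inf, 0.0, 0.0)
    for i, j in pairs:
        if x[i] == x[j]:
            continue
        slope = (y[j] - y[i]) / (x[j] - x[i])
        intercept = y[i] - slope * x[i]
        s = _m_scale(y - intercept - slope * x)
        if s < best[0]:
            best = (s, slope, intercept)
    scale, slope, intercept = best
    if scale > 0:
        for _ in range(20):  # alternate refinement: IRWLS step + rescale
            slope, intercept = _irwls(x, y, slope, intercept, scale, _TUKEY_C_S, max_iter=1)
            new_scale = _m_scale(y - intercept - slope * x)
            if new_scale >= scale - 1e-12 * max(scale, 1.0):
                break
            scale = new_scale
    return slope, intercept, scale


def _weighted_r2(x, y, slope, intercept, scale, c):
    """Robustness-weighted R^2 in [0, 1] (convention for M/S/MM fits)."""
    res = y - intercept - slope * x
    if scale == 0:
        return 1.0
    w = _tukey_weight(res / scale, c)
    if w.sum() == 0:
        return 0.0
    ybar = float(np.average(y, weights=w)) if w.sum() > 0 else y.mean()
    ss_res = float(np.sum(w * res**2))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return max(0.0, min(1.0, 1.0 - ss_res / ss_tot))


def fit_robust(x, y, estimator: str = "lts", seed: int | None = 0) -> RegressionFit:
    """Robust linear regression of y on x.

    Estimators: ``huber`` (M-estimation, k = 1.345), ``lad`` (median
    regression), ``lms`` (least median of squares, elemental-pair search),
    ``lts`` (least trimmed squares, h = floor((n+p+1)/2), exhaustive for
    n <= 20, seeded C-step search otherwise), ``s`` (50%-breakdown Tukey
    S-estimator) and ``mm`` (MM: S start + 85%-efficiency bisquare M-step).

    ``r_squared`` conventions, always named in ``metadata``: trimmed R^2 on
    the h retained observations for LTS/LMS (the OLS-style R^2 on all points
    is also emitted as ``r_squared_all``); robustness-weighted R^2 for
    Huber/S/MM; the L1 analogue 1 - sum|res| / sum|y - median(y)| for LAD.
    """
    x, y = _as_xy(x, y)
    n = x.size
    if estimator not in ESTIMATORS:
        raise AnalysisError(f"unknown estimator {estimator!r}; expected one of {ESTIMATORS}")
    if estimator == "ols":
        return fit_slr(x, y)

    if estimator in ("lts", "lms"):
        if n < lts_subset_size(n) or n < 4:
            raise AnalysisError(f"n = {n} too small for the trimming subset size")
        if estimator == "lts":
            slope, intercept, r2, h, keep, method = _fit_lts(x, y, seed)
            meta_method = method
        else:
            slope, intercept, r2, h, keep = _fit_lms(x, y, seed)
            meta_method = "elemental-pairs" if n <= 20 else "random-pairs"
        return RegressionFit(
            estimator=estimator,
            slope=float(slope),
            intercept=float(intercept),
            r_squared=float(r2),
            n=n,
            subset_size=h,
            metadata={
                "r_squared_definition": (
                    "trimmed R^2: 1 - SS_res(h)/SS_tot(h) on the h retained observations"
                ),
                "r_squared_all": _r2_all(x, y, slope, intercept),
                "retained_indices": [int(i) for i in keep],
                "search": meta_method,
            },
        )

    if estimator == "huber":
        import statsmodels.api as sm

        X = sm.add_constant(x)
        fit = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=_HUBER_K)).fit()
        slope, intercept = float(fit.params[1]), float(fit.params[0])
        res = y - fit.fittedvalues
        try:
            w = np.asarray(fit.weights, dtype=float)
        except AttributeError:  # perfect fit: scale 0, no final weights kept
            w = np.ones_like(y)
        ybar = float(np.average(y, weights=w))
        ss_res = float(np.sum(w * res**2))
        ss_tot = float(np.sum(w * (y - ybar) ** 2))
        r2 = max(0.0, min(1.0, 1.0 - ss_res / ss_tot)) if ss_tot > 0 else 1.0
        return RegressionFit(
            estimator="huber", slope=slope, intercept=intercept, r_squared=r2, n=n,
            metadata={
                "tuning_k": _HUBER_K,
                "r_squared_definition": "IRLS-weighted R^2",
                "r_squared_all": _r2_all(x, y, slope, intercept),
            },
        )

    if estimator == "lad":
        import statsmodels.api as sm

        X = sm.add_constant(x)
        fit = sm.QuantReg(y, X).fit(q=0.5)
        slope, intercept = float(fit.params[1]), float(fit.params[0])
        abs_res = float(np.sum(np.abs(y - intercept - slope * x)))
        abs_tot = float(np.sum(np.abs(y - np.median(y))))
        r2 = max(0.0, min(1.0, 1.0 - abs_res / abs_tot)) if abs_tot > 0 else 1.0
        return RegressionFit(
            estimator="lad", slope=slope, intercept=intercept, r_squared=r2, n=n,
            metadata={
                "r_squared_definition": "L1 analogue: 1 - sum|res|/sum|y - median(y)|",
                "r_squared_all": _r2_all(x, y, slope, intercept),
            },
        )

    # s / mm
    slope, intercept, scale = _fit_s(x, y, seed)
    if estimator == "s":
        r2 = _weighted_r2(x, y, slope, intercept, scale, _TUKEY_C_S)
        return RegressionFit(
            estimator="s", slope=float(slope), intercept=float(intercept),
            r_squared=r2, n=n,
            metadata={
                "tuning_c": _TUKEY_C_S, "scale": float(scale),
                "r_squared_definition": "robustness-weighted R^2",
                "r_squared_all": _r2_all(x, y, slope, intercept),
            },
        )
    if scale > 0:
        slope, intercept = _irwls(x, y, slope, intercept, scale, _TUKEY_C_MM)
    r2 = _weighted_r2(x, y, slope, intercept, scale, _TUKEY_C_MM)
    return RegressionFit(
        estimator="mm", slope=float(slope), intercept=float(intercept), r_squared=r2, n=n,
        metadata={
            "tuning_c": _TUKEY_C_MM, "efficiency": 0.85, "scale": float(scale),
            "r_squared_definition": "robustness-weighted R^2",
            "r_squared_all": _r2_all(x, y, slope, intercept),
        },
    )


# ---------------------------------------------------------------------------
# correlation


def spearman(x, y, exact: bool = False) -> CorrelationResult:
    """Tie-corrected Spearman rank correlation.

    Midranks for ties; r is the Pearson correlation of the rank vectors; the
    two-sided p-value uses the t approximation with n - 2 degrees of freedom
    (or the exact permutation distribution for ``exact=True``, n <= 8).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n or n < 4:
        raise AnalysisError("need two equal-length vectors with n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise AnalysisError("correlation undefined for a constant vector")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    r = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 8:
            raise AnalysisError("exact permutation p-value supported for n <= 8 only")
        from itertools import permutations

        count = total = 0
        for perm in permutations(range(n)):
            rp = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
            total += 1
            if abs(rp) >= abs(r) - 1e-12:
                count += 1
        p = count / total
    elif abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * sqrt((n - 2) / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), n - 2))
    return CorrelationResult(r=r, p_value=p, n=n, tie_corrected=True)


def compare_dependent_correlations(
    r12: float, r13: float, r23: float, n: int
) -> CorrelationComparison:
    """Dunn & Clark's z for two dependent overlapping correlations.

    Tests r12 = r13 where both correlations share variable 1, using the
    Hittner/May/Silver modification: the covariance term uses the
    backtransformed average of the Fisher transforms of r12 and r13.
    Two-sided normal p-value.
    """
    if n < 4:
        raise AnalysisError("need n >= 4")
    for r in (r12, r13, r23):
        if not -1 <= r <= 1:
            raise AnalysisError(f"correlation {r} outside [-1, 1]")
    if abs(r12) >= 1 or abs(r13) >= 1:
        raise AnalysisError("|r| = 1 overflows the Fisher transform")
    z12, z13 = atanh(r12), atanh(r13)
    rbar = tanh((z12 + z13) / 2.0)
    cov = (r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)) / (
        (1 - rbar**2) ** 2
    )
    z = (z12 - z13) * sqrt((n - 3) / (2.0 * (1.0 - cov)))
    p = float(2 * sps.norm.sf(abs(z)))
    return CorrelationComparison(r12=r12, r13=r13, r23=r23, n=n, z_statistic=float(z), p_value=p)


# ---------------------------------------------------------------------------
# agreement


def strength_label(icc: float) -> str:
    """Categorical agreement strength of an ICC point estimate.

    Cut-points (lower bound inclusive): < 0.30 poor, 0.30-0.49 fair,
    0.50-0.69 moderate, 0.70-0.89 strong, >= 0.90 almost perfect.
    """
    if icc < 0.30:
        return "poor"
    if icc < 0.50:
        return "fair"
    if icc < 0.70:
        return "moderate"
    if icc < 0.90:
        return "strong"
    return "almost_perfect"


def icc_agreement(
    table: RaterTable, measure: str = "single", alpha: float = 0.05
) -> ICCResult:
    """Two-way absolute-agreement intraclass correlation with 95% CI.

    Single-measure form (each rater contributes one score) by default; the
    average-measure form is available with ``measure="average"``.  Mean
    squares come from the two-way crossed decomposition (subjects, raters,
    error); the confidence interval uses the F-based method with a
    Satterthwaite degrees-of-freedom approximation.
    """
    if measure not in ("single", "average"):
        raise AnalysisError("measure must be 'single' or 'average'")
    Y = table.scores
    n, k = Y.shape
    if n < 5 or k < 2:
        raise AnalysisError("need >= 5 subjects and >= 2 raters")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((Y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc1 = (msr - mse) / denom if denom > 0 else 1.0

    if 1 - icc1 < 1e-12 or mse == 0:
        lo = hi = icc1  # degenerate (perfect agreement): the CI collapses
    else:
        a = (k * icc1) / (n * (1 - icc1))
        b = 1 + (k * icc1 * (n - 1)) / (n * (1 - icc1))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (
            f_l * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_u * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_u * msr
        )
    if measure == "average":
        def _avg(r):
            return r * k / (1 + (k - 1) * r) if (1 + (k - 1) * r) != 0 else 1.0

        icc1, lo, hi = _avg(icc1), _avg(lo), _avg(hi)
        model = "two-way agreement, average measures"
    else:
        model = "two-way agreement, single measures"
    icc1 = float(icc1)
    return ICCResult(
        icc=icc1,
        ci_low=float(min(lo, icc1)),
        ci_high=float(max(hi, icc1)),
        model=model,
        strength_label=strength_label(icc1),
        mean_squares={"msr": float(msr), "msc": float(msc), "mse": float(mse)},
    )


# ---------------------------------------------------------------------------
# power


def power_correlation(r: float, n: int, alpha: float = 0.05) -> PowerResult:
    """Analytic power of the two-sided test of zero correlation.

    Fisher-z approximation with the small-sample bias term: the hypothesized
    correlation maps to z_r = atanh(r) + r / (2(n-1)); the critical
    correlation r_c comes from the t quantile at n - 2 degrees of freedom;
    power = Phi((z_r - atanh(r_c)) * sqrt(n - 3)).
    """
    if not 0 < r < 1:
        raise AnalysisError("hypothesized r must be in (0, 1)")
    if n < 4:
        raise AnalysisError("need n >= 4")
    if not 0 < alpha < 1:
        raise AnalysisError("alpha must be in (0, 1)")
    z_r = atanh(r) + r / (2 * (n - 1))
    t_crit = sps.t.ppf(1 - alpha / 2, n - 2)
    r_c = sqrt(t_crit**2 / (t_crit**2 + n - 2))
    power = float(sps.norm.cdf((z_r - atanh(r_c)) * sqrt(n - 3)))
    return PowerResult(r=r, n=n, alpha=alpha, power=power)


# ---------------------------------------------------------------------------
# sweeps over the validation table


def score_evlw_regressions(
    table: pd.DataFrame, estimator: str = "ols", seed: int | None = 0
) -> dict[str, RegressionFit]:
    """Regress EVLW on each score column of a per-patient score table."""
    from .datasets import SCORE_COLUMNS

    out = {}
    for col in SCORE_COLUMNS:
        if estimator == "ols":
            out[col] = fit_slr(table[col], table["EVLW"])
        else:
            out[col] = fit_robust(table[col], table["EVLW"], estimator, seed)
    return out


def qluss_correlations(table: pd.DataFrame) -> dict[str, CorrelationResult]:
    """Spearman correlation of the automatic score with each comparator."""
    return {
        col: spearman(table["QLUSS"], table[col])
        for col in ("qLUSS", "%LUSS", "cLUSS", "nLUSS")
    }
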