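"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a :class:`~mrkit.summary_io.HarmonizedSet` and return
an :class:`MREstimate` carrying the causal slope theta (log-OR of outcome
per unit of exposure liability for binary traits), its SE, a 95% CI, a
two-sided p-value, and the exponentiated (odds-ratio) scale.

Methods
-------
wald_ratio
    Per-variant ratio beta_Y / beta_X with first-order delta-method SE.
ivw
    Inverse-variance-weighted mean of the ratios; fixed-effect SE, or
    multiplicative-random-effects SE inflated by max(1, sqrt(Q/(L-1))).
mr_egger
    Weighted regression of beta_Y on beta_X with a free intercept; the
    intercept estimates directional pleiotropy.
weighted_median
    Weighted 50% point of the ordered ratios; consistent when >= 50% of the
    weight comes from valid instruments.  SE by parametric bootstrap.
mode_estimator
    Argmax of a kernel-smoothed density of the ratios (simple or
    inverse-variance weighted); SE by parametric bootstrap.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import HarmonizedRecord, HarmonizedSet

Z95 = 1.96  # normal 95% multiplier used for all reported intervals


@dataclass
class MREstimate:
    method: str
    n_snp: int
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    or_: float
    or_low: float
    or_high: float


@dataclass
class EggerFit:
    """MR-Egger slope estimate plus the pleiotropy intercept."""

    slope: MREstimate
    intercept: float
    intercept_se: float
    intercept_pval: float


def to_or_scale(theta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds slope and its 95% Wald limits."""
    if se <= 0:
        raise ValueError("se must be positive")
    return (
        float(np.exp(theta)),
        float(np.exp(theta - Z95 * se)),
        float(np.exp(theta + Z95 * se)),
    )


def _estimate(method: str, n_snp: int, theta: float, se: float, df: int | None = None) -> MREstimate:
    """Assemble an MREstimate; p two-sided normal, or t(df) when df given."""
    if df is None:
        pval = 2.0 * stats.norm.sf(abs(theta) / se) if se > 0 else (1.0 if theta == 0 else 0.0)
    else:
        pval = 2.0 * stats.t.sf(abs(theta) / se, df) if se > 0 else (1.0 if theta == 0 else 0.0)
    or_, lo, hi = to_or_scale(theta, se) if se > 0 else (np.exp(theta),) * 3
    return MREstimate(
        method=method,
        n_snp=n_snp,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z95 * se),
        ci_high=float(theta + Z95 * se),
        pval=float(pval),
        or_=float(or_),
        or_low=float(lo),
        or_high=float(hi),
    )


def _ratios(hs: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant Wald ratios and their first-order SEs."""
    bx = np.array([r.beta_exposure for r in hs.records], dtype=float)
    by = np.array([r.beta_outcome for r in hs.records], dtype=float)
    sy = np.array([r.se_outcome for r in hs.records], dtype=float)
    if np.any(bx == 0):
        raise ValueError("zero exposure beta: Wald ratio undefined")
    return by / bx, sy / np.abs(bx)


def wald_ratio(record: HarmonizedRecord) -> MREstimate:
    """Single-variant causal estimate beta_Y / beta_X.

    The SE is the first-order delta approximation se_Y / |beta_X|, which
    ignores the uncertainty in beta_X — the dominant convention when
    instruments are strong.
    """
    if record.beta_exposure == 0:
        raise ValueError("zero exposure beta: Wald ratio undefined")
    theta = record.beta_outcome / record.beta_exposure
    se = record.se_outcome / abs(record.beta_exposure)
    return _estimate("wald", 1, theta, se)


def ivw(hs: HarmonizedSet, effects_model: str = "mre") -> MREstimate:
    """Inverse-variance-weighted estimate over all retained variants.

    ``effects_model='fe'`` gives the fixed-effect SE (Sum w)^-1/2;
    ``'mre'`` multiplies it by max(1, sqrt(Q/(L-1))) where Q is Cochran's
    Q, so the random-effects SE is never smaller than the fixed-effect one.
    The point estimate is identical under both models.
    """
    if effects_model not in ("fe", "mre"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    if len(hs) < 2:
        raise ValueError("ivw requires at least 2 variants")
    theta_j, se_j = _ratios(hs)
    w = 1.0 / se_j**2
    theta = float(np.sum(w * theta_j) / np.sum(w))
    se_fe = float(np.sum(w) ** -0.5)
    if effects_model == "fe":
        return _estimate("ivw_fe", len(hs), theta, se_fe)
    q = float(np.sum(w * (theta_j - theta) ** 2))
    scale = max(1.0, np.sqrt(q / (len(hs) - 1)))
    return _estimate("ivw_mre", len(hs), theta, se_fe * scale)


def _oriented(hs: HarmonizedSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(beta_X, beta_Y, se_Y) with every record oriented so beta_X >= 0."""
    bx = np.array([r.beta_exposure for r in hs.records], dtype=float)
    by = np.array([r.beta_outcome for r in hs.records], dtype=float)
    sy = np.array([r.se_outcome for r in hs.records], dtype=float)
    sign = np.where(bx < 0, -1.0, 1.0)
    return bx * sign, by * sign, sy


def mr_egger(hs: HarmonizedSet) -> EggerFit:
    """Egger regression: WLS of beta_Y on beta_X with a free intercept.

    Records are first oriented so every beta_X >= 0 (flipping beta_Y with
    it), weights are 1/se_Y², and both SEs carry the multiplicative
    overdispersion scale max(1, sqrt(RSS_w / (L-2))).  P-values use
    t(L-2).  A nonzero intercept indicates directional pleiotropy; the
    slope is a pleiotropy-adjusted causal estimate under the InSIDE
    assumption.
    """
    L = len(hs)
    if L < 3:
        raise ValueError("mr_egger requires at least 3 variants")
    bx, by, sy = _oriented(hs)
    if np.allclose(bx, bx[0]):
        raise ValueError("mr_egger requires variation in the exposure betas")
    import statsmodels.api as sm

    X = sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=1.0 / sy**2).fit()
    # unit covariance (X'WX)^-1 scaled by the floored overdispersion factor,
    # so exact-fit data (RSS=0) falls back to the fixed-effect SE
    sigma2 = float(fit.mse_resid)
    unit_se = np.sqrt(np.diag(fit.normalized_cov_params))
    scale = np.sqrt(max(1.0, sigma2))
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    se_int, se_slope = float(unit_se[0]) * scale, float(unit_se[1]) * scale
    slope_est = _estimate("egger", L, slope, se_slope, df=L - 2)
    int_p = 2.0 * stats.t.sf(abs(intercept) / se_int, L - 2)
    return EggerFit(slope=slope_est, intercept=intercept, intercept_se=se_int, intercept_pval=float(int_p))


def _weighted_median(theta_sorted: np.ndarray, w_sorted: np.ndarray) -> float:
    """Interpolated weighted median of pre-sorted ratio estimates."""
    wn = w_sorted / w_sorted.sum()
    p = np.cumsum(wn) - wn / 2.0
    return float(np.interp(0.5, p, theta_sorted))


def weighted_median(hs: HarmonizedSet, n_boot: int = 1000, seed: int | None = 0) -> MREstimate:
    """Weighted-median causal estimate with parametric-bootstrap SE.

    The point estimate interpolates the ordered ratios against their
    cumulative weight midpoints at 0.5.  The SE is the standard deviation
    of the estimate over ``n_boot`` replicates in which each ratio is
    resampled from Normal(theta_j, se_j) with the weights held fixed.
    """
    if len(hs) < 3:
        raise ValueError("weighted_median requires at least 3 variants")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    theta_j, se_j = _ratios(hs)
    w = 1.0 / se_j**2
    order = np.argsort(theta_j)
    point = _weighted_median(theta_j[order], w[order])
    se = _bootstrap_se(theta_j, se_j, w, n_boot, seed, _weighted_median)
    return _estimate("weighted_median", len(hs), point, se)


def _bootstrap_se(theta_j, se_j, w, n_boot, seed, statistic) -> float:
    rng = np.random.default_rng(seed)
    draws = theta_j + se_j * rng.standard_normal((n_boot, theta_j.size))
    order = np.argsort(draws, axis=1)
    ts = np.take_along_axis(draws, order, axis=1)
    ws = w[order]
    vals = np.array([statistic(ts[i], ws[i]) for i in range(n_boot)])
    return float(vals.std(ddof=1))


def _mode_point(theta_sorted: np.ndarray, w_sorted: np.ndarray, bandwidth_factor: float, grid_size: int = 512) -> float:
    """Argmax of a weighted normal-kernel density of the ratios."""
    theta = theta_sorted
    L = theta.size
    s = np.std(theta, ddof=1)
    mad = stats.median_abs_deviation(theta, scale="normal")
    spread = min(x for x in (s, mad) if x > 0) if (s > 0 or mad > 0) else 0.0
    if spread == 0.0:  # point mass
        return float(theta[0])
    h = bandwidth_factor * 0.9 * spread * L ** (-1.0 / 5.0)
    grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, grid_size)
    dens = np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2) @ w_sorted
    return float(grid[int(np.argmax(dens))])


def mode_estimator(
    hs: HarmonizedSet,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = 0,
) -> MREstimate:
    """Mode-based causal estimate (simple or inverse-variance weighted).

    The ratio estimates are kernel-smoothed (normal kernel, modified
    Silverman bandwidth scaled by ``bandwidth_factor``) and the estimate is
    the density argmax; the weighted variant weights each ratio by
    1/se_j².  SE by the same parametric bootstrap as the weighted median.
    """
    if len(hs) < 3:
        raise ValueError("mode_estimator requires at least 3 variants")
    if bandwidth_factor <= 0:
        raise ValueError("bandwidth_factor must be positive")
    theta_j, se_j = _ratios(hs)
    w = 1.0 / se_j**2 if weighted else np.ones_like(theta_j)
    order = np.argsort(theta_j)
    stat = lambda t, ww: _mode_point(t, ww, bandwidth_factor)  # noqa: E731
    point = stat(theta_j[order], w[order])
    se = _bootstrap_se(theta_j, se_j, w, n_boot, seed, stat)
    method = "weighted_mode" if weighted else "simple_mode"
    return _estimate(method, len(hs), point, se)


def all_estimates(
    hs: HarmonizedSet,
    n_boot: int = 1000,
    seed: int | None = 0,
    bandwidth_factor: float = 1.0,
) -> list[MREstimate]:
    """The full six-method suite on one harmonized set."""
    egger = mr_egger(hs)
    return [
        ivw(hs, "fe"),
        ivw(hs, "mre"),
        egger.slope,
        weighted_median(hs, n_boot=n_boot, seed=seed),
        mode_estimator(hs, weighted=False, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed),
        mode_estimator(hs, weighted=True, bandwidth_factor=bandwidth_factor, n_boot=n_boot, seed=seed),
    ]


def results_table(hs: HarmonizedSet, estimates: list[MREstimate]) -> pd.DataFrame:
    """One row per method, in the layout of a forest-plot results table."""
    return pd.DataFrame(
        [
            {
                "exposure": hs.exposure_label,
                "outcome": hs.outcome_label,
                "method": e.method,
                "nsnp": e.n_snp,
                "b": e.theta,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "pval": e.pval,
                "or": e.or_,
                "or_lci95": e.or_low,
                "or_uci95": e.or_high,
            }
            for e in estimates
        ]
    )
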