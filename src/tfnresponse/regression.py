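"""Uncertainty-aware fitting statistics.

Implements the regression conventions used throughout the pipeline:

* :class:`McOLS` — ordinary least squares on data points with known y
  uncertainties (SEM), where each of the N points is expanded into m Monte
  Carlo draws from Normal(y, sem).  P-value_1 tests the null that a constant
  (horizontal) model fits as well as the line; P-value_2 (when N > 3) tests
  the x^2 coefficient of a quadratic against 0.  Both use degrees of freedom
  based on N, never N·m — the expansion represents measurement uncertainty,
  not extra observations.  The 68.2% confidence band is taken from pointwise
  quantiles over the per-draw fitted lines.
* :func:`null_model_fit` — a pairing-destroyed null regression: repeated
  without-replacement subsamples of independently permuted x and y, pooled
  into one OLS whose p-values are corrected to df = size_XY − C.
* :class:`SigmoidModel` — 4-parameter logistic fit of a noisy time series by
  Monte Carlo resampling of each point from Normal(y, sem).
* :func:`ancova_compare` — ANCOVA test of whether two fitted lines share
  slope and intercept.
* basic two-sample t/KS, one-sample Z and Fisher exact tests, all decided at
  the 10% significance level, and first-order error propagation for the
  abundance/area concentration ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

__all__ = [
    "ALPHA",
    "McOLS",
    "McOLSResults",
    "mc_ols",
    "null_model_fit",
    "SigmoidModel",
    "SigmoidResults",
    "sigmoid_mc_fit",
    "logistic4",
    "ancova_compare",
    "t_test_2sample",
    "ks_test_2sample",
    "z_test_1sample",
    "fisher_test",
    "relative_concentration",
]

#: Significance level used for every hypothesis decision in the pipeline.
ALPHA = 0.10

#: Number of Monte Carlo draws representing each uncertain data point.
MC_DRAWS = 1000


@dataclass
class McOLSResults:
    """Linear fit of uncertain points with MC-expanded confidence band.

    ``p_value_1`` — t-test of the slope against the degenerate constant-only
    model (df = N − 2); reject the horizontal line when < 0.1.
    ``p_value_2`` — t-test of the quadratic term (df = N − 3; None for
    N ≤ 3); reject the linear model in favour of the quadratic when < 0.1.
    """

    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    rmse: float
    p_value_1: float
    p_value_2: float | None
    n: int
    df_resid: int
    _draw_slopes: np.ndarray = field(repr=False, default=None)
    _draw_intercepts: np.ndarray = field(repr=False, default=None)

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, float)

    def conf_band(self, x, level: float = 0.682) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise confidence band from the per-draw fitted lines."""
        x = np.asarray(x, float)
        lines = self._draw_intercepts[:, None] + self._draw_slopes[:, None] * x[None, :]
        lo = np.quantile(lines, (1 - level) / 2, axis=0)
        hi = np.quantile(lines, 1 - (1 - level) / 2, axis=0)
        fit = self.predict(x)
        return np.minimum(lo, fit), np.maximum(hi, fit)

    def summary(self) -> str:
        lines = [
            "MC-expanded OLS fit",
            f"  n points:   {self.n}  (df = {self.df_resid})",
            f"  slope:      {self.slope:+.6g} +/- {self.slope_se:.3g}",
            f"  intercept:  {self.intercept:+.6g}",
            f"  R^2:        {self.r_squared:.4f}   RMSE: {self.rmse:.4g}",
            f"  P-value_1 (line vs constant):   {self.p_value_1:.4g}",
        ]
        if self.p_value_2 is not None:
            lines.append(f"  P-value_2 (quadratic term = 0): {self.p_value_2:.4g}")
        return "\n".join(lines)

    def plot(self, ax=None, band: bool = True, **scatter_kw):
        """Scatter + fitted line + 68.2% band on a matplotlib axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xs = np.linspace(float(np.min(self._x)), float(np.max(self._x)), 100)
        ax.errorbar(self._x, self._y, yerr=self._sem, fmt="o", **scatter_kw)
        ax.plot(xs, self.predict(xs), color="C3")
        if band:
            lo, hi = self.conf_band(xs)
            ax.fill_between(xs, lo, hi, alpha=0.3, color="C3")
        return ax


class McOLS:
    """Linear model for N uncertain points (x exact, y with SEM).

    Each point's y uncertainty is represented by *m* random draws from
    Normal(y, sem); the line is the OLS fit of the resulting cloud (which,
    with a common x per point, equals OLS on the per-point draw means).
    With all SEMs zero this reduces exactly to textbook OLS on the N points.
    """

    def __init__(self, x: Sequence[float], y: Sequence[float],
                 y_sem: Sequence[float] | None = None):
        self.x = np.asarray(x, float)
        self.y = np.asarray(y, float)
        self.y_sem = (np.zeros_like(self.y) if y_sem is None
                      else np.asarray(y_sem, float))
        if self.x.shape != self.y.shape or self.x.shape != self.y_sem.shape:
            raise ValueError("x, y and y_sem must have equal length")
        if (self.y_sem < 0).any():
            raise ValueError("y_sem must be non-negative")
        if len(self.x) < 3:
            raise ValueError("at least 3 points are required")
        if np.ptp(self.x) == 0:
            raise ValueError("x is constant; the fit is degenerate")

    def fit(self, m: int = MC_DRAWS, seed: int | None = None) -> McOLSResults:
        rng = np.random.default_rng(seed)
        n = len(self.x)
        draws = self.y[:, None] + self.y_sem[:, None] * rng.standard_normal((n, m))
        ybar = draws.mean(axis=1)

        X = sm.add_constant(self.x)
        ols = sm.OLS(ybar, X).fit()
        intercept, slope = ols.params
        resid = ybar - ols.fittedvalues
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        p1 = float(ols.pvalues[1])

        p2 = None
        if n > 3:
            X2 = np.column_stack([np.ones(n), self.x, self.x ** 2])
            ols2 = sm.OLS(ybar, X2).fit()
            p2 = float(ols2.pvalues[2])

        # per-draw lines (vectorized simple OLS) for the confidence band
        xc = self.x - self.x.mean()
        sxx = float(np.sum(xc ** 2))
        draw_slopes = xc @ draws / sxx
        draw_intercepts = draws.mean(axis=0) - draw_slopes * self.x.mean()

        res = McOLSResults(
            slope=float(slope),
            intercept=float(intercept),
            slope_se=float(ols.bse[1]),
            r_squared=float(ols.rsquared),
            rmse=rmse,
            p_value_1=p1,
            p_value_2=p2,
            n=n,
            df_resid=n - 2,
            _draw_slopes=draw_slopes,
            _draw_intercepts=draw_intercepts,
        )
        res._x, res._y, res._sem = self.x, self.y, self.y_sem
        return res


def mc_ols(x, y, y_sem=None, m: int = MC_DRAWS, seed: int | None = None) -> McOLSResults:
    """Convenience wrapper: ``McOLS(x, y, y_sem).fit(m, seed)``."""
    return McOLS(x, y, y_sem).fit(m=m, seed=seed)


def null_model_fit(x: Sequence[float], y: Sequence[float],
                   sample_frac: float = 0.05, max_size: float = 45980 / 2,
                   seed: int | None = None) -> McOLSResults:
    """Pairing-destroyed null regression with df correction.

    K = max_size / (sample_frac · size_XY) subsamples of
    ⌈sample_frac · size_XY⌉ points are drawn without replacement from the x
    and y arrays *independently* (destroying the pairing), pooled, and fitted
    by OLS.  Because the pooled cloud over-represents the original points,
    p-values are computed at df = size_XY − C (C = 2 for a line), not at the
    pooled size.  For fewer than 20 points the fallback is a single full
    permutation of y against x.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    size = len(x)
    rng = np.random.default_rng(seed)
    if size < 20:
        px = x.copy()
        py = rng.permutation(y)
        pooled_x, pooled_y = px, py
    else:
        s = int(np.ceil(sample_frac * size))
        K = max(1, int(max_size / (sample_frac * size)))
        xs, ys = [], []
        for _ in range(K):
            xs.append(x[rng.choice(size, s, replace=False)])
            ys.append(y[rng.choice(size, s, replace=False)])
        pooled_x = np.concatenate(xs)
        pooled_y = np.concatenate(ys)

    X = sm.add_constant(pooled_x)
    ols = sm.OLS(pooled_y, X).fit()
    n_pool = len(pooled_x)
    df = max(size - 2, 1)
    # rescale the t statistic from pooled-df to the corrected df
    t_pool = ols.tvalues[1]
    t_corr = t_pool * np.sqrt(df / max(n_pool - 2, 1))
    p1 = float(2 * stats.t.sf(abs(t_corr), df))
    resid = pooled_y - ols.fittedvalues
    res = McOLSResults(
        slope=float(ols.params[1]),
        intercept=float(ols.params[0]),
        slope_se=float(ols.bse[1] * np.sqrt(max(n_pool - 2, 1) / df)),
        r_squared=float(ols.rsquared),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        p_value_1=p1,
        p_value_2=None,
        n=size,
        df_resid=df,
        _draw_slopes=np.array([ols.params[1]]),
        _draw_intercepts=np.array([ols.params[0]]),
    )
    res._x, res._y, res._sem = pooled_x, pooled_y, np.zeros(n_pool)
    return res


def logistic4(t, a, c, t0, k):
    """4-parameter logistic: a + (c − a) / (1 + exp(−k (t − t0)))."""
    return a + (c - a) / (1.0 + np.exp(-k * (t - np.asarray(t0))))


@dataclass
class SigmoidResults:
    """Monte-Carlo 4PL fit: mean parameters and pointwise 68.2% band."""

    a: float
    c: float
    t0: float
    k: float
    n_iterations: int
    n_failed: int
    param_draws: np.ndarray = field(repr=False, default=None)  # (iters, 4)
    t: np.ndarray = field(repr=False, default=None)

    @property
    def params(self) -> dict[str, float]:
        return {"a": self.a, "c": self.c, "t0": self.t0, "k": self.k}

    def predict(self, t) -> np.ndarray:
        return logistic4(np.asarray(t, float), self.a, self.c, self.t0, self.k)

    def conf_band(self, t, level: float = 0.682) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(t, float)
        curves = np.stack([logistic4(t, *p) for p in self.param_draws])
        lo = np.quantile(curves, (1 - level) / 2, axis=0)
        hi = np.quantile(curves, 1 - (1 - level) / 2, axis=0)
        return lo, hi

    def param_halfwidths(self, level: float = 0.682) -> dict[str, float]:
        """Half-width of the central *level* interval for each parameter."""
        lo = np.quantile(self.param_draws, (1 - level) / 2, axis=0)
        hi = np.quantile(self.param_draws, 1 - (1 - level) / 2, axis=0)
        names = ("a", "c", "t0", "k")
        return {nm: float((h - l) / 2) for nm, l, h in zip(names, lo, hi)}

    def summary(self) -> str:
        hw = self.param_halfwidths()
        return "\n".join([
            "Monte-Carlo 4PL (logistic) fit",
            f"  iterations: {self.n_iterations} ({self.n_failed} failed)",
            f"  a  (lower asymptote): {self.a:.6g} +/- {hw['a']:.3g}",
            f"  c  (upper asymptote): {self.c:.6g} +/- {hw['c']:.3g}",
            f"  t0 (midpoint):        {self.t0:.6g} +/- {hw['t0']:.3g}",
            f"  k  (rate):            {self.k:.6g} +/- {hw['k']:.3g}",
        ])

    def plot(self, ax=None, y=None, y_sem=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ts = np.linspace(float(self.t.min()), float(self.t.max()), 200)
        if y is not None:
            ax.errorbar(self.t, y, yerr=y_sem, fmt="o")
        ax.plot(ts, self.predict(ts), color="C3")
        lo, hi = self.conf_band(ts)
        ax.fill_between(ts, lo, hi, alpha=0.3, color="C3")
        return ax


class SigmoidModel:
    """4-parameter logistic model of a time series with per-point SEM."""

    def __init__(self, t: Sequence[float], y: Sequence[float],
                 y_sem: Sequence[float] | None = None):
        self.t = np.asarray(t, float)
        self.y = np.asarray(y, float)
        self.y_sem = (np.zeros_like(self.y) if y_sem is None
                      else np.asarray(y_sem, float))
        if len(self.t) < 5:
            raise ValueError("at least 5 timepoints are required")

    def _p0(self, y) -> list[float]:
        span = float(self.t.max() - self.t.min()) or 1.0
        return [float(y[0]), float(y[-1]), float(np.median(self.t)), 4.0 / span]

    def _bounds(self, y) -> tuple[list[float], list[float]]:
        """Plausible parameter box: asymptotes near the data range, midpoint
        near the observation window, rate positive and resolvable."""
        span = float(self.t.max() - self.t.min()) or 1.0
        ylo, yhi = float(np.min(y)), float(np.max(y))
        dy = max(yhi - ylo, 1e-6)
        return ([ylo - 2 * dy, ylo - 2 * dy, float(self.t.min()) - span, 1e-4],
                [yhi + 2 * dy, yhi + 2 * dy, float(self.t.max()) + span,
                 100.0 / span])

    def _fit_once(self, y) -> np.ndarray | None:
        lo, hi = self._bounds(y)
        p0 = np.clip(self._p0(y), lo, hi)
        # fast unconstrained fit first; fall back to the bounded solver when
        # it fails or wanders outside the plausible box (asymptote swaps,
        # runaway rates)
        try:
            popt, _ = optimize.curve_fit(logistic4, self.t, y, p0=p0,
                                         maxfev=5000)
            if np.all(np.isfinite(popt)) and np.all(popt >= lo) and np.all(popt <= hi):
                return popt
        except (RuntimeError, optimize.OptimizeWarning):
            pass
        try:
            popt, _ = optimize.curve_fit(logistic4, self.t, y, p0=p0,
                                         bounds=(lo, hi), maxfev=5000)
        except (RuntimeError, ValueError, optimize.OptimizeWarning):
            return None
        if not np.all(np.isfinite(popt)):
            return None
        return popt

    def fit(self, iterations: int = 1000, seed: int | None = None) -> SigmoidResults:
        rng = np.random.default_rng(seed)
        if np.all(self.y_sem == 0):
            popt = self._fit_once(self.y)
            if popt is None:
                raise RuntimeError("sigmoid fit failed to converge")
            draws = np.tile(popt, (1, 1))
            n_failed = 0
            iterations_done = 1
        else:
            fits = []
            n_failed = 0
            for _ in range(iterations):
                y = self.y + self.y_sem * rng.standard_normal(len(self.y))
                popt = self._fit_once(y)
                if popt is None:
                    n_failed += 1
                else:
                    fits.append(popt)
            if n_failed > iterations / 2:
                raise RuntimeError(
                    f"sigmoid fit: {n_failed}/{iterations} iterations failed")
            draws = np.array(fits)
            iterations_done = iterations
        a, c, t0, k = draws.mean(axis=0)
        return SigmoidResults(a=float(a), c=float(c), t0=float(t0), k=float(k),
                              n_iterations=iterations_done, n_failed=n_failed,
                              param_draws=draws, t=self.t)


def sigmoid_mc_fit(t, y, y_sem=None, iterations: int = 1000,
                   seed: int | None = None) -> SigmoidResults:
    """Convenience wrapper: ``SigmoidModel(t, y, y_sem).fit(iterations, seed)``."""
    return SigmoidModel(t, y, y_sem).fit(iterations=iterations, seed=seed)


def ancova_compare(group_a: tuple[Sequence[float], Sequence[float]],
                   group_b: tuple[Sequence[float], Sequence[float]]
                   ) -> dict[str, float]:
    """ANCOVA test of whether two lines share slope and intercept.

    Fits y ~ x with a group factor; the equal-slope p-value is the t-test of
    the x:group interaction, the equal-intercept p-value the t-test of the
    group offset in the common-slope model.  Decisions at the 10% level.
    """
    xa, ya = np.asarray(group_a[0], float), np.asarray(group_a[1], float)
    xb, yb = np.asarray(group_b[0], float), np.asarray(group_b[1], float)
    if len(xa) < 3 or len(xb) < 3:
        raise ValueError("each group needs at least 3 pairs")
    x = np.concatenate([xa, xb])
    y = np.concatenate([ya, yb])
    g = np.concatenate([np.zeros(len(xa)), np.ones(len(xb))])

    def _p(model, idx):
        p = model.pvalues[idx]
        tss = model.centered_tss
        if not np.isfinite(p) or model.ssr <= 1e-12 * max(tss, 1e-300):
            # degenerate (identical groups or an exact fit, where the
            # residual is pure round-off): no evidence against equality
            return 1.0
        return float(p)

    X_full = np.column_stack([np.ones_like(x), x, g, x * g])
    full = sm.OLS(y, X_full).fit()
    p_slope = _p(full, 3)
    X_red = np.column_stack([np.ones_like(x), x, g])
    red = sm.OLS(y, X_red).fit()
    p_intercept = _p(red, 2)
    return {
        "p_slope": p_slope,
        "p_intercept": p_intercept,
        "reject_equal_slope": p_slope < ALPHA,
        "reject_equal_intercept": p_intercept < ALPHA,
    }


# --------------------------------------------------------------------------
# basic hypothesis tests (all decided at the 10% level)

def t_test_2sample(a, b) -> dict[str, float]:
    """Welch two-sample t-test (unequal, unknown variances)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    stat, p = stats.ttest_ind(a, b, equal_var=False)
    return {"statistic": float(stat), "p_value": float(p), "reject": p < ALPHA}


def ks_test_2sample(a, b) -> dict[str, float]:
    """Two-sample Kolmogorov–Smirnov test of equal distributions."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    stat, p = stats.ks_2samp(a, b)
    return {"statistic": float(stat), "p_value": float(p), "reject": p < ALPHA}


def z_test_1sample(sample, m: float, sigma: float) -> dict[str, float]:
    """One-sample Z-test against Normal(m, sigma).

    In the pipeline, *m* and *sigma* are typically estimated from the genes
    with K_TF = 0 (the TF-unregulated background).
    """
    sample = np.asarray(sample, float)
    if len(sample) == 0:
        raise ValueError("empty sample")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    z = (sample.mean() - m) / (sigma / np.sqrt(len(sample)))
    p = float(2 * stats.norm.sf(abs(z)))
    return {"statistic": float(z), "p_value": p, "reject": p < ALPHA}


def fisher_test(table) -> dict[str, float]:
    """Two-sided Fisher exact test of association in a 2×2 table."""
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return {"statistic": float(odds), "p_value": float(p), "reject": p < ALPHA}


def relative_concentration(abundance_rel: float, area_rel: float,
                           abundance_sem: float = 0.0, area_sem: float = 0.0
                           ) -> tuple[float, float]:
    """Concentration relative to control: abundance ratio over area ratio.

    The mean reporter abundance (relative to control) divided by the mean
    cell area (a proxy for cell volume) estimates the relative intracellular
    concentration; the SEM follows first-order error propagation.
    """
    if area_rel <= 0:
        raise ValueError("area_rel must be positive")
    ratio = abundance_rel / area_rel
    sem = np.sqrt((abundance_sem / area_rel) ** 2
                  + (abundance_rel * area_sem / area_rel ** 2) ** 2)
    return float(ratio), float(sem)
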