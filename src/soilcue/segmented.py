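"""Continuous piecewise-linear (segmented) regression with bootstrap CIs.

The decoupling threshold between carbon use efficiency and heterotrophic
respiration is estimated as the breakpoint psi of the continuous
two-segment model

    cue = a + b1 * rh + b2 * max(0, rh - psi)

fitted by least squares.  For a fixed psi the model is linear, so the
profile SSE(psi) is evaluated in closed form; psi is located by an
exhaustive scan over every midpoint between consecutive distinct rh values
inside the interior quantile range, followed by bounded local refinement.
Uncertainty comes from a nonparametric pairs bootstrap (percentile CI and
SD of the bootstrap psi distribution).

The module also carries the companion fits used around the threshold
analysis: per-stratum straight-line fits ("GLM" lines with Gaussian
identity link) and the three nonlinear candidate forms (exponential,
logarithmic, quadratic) ranked by AICc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
import statsmodels.api as sm

from .exceptions import FitError

__all__ = [
    "SegmentedRegression",
    "SegmentedResults",
    "BootstrapThreshold",
    "fit_segmented",
    "fit_stratified_glm",
    "fit_nonlinear_candidates",
]

# Minimum observations for a segmented fit and minimum distinct x values.
_MIN_N = 20
_MIN_DISTINCT = 10


def _gaussian_loglik(rss: float, n: int) -> float:
    if rss <= 0:
        return math.inf
    return -0.5 * n * (math.log(2 * math.pi * rss / n) + 1.0)


def _bic(rss: float, n: int, k: int) -> float:
    return -2.0 * _gaussian_loglik(rss, n) + k * math.log(n)


def _aicc(rss: float, n: int, k: int) -> float:
    aic = -2.0 * _gaussian_loglik(rss, n) + 2.0 * k
    if n - k - 1 <= 0:
        return math.inf
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


class SegmentedRegression:
    """Two-segment continuous linear model for a (x, y) scatter.

    Parameters
    ----------
    endog : array-like
        Response (CUE_ST in the reference analysis).
    exog : array-like
        Single explanatory variable (R_h).
    min_segment_frac : float
        The breakpoint is searched between the ``min_segment_frac`` and
        ``1 - min_segment_frac`` quantiles of ``exog``.
    min_segment_size : int
        Each segment must keep at least this many observations.
    """

    def __init__(self, endog, exog, *, min_segment_frac: float = 0.05,
                 min_segment_size: int = 10):
        y = np.asarray(endog, dtype=float)
        x = np.asarray(exog, dtype=float)
        if y.ndim != 1 or x.shape != y.shape:
            raise FitError("endog and exog must be 1-d arrays of equal length")
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        n = x.size
        if n < _MIN_N:
            raise FitError(f"segmented fit needs at least {_MIN_N} points, got {n}")
        if np.unique(x).size < _MIN_DISTINCT:
            raise FitError(f"exog needs at least {_MIN_DISTINCT} distinct values")
        if not (0 < min_segment_frac < 0.5):
            raise FitError("min_segment_frac must be in (0, 0.5)")
        order = np.argsort(x, kind="mergesort")
        self.x = x[order]
        self.y = y[order]
        self.nobs = n
        self.min_segment_frac = min_segment_frac
        self.min_segment_size = min_segment_size
        self._prepare_sums()

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, x: str = "rh", y: str = "cue", **kwargs):
        return cls(data[y].to_numpy(), data[x].to_numpy(), **kwargs)

    # -- profile SSE machinery -------------------------------------------

    def _prepare_sums(self):
        x, y = self.x, self.y
        self._Sx = x.sum()
        self._Sy = y.sum()
        self._Sxx = (x * x).sum()
        self._Sxy = (x * y).sum()
        self._Syy = (y * y).sum()
        # suffix sums: _suf[i] = sum over points i..n-1
        def suf(a):
            return np.concatenate([np.cumsum(a[::-1])[::-1], [0.0]])
        self._sufx = suf(x)
        self._sufxx = suf(x * x)
        self._sufy = suf(y)
        self._sufxy = suf(x * y)

    def _profile(self, psis: np.ndarray):
        """SSE and coefficients of the 3-parameter model for each psi.

        Uses closed-form normal equations built from suffix sums, so each
        candidate costs O(1) after the O(n log n) setup.
        """
        psis = np.atleast_1d(np.asarray(psis, dtype=float))
        n = float(self.nobs)
        idx = np.searchsorted(self.x, psis, side="right")
        s1 = n - idx
        sxp = self._sufx[idx]
        sxxp = self._sufxx[idx]
        syp = self._sufy[idx]
        sxyp = self._sufxy[idx]
        su = sxp - psis * s1
        suu = sxxp - 2 * psis * sxp + psis ** 2 * s1
        sxu = sxxp - psis * sxp
        suy = sxyp - psis * syp

        G = psis.size
        XtX = np.empty((G, 3, 3))
        XtX[:, 0, 0] = n
        XtX[:, 0, 1] = XtX[:, 1, 0] = self._Sx
        XtX[:, 0, 2] = XtX[:, 2, 0] = su
        XtX[:, 1, 1] = self._Sxx
        XtX[:, 1, 2] = XtX[:, 2, 1] = sxu
        XtX[:, 2, 2] = suu
        Xty = np.stack([np.full(G, self._Sy), np.full(G, self._Sxy), suy], axis=1)
        try:
            beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        except np.linalg.LinAlgError:
            beta = np.empty((G, 3))
            for g in range(G):
                beta[g] = np.linalg.lstsq(XtX[g], Xty[g], rcond=None)[0]
        sse = self._Syy - np.einsum("gi,gi->g", beta, Xty)
        return np.maximum(sse, 0.0), beta

    def _candidates(self) -> np.ndarray:
        x = self.x
        n = self.nobs
        lo_q = np.quantile(x, self.min_segment_frac)
        hi_q = np.quantile(x, 1.0 - self.min_segment_frac)
        m = max(self.min_segment_size, int(math.ceil(self.min_segment_frac * n)))
        # every midpoint between consecutive distinct sorted values ...
        ux = np.unique(x)
        mids = 0.5 * (ux[:-1] + ux[1:])
        # ... restricted to the interior quantile band and to splits that
        # leave >= m points on each side
        counts_left = np.searchsorted(x, mids, side="right")
        ok = (mids >= lo_q) & (mids <= hi_q) & (counts_left >= m) & (n - counts_left >= m)
        mids = mids[ok]
        if mids.size == 0:
            raise FitError("no admissible breakpoint candidates "
                           "(degenerate exog or segments too small)")
        return mids

    def fit(self, refine: bool = True) -> "SegmentedResults":
        """Estimate the breakpoint and segment coefficients.

        Grid scan over all admissible midpoints, then bounded scalar
        refinement around the best candidate (``refine=False`` skips the
        polish; the grid optimum is already within one data gap).
        """
        cands = self._candidates()
        sse, beta = self._profile(cands)
        k = int(np.argmin(sse))
        best_psi, best_sse, best_beta = float(cands[k]), float(sse[k]), beta[k]
        if refine and cands.size > 2:
            lo = cands[max(k - 1, 0)]
            hi = cands[min(k + 1, cands.size - 1)]
            if hi > lo:
                res = optimize.minimize_scalar(
                    lambda p: float(self._profile(np.array([p]))[0][0]),
                    bounds=(lo, hi), method="bounded",
                    options={"xatol": 1e-10 * max(abs(hi), 1.0)})
                s, b = self._profile(np.array([res.x]))
                if s[0] < best_sse:
                    best_psi, best_sse, best_beta = float(res.x), float(s[0]), b[0]

        # one-line reference fit
        X1 = np.column_stack([np.ones(self.nobs), self.x])
        b1, rss1, *_ = np.linalg.lstsq(X1, self.y, rcond=None)
        resid1 = self.y - X1 @ b1
        sse_line = float(resid1 @ resid1)

        syy_c = float(self._Syy - self._Sy ** 2 / self.nobs)
        tiny = 1e-12 * max(syy_c, 1.0)
        if sse_line <= tiny:
            has_threshold = False  # a single line already fits perfectly
        else:
            bic_seg = _bic(max(best_sse, tiny), self.nobs, 5)
            bic_line = _bic(sse_line, self.nobs, 3)
            has_threshold = bic_seg < bic_line

        return SegmentedResults(model=self, psi=best_psi,
                                intercept=float(best_beta[0]),
                                slope_pre=float(best_beta[1]),
                                slope_post=float(best_beta[1] + best_beta[2]),
                                sse=best_sse, sse_line=sse_line,
                                has_threshold=bool(has_threshold))


@dataclass
class BootstrapThreshold:
    """Pairs-bootstrap summary of the breakpoint distribution."""

    psi_ci_low: float
    psi_ci_high: float
    psi_se: float
    n_boot: int
    n_failures: int
    psis: np.ndarray = field(repr=False)


@dataclass
class SegmentedResults:
    """Fitted segmented model: breakpoint, per-segment lines, diagnostics.

    ``slope_pre``/``slope_post`` are the segment slopes of the continuous
    model.  ``r2_pre``/``p_pre`` etc. come from separate straight-line fits
    on each side of the breakpoint, mirroring how pre/post relationships
    are reported alongside the threshold.
    """

    model: SegmentedRegression = field(repr=False)
    psi: float
    intercept: float
    slope_pre: float
    slope_post: float
    sse: float
    sse_line: float
    has_threshold: bool

    def __post_init__(self):
        x, y = self.model.x, self.model.y
        pre = x <= self.psi
        self.n_pre = int(pre.sum())
        self.n_post = int((~pre).sum())
        self.r2_pre, self.p_pre = _side_fit(x[pre], y[pre])
        self.r2_post, self.p_post = _side_fit(x[~pre], y[~pre])

    @property
    def nobs(self) -> int:
        return self.model.nobs

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return (self.intercept + self.slope_pre * np.minimum(x, self.psi)
                + self.slope_post * np.maximum(x - self.psi, 0.0))

    def bootstrap_ci(self, n_boot: int = 1000, seed=None, alpha: float = 0.05,
                     max_failure_frac: float = 0.2) -> BootstrapThreshold:
        """Nonparametric pairs bootstrap for the breakpoint.

        Resamples (x, y) pairs with replacement, refits, and summarises the
        psi distribution with a percentile CI and its SD.  Resamples whose
        fit fails are excluded and counted; more than ``max_failure_frac``
        failures raises.
        """
        if n_boot < 2:
            raise FitError("n_boot must be at least 2 for percentile intervals")
        rng = np.random.default_rng(seed)
        m = self.model
        psis, failures = [], 0
        for _ in range(n_boot):
            idx = rng.integers(0, m.nobs, m.nobs)
            try:
                sub = SegmentedRegression(m.y[idx], m.x[idx],
                                          min_segment_frac=m.min_segment_frac,
                                          min_segment_size=m.min_segment_size)
                psis.append(sub.fit(refine=False).psi)
            except FitError:
                failures += 1
        if failures > max_failure_frac * n_boot:
            raise FitError(f"{failures}/{n_boot} bootstrap refits failed")
        psis = np.asarray(psis)
        lo, hi = np.quantile(psis, [alpha / 2, 1 - alpha / 2])
        return BootstrapThreshold(psi_ci_low=float(lo), psi_ci_high=float(hi),
                                  psi_se=float(psis.std(ddof=1)),
                                  n_boot=n_boot, n_failures=failures, psis=psis)

    def summary(self) -> str:
        lines = [
            "Segmented regression (continuous two-segment linear model)",
            f"  n = {self.nobs}   breakpoint psi = {self.psi:.4g}",
            f"  threshold detected: {self.has_threshold}",
            f"  slope pre  = {self.slope_pre: .4e}  (n={self.n_pre}, "
            f"R2={self.r2_pre:.3f}, p={self.p_pre:.3g})",
            f"  slope post = {self.slope_post: .4e}  (n={self.n_post}, "
            f"R2={self.r2_post:.3f}, p={self.p_post:.3g})",
            f"  SSE = {self.sse:.6g}   (single line: {self.sse_line:.6g})",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"psi": self.psi, "intercept": self.intercept,
                "slope_pre": self.slope_pre, "slope_post": self.slope_post,
                "r2_pre": self.r2_pre, "r2_post": self.r2_post,
                "p_pre": self.p_pre, "p_post": self.p_post,
                "n_pre": self.n_pre, "n_post": self.n_post,
                "sse": self.sse, "sse_line": self.sse_line,
                "has_threshold": self.has_threshold, "n": self.nobs}


def _side_fit(x, y):
    """R^2 and slope p-value of a straight line on one segment."""
    if x.size < 3 or np.unique(x).size < 2:
        return float("nan"), float("nan")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.rsquared), float(fit.pvalues[1])


def fit_segmented(data, x: str = "rh", y: str = "cue", *,
                  min_segment_frac: float = 0.05,
                  min_segment_size: int = 10) -> SegmentedResults:
    """Convenience wrapper: build and fit a :class:`SegmentedRegression`.

    ``data`` is a DataFrame with columns ``x`` and ``y`` or a tuple of
    arrays ``(x_values, y_values)``.
    """
    if isinstance(data, pd.DataFrame):
        model = SegmentedRegression.from_dataframe(
            data, x=x, y=y, min_segment_frac=min_segment_frac,
            min_segment_size=min_segment_size)
    else:
        xv, yv = data
        model = SegmentedRegression(yv, xv, min_segment_frac=min_segment_frac,
                                    min_segment_size=min_segment_size)
    return model.fit()


def fit_stratified_glm(data: pd.DataFrame, stratum: str, *, x: str = "rh",
                       y: str = "cue", min_n: int = 10) -> pd.DataFrame:
    """Straight-line fit of y on x within each stratum.

    Implements the per-zone / per-productivity-class "GLM" lines as
    Gaussian-identity OLS with a slope t-test.  Strata with fewer than
    ``min_n`` complete observations are reported as skipped rather than
    silently dropped.
    """
    rows = []
    for label, grp in data.groupby(stratum, observed=True, sort=True):
        sub = grp[[x, y]].dropna()
        if len(sub) < min_n:
            rows.append({"stratum": label, "n": len(sub), "slope": np.nan,
                         "intercept": np.nan, "r2": np.nan, "p": np.nan,
                         "skipped": f"n={len(sub)} < {min_n}"})
            continue
        if sub[x].nunique() < 2:
            rows.append({"stratum": label, "n": len(sub), "slope": np.nan,
                         "intercept": np.nan, "r2": np.nan, "p": np.nan,
                         "skipped": "degenerate x"})
            continue
        fit = sm.OLS(sub[y].to_numpy(), sm.add_constant(sub[x].to_numpy())).fit()
        rows.append({"stratum": label, "n": len(sub),
                     "slope": float(fit.params[1]),
                     "intercept": float(fit.params[0]),
                     "r2": float(fit.rsquared), "p": float(fit.pvalues[1]),
                     "skipped": ""})
    return pd.DataFrame(rows)


def fit_nonlinear_candidates(data, x: str = "rh", y: str = "cue") -> pd.DataFrame:
    """Fit exponential, logarithmic and quadratic forms and rank by AICc.

    Forms: y = a*exp(b*x); y = a + b*ln(x) (requires x > 0);
    y = a + b*x + c*x^2.  Each is fitted by least squares; a form that
    fails to converge is flagged and the others are still returned.
    """
    if isinstance(data, pd.DataFrame):
        xv = data[x].to_numpy(dtype=float)
        yv = data[y].to_numpy(dtype=float)
    else:
        xv, yv = (np.asarray(a, dtype=float) for a in data)
    keep = np.isfinite(xv) & np.isfinite(yv)
    xv, yv = xv[keep], yv[keep]
    n = xv.size
    rows = []

    def add(form, coefs, rss, k, note=""):
        rows.append({"form": form, "aicc": _aicc(max(rss, 1e-300), n, k),
                     "coefficients": coefs, "converged": not note, "note": note})

    # exponential, warm-started from the log-linear fit when y > 0
    try:
        if np.all(yv > 0):
            lb = np.polyfit(xv, np.log(yv), 1)
            p0 = (math.exp(lb[1]), lb[0])
        else:
            p0 = (float(np.mean(yv)), 0.0)
        popt, _ = optimize.curve_fit(lambda t, a, b: a * np.exp(b * t),
                                     xv, yv, p0=p0, maxfev=20000)
        r = yv - popt[0] * np.exp(popt[1] * xv)
        add("exponential", {"a": float(popt[0]), "b": float(popt[1])},
            float(r @ r), 3)
    except (RuntimeError, TypeError, ValueError) as exc:
        rows.append({"form": "exponential", "aicc": math.inf, "coefficients": {},
                     "converged": False, "note": f"nonconvergence: {exc}"})

    # logarithmic (defined only for positive x)
    if np.all(xv > 0):
        X = np.column_stack([np.ones(n), np.log(xv)])
        b, *_ = np.linalg.lstsq(X, yv, rcond=None)
        r = yv - X @ b
        add("logarithmic", {"a": float(b[0]), "b": float(b[1])}, float(r @ r), 3)
    else:
        rows.append({"form": "logarithmic", "aicc": math.inf, "coefficients": {},
                     "converged": False, "note": "x must be positive for ln(x)"})

    # quadratic
    X = np.column_stack([np.ones(n), xv, xv ** 2])
    b, *_ = np.linalg.lstsq(X, yv, rcond=None)
    r = yv - X @ b
    add("quadratic", {"a": float(b[0]), "b": float(b[1]), "c": float(b[2])},
        float(r @ r), 4)

    out = pd.DataFrame(rows).sort_values("aicc", kind="mergesort").reset_index(drop=True)
    return out
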