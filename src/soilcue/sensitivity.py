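"""Stratified random-removal sensitivity test.

Checks that the sign (and significance) of the within-stratum CUE-R_h
slope is not carried by a handful of observations: a fixed fraction of
pairs (default 20%) is removed uniformly at random within each stratum,
the straight-line slope is refitted, and the distribution of refitted
slopes is summarised over many repetitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ConfigError, FitError

__all__ = ["RemovalReport", "stratified_removal_test"]


@dataclass
class RemovalReport:
    """Removal-test summary for one stratum.

    ``sign_persistence`` is the fraction of repetitions whose refitted
    slope has the same sign as the full-data slope;
    ``significance_persistence`` the fraction with slope p < 0.05.
    """

    stratum: object
    n: int
    n_removed: int
    n_reps: int
    removal_frac: float
    full_slope: float
    full_p: float
    slope_mean: float
    slope_sd: float
    slope_q025: float
    slope_q975: float
    sign_persistence: float
    significance_persistence: float
    skipped: str = ""
    slopes: np.ndarray = field(default=None, repr=False)


def _ols_slope(x: np.ndarray, y: np.ndarray):
    """Slope and its t-test p-value (closed form, no model object overhead)."""
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        return np.nan, np.nan
    b = float(xc @ yc) / sxx
    resid = yc - b * xc
    dof = n - 2
    if dof <= 0:
        return b, np.nan
    s2 = float(resid @ resid) / dof
    se = np.sqrt(s2 / sxx)
    if se == 0:
        return b, 0.0
    t = b / se
    return b, float(2.0 * stats.t.sf(abs(t), dof))


def stratified_removal_test(data, stratify_by: str, *, x: str = "rh",
                            y: str = "cue", removal_frac: float = 0.2,
                            n_reps: int = 1000, seed=None,
                            min_retained: int = 10) -> dict:
    """Run the removal test within each stratum of ``data``.

    For each repetition, ``floor(removal_frac * n_stratum)`` rows are
    removed without replacement, the slope of y on x refitted, and the
    slope distribution accumulated.  Fully deterministic for a given seed.
    Returns ``{stratum: RemovalReport}``; strata that would retain fewer
    than ``min_retained`` points are reported as skipped.
    """
    if not (0 < removal_frac < 1):
        raise ConfigError(f"removal_frac must be in (0, 1), got {removal_frac}")
    if n_reps < 1:
        raise ConfigError("n_reps must be positive")
    rng = np.random.default_rng(seed)
    reports = {}
    for label, grp in data.groupby(stratify_by, observed=True, sort=True):
        sub = grp[[x, y]].dropna()
        n = len(sub)
        n_removed = int(np.floor(removal_frac * n))
        if n - n_removed < min_retained:
            reports[label] = RemovalReport(
                stratum=label, n=n, n_removed=n_removed, n_reps=0,
                removal_frac=removal_frac, full_slope=np.nan, full_p=np.nan,
                slope_mean=np.nan, slope_sd=np.nan, slope_q025=np.nan,
                slope_q975=np.nan, sign_persistence=np.nan,
                significance_persistence=np.nan,
                skipped=f"would retain {n - n_removed} < {min_retained} points")
            continue
        xv = sub[x].to_numpy(dtype=float)
        yv = sub[y].to_numpy(dtype=float)
        full_slope, full_p = _ols_slope(xv, yv)
        slopes = np.empty(n_reps)
        pvals = np.empty(n_reps)
        for r in range(n_reps):
            keep = rng.permutation(n)[n_removed:]
            slopes[r], pvals[r] = _ols_slope(xv[keep], yv[keep])
        q025, q975 = np.quantile(slopes, [0.025, 0.975])
        reports[label] = RemovalReport(
            stratum=label, n=n, n_removed=n_removed, n_reps=n_reps,
            removal_frac=removal_frac, full_slope=full_slope, full_p=full_p,
            slope_mean=float(slopes.mean()), slope_sd=float(slopes.std(ddof=1)),
            slope_q025=float(q025), slope_q975=float(q975),
            sign_persistence=float(np.mean(np.sign(slopes) == np.sign(full_slope))),
            significance_persistence=float(np.mean(pvals < 0.05)),
            slopes=slopes)
    return reports
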