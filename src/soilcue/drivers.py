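"""Environmental-driver attribution for the CUE/R_h ratio.

Given a response (by default the ratio of carbon use efficiency to
heterotrophic respiration) and a set of candidate environmental predictors
(mean annual air/soil temperature, precipitation, leaf area index, above-
and belowground biomass, pH, cation-exchange capacity, clay content), this
module provides:

* all-subsets linear-model selection scored by AICc, with per-predictor
  importance as the sum of Akaike weights of the models containing it and
  an "essential" flag at importance >= 0.8;
* single-predictor straight-line fits per stratum;
* partial correlation between two variables controlling for others,
  computed from residual-on-residual Pearson correlation;
* variation partitioning of adjusted R^2 into per-variable independent
  fractions and a joint fraction, with relative influences expressed as
  fractions of the total explanation;
* robustness refits for a skewed positive response: normality tests, OLS on
  the log response with HC3 robust covariance, and a gamma GLM (log link).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors, normal_ad

from .exceptions import FitError

__all__ = [
    "DEFAULT_PREDICTORS",
    "KEY_VARIABLES",
    "AllSubsetsSelection",
    "ImportanceResult",
    "all_subsets_aicc",
    "per_variable_glm",
    "partial_correlation",
    "variation_partitioning",
    "PartitionResult",
    "robustness_fits",
]

#: The nine candidate environmental predictors.
DEFAULT_PREDICTORS = ("mat", "soil_mat", "map_mm", "lai", "agb", "bgb",
                      "ph", "cec", "clay")
#: The four key variables examined by partial correlation / partitioning.
KEY_VARIABLES = ("soil_mat", "map_mm", "lai", "ph")

ESSENTIAL_CUTOFF = 0.8


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise FitError("constant predictor cannot be standardized")
    return (X - mu) / sd


def _check_collinearity(X: np.ndarray, names) -> None:
    """Raise naming the offending set if the standardized design is rank-deficient."""
    n, p = X.shape
    if np.linalg.matrix_rank(X, tol=1e-8 * max(n, p)) < p:
        # name the columns whose QR diagonal collapses
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[j] for j in range(p) if diag[j] < 1e-8 * diag.max()]
        raise FitError(f"rank-deficient design; collinear predictors involve: "
                       f"{bad or list(names)}")


@dataclass
class ImportanceResult:
    """Per-predictor sum-of-Akaike-weights importance from all-subsets AICc.

    ``importance`` maps predictor name -> sum of the Akaike weights of all
    models containing it (in [0, 1]); ``essential`` flags predictors at or
    above the 0.8 cutoff.  ``total_r2`` is the R^2 of the full model and
    ``weights`` the normalized Akaike weights over the enumerated set.
    """

    importance: dict
    essential: dict
    model_count: int
    total_r2: float
    nobs: int
    n_dropped: int
    weights: np.ndarray = field(repr=False)
    subsets: list = field(repr=False)

    def essential_set(self):
        return tuple(k for k, v in self.essential.items() if v)

    def summary(self) -> str:
        lines = [f"All-subsets AICc selection: {self.model_count} models, "
                 f"n = {self.nobs} ({self.n_dropped} rows dropped), "
                 f"full-model R2 = {self.total_r2:.3f}",
                 f"{'predictor':<10} {'importance':>10}  essential(>= {ESSENTIAL_CUTOFF})"]
        for k in sorted(self.importance, key=self.importance.get, reverse=True):
            lines.append(f"{k:<10} {self.importance[k]:>10.3f}  "
                         f"{'*' if self.essential[k] else ''}")
        return "\n".join(lines)


class AllSubsetsSelection:
    """Enumerate all main-effects OLS models over a predictor set.

    Predictors are standardized (zero mean, unit SD) before enumeration;
    rows with any missing value are dropped and counted.  The candidate set
    includes the intercept-only model, so 2^k models for k predictors.
    """

    def __init__(self, data: pd.DataFrame, response: str = "ratio",
                 predictors=DEFAULT_PREDICTORS):
        predictors = list(predictors)
        cols = [response] + predictors
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise FitError(f"missing columns: {missing}")
        sub = data[cols].dropna()
        self.n_dropped = len(data) - len(sub)
        n, k = len(sub), len(predictors)
        if n <= k + 10:
            raise FitError(f"need n > k + 10 = {k + 10} complete rows, got {n}")
        self.y = sub[response].to_numpy(dtype=float)
        X = sub[predictors].to_numpy(dtype=float)
        self.X = _standardize(X)
        _check_collinearity(self.X, predictors)
        self.predictors = predictors
        self.nobs = n

    def fit(self) -> ImportanceResult:
        y, X = self.y, self.X
        n, k = self.nobs, len(self.predictors)
        ones = np.ones((n, 1))
        subsets, aiccs, r2s = [], [], []
        yc = y - y.mean()
        tss = float(yc @ yc)
        for size in range(k + 1):
            for combo in combinations(range(k), size):
                Xd = np.hstack([ones, X[:, combo]]) if combo else ones
                beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
                r = y - Xd @ beta
                rss = float(r @ r)
                p = len(combo) + 2  # coefficients incl. intercept, plus sigma
                aic = n * math.log(max(rss, 1e-300) / n) + 2 * p
                aicc = aic + 2 * p * (p + 1) / (n - p - 1)
                subsets.append(combo)
                aiccs.append(aicc)
                r2s.append(1.0 - rss / tss if tss > 0 else 0.0)
        aiccs = np.asarray(aiccs)
        delta = aiccs - aiccs.min()
        w = np.exp(-delta / 2.0)
        w /= w.sum()
        importance = {}
        for j, name in enumerate(self.predictors):
            mask = np.fromiter((j in s for s in subsets), bool, len(subsets))
            importance[name] = float(w[mask].sum())
        essential = {k_: v >= ESSENTIAL_CUTOFF for k_, v in importance.items()}
        return ImportanceResult(importance=importance, essential=essential,
                                model_count=len(subsets),
                                total_r2=float(r2s[-1]), nobs=n,
                                n_dropped=self.n_dropped,
                                weights=w, subsets=subsets)


def all_subsets_aicc(data: pd.DataFrame, response: str = "ratio",
                     predictors=DEFAULT_PREDICTORS) -> ImportanceResult:
    """Convenience wrapper around :class:`AllSubsetsSelection`."""
    return AllSubsetsSelection(data, response, predictors).fit()


def per_variable_glm(data: pd.DataFrame, stratum: str,
                     response: str = "ratio",
                     predictors=DEFAULT_PREDICTORS,
                     min_n: int = 10, fdr: bool = True) -> pd.DataFrame:
    """Single-predictor straight-line fits per (variable, stratum).

    Returns slope, R^2 and raw p per combination; constant predictors and
    undersized strata are recorded as skipped.  A Benjamini-Hochberg
    adjusted-p column (``p_bh``) is appended as a labelled extension beyond
    the raw per-variable tests.
    """
    rows = []
    for label, grp in data.groupby(stratum, observed=True, sort=True):
        for var in predictors:
            sub = grp[[response, var]].dropna()
            if len(sub) < min_n:
                rows.append({"stratum": label, "variable": var, "n": len(sub),
                             "slope": np.nan, "r2": np.nan, "p": np.nan,
                             "skipped": f"n={len(sub)} < {min_n}"})
                continue
            if sub[var].nunique() < 2:
                rows.append({"stratum": label, "variable": var, "n": len(sub),
                             "slope": np.nan, "r2": np.nan, "p": np.nan,
                             "skipped": "constant predictor"})
                continue
            fit = sm.OLS(sub[response].to_numpy(),
                         sm.add_constant(sub[var].to_numpy())).fit()
            rows.append({"stratum": label, "variable": var, "n": len(sub),
                         "slope": float(fit.params[1]),
                         "r2": float(fit.rsquared),
                         "p": float(fit.pvalues[1]), "skipped": ""})
    out = pd.DataFrame(rows)
    if fdr:
        out["p_bh"] = np.nan
        ok = out["p"].notna()
        if ok.any():
            from statsmodels.stats.multitest import multipletests
            out.loc[ok, "p_bh"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def partial_correlation(data: pd.DataFrame, x: str, y: str, controls):
    """Partial Pearson correlation of x and y controlling for `controls`.

    Both variables are regressed (with intercept) on the controls; the
    Pearson correlation of the two residual series is returned with a
    t-distribution p-value on n - 2 - g degrees of freedom (g controls).
    """
    controls = list(controls)
    sub = data[[x, y] + controls].dropna()
    n, g = len(sub), len(controls)
    if n <= 5 + g:
        raise FitError(f"need n > {5 + g} complete rows, got {n}")
    C = np.column_stack([np.ones(n), sub[controls].to_numpy(dtype=float)])
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise FitError("singular control matrix")
    def resid(v):
        b, *_ = np.linalg.lstsq(C, v, rcond=None)
        return v - C @ b
    rx = resid(sub[x].to_numpy(dtype=float))
    ry = resid(sub[y].to_numpy(dtype=float))
    r = float(np.dot(rx, ry) / math.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    df = n - 2 - g
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


@dataclass
class PartitionResult:
    """Adjusted-R^2 variation partition over a small variable set.

    ``independent`` maps variable -> adjR2(all) - adjR2(all minus it);
    ``joint`` is the remainder so that sum(independent) + joint equals the
    full-model adjusted R^2 by construction.  ``*_relative`` divide by the
    total explanation.  Negative adjusted-R^2 fractions are reported as-is
    and flagged.
    """

    variables: tuple
    total_adj_r2: float
    independent: dict
    joint: float
    independent_relative: dict
    joint_relative: float
    has_negative_fractions: bool
    subset_adj_r2: dict = field(repr=False)


def _adj_r2(y: np.ndarray, X: np.ndarray) -> float:
    n = y.size
    Xd = np.hstack([np.ones((n, 1)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    r = y - Xd @ beta
    rss = float(r @ r)
    yc = y - y.mean()
    tss = float(yc @ yc)
    p = X.shape[1]
    if tss <= 0 or n - p - 1 <= 0:
        return float("nan")
    return 1.0 - (rss / (n - p - 1)) / (tss / (n - 1))


def variation_partitioning(data: pd.DataFrame, response: str,
                           variables=KEY_VARIABLES) -> PartitionResult:
    """Partition explained variance among a small set of variables.

    Computes adjusted R^2 for every nonempty variable subset, defines each
    variable's independent fraction as the drop in full-model adjusted R^2
    when it is removed, and the joint fraction as the remainder.  Relative
    influences divide by the full-model adjusted R^2 (the total
    explanation); the partition is flagged undefined when that total is
    not positive.
    """
    variables = tuple(variables)
    sub = data[[response] + list(variables)].dropna()
    y = sub[response].to_numpy(dtype=float)
    X = sub[list(variables)].to_numpy(dtype=float)
    k = len(variables)
    subset_adj = {}
    for size in range(1, k + 1):
        for combo in combinations(range(k), size):
            subset_adj[tuple(variables[j] for j in combo)] = _adj_r2(y, X[:, combo])
    total = subset_adj[variables]
    if not np.isfinite(total) or total <= 0:
        raise FitError("partition undefined: full-model adjusted R^2 <= 0")
    independent = {}
    for j, v in enumerate(variables):
        rest = tuple(w for w in variables if w != v)
        independent[v] = total - subset_adj[rest]
    joint = total - sum(independent.values())
    neg = any(f < 0 for f in independent.values()) or joint < 0
    return PartitionResult(
        variables=variables, total_adj_r2=total, independent=independent,
        joint=joint,
        independent_relative={v: f / total for v, f in independent.items()},
        joint_relative=joint / total, has_negative_fractions=neg,
        subset_adj_r2=subset_adj)


def robustness_fits(data: pd.DataFrame, response: str = "ratio",
                    predictors=DEFAULT_PREDICTORS,
                    stratum: str | None = None) -> dict:
    """Normality tests plus distribution-robust refits of the driver model.

    For each stratum (or the pooled table) runs Shapiro-Wilk, Lilliefors
    and Anderson-Darling tests on the response, then fits
    (i) OLS on ln(response) with HC3 robust covariance and
    (ii) a gamma GLM with log link, on the standardized predictors, and
    tabulates coefficient signs/significance next to the Gaussian OLS fit.
    Rows with non-positive response are excluded (counted) since both
    robust forms need a positive response.
    """
    groups = ([(None, data)] if stratum is None
              else list(data.groupby(stratum, observed=True, sort=True)))
    report = {}
    for label, grp in groups:
        sub = grp[[response] + list(predictors)].dropna()
        n_nonpos = int((sub[response] <= 0).sum())
        sub = sub[sub[response] > 0]
        entry = {"n": len(sub), "n_nonpositive_excluded": n_nonpos}
        y = sub[response].to_numpy(dtype=float)
        if len(sub) < 20:
            entry["error"] = "too few positive rows"
            report[label] = entry
            continue
        if np.ptp(y) == 0:
            entry["error"] = "zero-variance response: normality tests undefined"
            report[label] = entry
            continue
        sw = stats.shapiro(y if y.size <= 5000 else y[:5000])
        lf = lilliefors(y, dist="norm")
        ad = normal_ad(y)
        entry["normality"] = {"shapiro_wilk": {"stat": float(sw.statistic), "p": float(sw.pvalue)},
                              "lilliefors": {"stat": float(lf[0]), "p": float(lf[1])},
                              "anderson_darling": {"stat": float(ad[0]), "p": float(ad[1])}}
        X = _standardize(sub[list(predictors)].to_numpy(dtype=float))
        Xd = sm.add_constant(X)
        gauss = sm.OLS(y, Xd).fit()
        logols = sm.OLS(np.log(y), Xd).fit(cov_type="HC3")
        try:
            gamma = sm.GLM(y, Xd, family=sm.families.Gamma(
                link=sm.families.links.Log())).fit()
            gamma_ok = True
        except Exception as exc:  # rare IRLS failure on ill-scaled data
            gamma, gamma_ok = None, False
            entry["gamma_error"] = str(exc)
        coefs = []
        for j, name in enumerate(predictors, start=1):
            row = {"variable": name,
                   "gaussian_coef": float(gauss.params[j]),
                   "gaussian_p": float(gauss.pvalues[j]),
                   "log_ols_hc3_coef": float(logols.params[j]),
                   "log_ols_hc3_p": float(logols.pvalues[j])}
            if gamma_ok:
                row["gamma_coef"] = float(gamma.params[j])
                row["gamma_p"] = float(gamma.pvalues[j])
                row["signs_agree"] = (np.sign(row["gaussian_coef"])
                                      == np.sign(row["log_ols_hc3_coef"])
                                      == np.sign(row["gamma_coef"]))
            coefs.append(row)
        entry["coefficients"] = coefs
        report[label] = entry
    return report
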