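"""Driver-attribution tests: AICc importance, partial correlation,
variation partitioning, robustness refits."""

import numpy as np
import pandas as pd
import pytest

from soilcue import (FitError, all_subsets_aicc, partial_correlation,
                     per_variable_glm, robustness_fits,
                     variation_partitioning)
from soilcue.drivers import DEFAULT_PREDICTORS


def _noise_table(rng, n, predictors=DEFAULT_PREDICTORS):
    return pd.DataFrame({p: rng.normal(size=n) for p in predictors})


class TestAllSubsetsAicc:
    def test_weights_normalized_on_toy_set(self, rng):
        n = 50
        df = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        df["y"] = df["a"] + rng.normal(size=n)
        res = all_subsets_aicc(df, response="y", predictors=("a", "b"))
        assert res.model_count == 4
        assert res.weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert all(0 <= v <= 1 for v in res.importance.values())

    def test_single_planted_driver_dominates(self):
        rng = np.random.default_rng(0)
        df = _noise_table(rng, 500)
        df["ratio"] = 2.0 * df["lai"] + rng.normal(0, 0.1, 500)
        res = all_subsets_aicc(df)
        assert res.importance["lai"] > 0.99
        assert all(v < 0.5 for k, v in res.importance.items() if k != "lai")
        assert res.essential_set() == ("lai",)

    def test_pure_noise_response_finds_nothing(self, rng):
        df = _noise_table(rng, 500)
        df["ratio"] = rng.normal(size=500)
        res = all_subsets_aicc(df)
        assert max(res.importance.values()) < 0.8

    def test_collinear_predictors_named(self, rng):
        df = _noise_table(rng, 200, predictors=("a", "b"))
        df["c"] = df["a"] + df["b"]
        df["y"] = rng.normal(size=200)
        with pytest.raises(FitError, match="collinear"):
            all_subsets_aicc(df, response="y", predictors=("a", "b", "c"))

    def test_undersized_table_rejected(self, rng):
        df = _noise_table(rng, 15)
        df["ratio"] = rng.normal(size=15)
        with pytest.raises(FitError):
            all_subsets_aicc(df)


class TestPerVariableGlm:
    def test_exact_relation_gives_unit_r2(self):
        x = np.linspace(0, 10, 30)
        df = pd.DataFrame({"x1": x, "ratio": 2 * x + 1, "stratum": "low"})
        out = per_variable_glm(df, "stratum", predictors=("x1",))
        assert out.loc[0, "r2"] == pytest.approx(1.0)

    def test_constant_predictor_skipped(self):
        df = pd.DataFrame({"x1": np.ones(30),
                           "ratio": np.random.default_rng(0).normal(size=30),
                           "stratum": "low"})
        out = per_variable_glm(df, "stratum", predictors=("x1",))
        assert out.loc[0, "skipped"] == "constant predictor"

    def test_strong_stratum_explains_more_than_weak(self, paired):
        out = per_variable_glm(paired, "productivity_class",
                               response="cue_st").dropna(subset=["r2"])
        means = out.groupby("stratum")["r2"].mean()
        assert means["low"] > means["high"]


class TestPartialCorrelation:
    def test_identical_pair_fully_correlated(self, rng):
        n = 200
        df = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n),
                           "c3": rng.normal(size=n)})
        df["x"] = rng.normal(size=n)
        df["y"] = df["x"]
        r, p = partial_correlation(df, "x", "y", ["c1", "c2", "c3"])
        assert r == pytest.approx(1.0, abs=1e-10)

    def test_confounded_pair_near_zero(self, rng):
        n = 1000
        c = rng.normal(size=n)
        df = pd.DataFrame({"c": c,
                           "x": c + rng.normal(0, 0.5, n),
                           "y": c + rng.normal(0, 0.5, n)})
        r, p = partial_correlation(df, "x", "y", ["c"])
        # no direct x-y link once c is controlled
        assert abs(r) < 2.5 / np.sqrt(n - 3)

    def test_matches_two_stage_residual_oracle(self, rng):
        n = 300
        df = pd.DataFrame({
            "c1": rng.normal(size=n), "c2": rng.normal(size=n),
            "c3": rng.normal(size=n)})
        df["x"] = 0.5 * df["c1"] + rng.normal(size=n)
        df["y"] = 0.3 * df["x"] - 0.4 * df["c2"] + rng.normal(size=n)
        r, _ = partial_correlation(df, "x", "y", ["c1", "c2", "c3"])
        C = np.column_stack([np.ones(n), df[["c1", "c2", "c3"]].to_numpy()])
        rx = df["x"] - C @ np.linalg.lstsq(C, df["x"], rcond=None)[0]
        ry = df["y"] - C @ np.linalg.lstsq(C, df["y"], rcond=None)[0]
        oracle = float(np.corrcoef(rx, ry)[0, 1])
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        n = 250
        df = pd.DataFrame({"c1": rng.normal(size=n), "c2": rng.normal(size=n)})
        df["x"] = df["c1"] + rng.normal(size=n)
        df["y"] = 0.4 * df["x"] + df["c2"] + rng.normal(size=n)
        r, p = partial_correlation(df, "x", "y", ["c1", "c2"])
        ref = pingouin.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_singular_controls_rejected(self, rng):
        n = 100
        c = rng.normal(size=n)
        df = pd.DataFrame({"c1": c, "c2": 2 * c, "x": rng.normal(size=n),
                           "y": rng.normal(size=n)})
        with pytest.raises(FitError, match="singular"):
            partial_correlation(df, "x", "y", ["c1", "c2"])


class TestVariationPartitioning:
    def test_orthogonal_equal_contributions(self):
        # balanced full-factorial design: exactly orthogonal columns
        rng = np.random.default_rng(8)
        n = 1024
        X = rng.normal(size=(n, 4))
        Q, _ = np.linalg.qr(X)
        X = Q * np.sqrt(n)
        y = X.sum(axis=1) + rng.normal(0, 0.5, n)
        df = pd.DataFrame(X, columns=["v1", "v2", "v3", "v4"])
        df["y"] = y
        res = variation_partitioning(df, "y", ("v1", "v2", "v3", "v4"))
        fracs = np.array(list(res.independent.values()))
        assert np.allclose(fracs, fracs.mean(), atol=0.02)
        assert abs(res.joint) < 0.02

    def test_duplicated_predictors_share_jointly(self, rng):
        n = 400
        a = rng.normal(size=n)
        df = pd.DataFrame({"a1": a, "a2": a + rng.normal(0, 1e-6, n),
                           "b": rng.normal(size=n), "c": rng.normal(size=n)})
        df["y"] = a + rng.normal(0, 0.3, n)
        res = variation_partitioning(df, "y", ("a1", "a2", "b", "c"))
        assert abs(res.independent["a1"]) < 0.01
        assert abs(res.independent["a2"]) < 0.01
        assert res.joint > 0.5

    def test_partition_identity(self, rng):
        n = 500
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        df["b"] += 0.6 * df["a"]
        df["y"] = df["a"] - 0.5 * df["b"] + 0.2 * df["c"] + rng.normal(size=n)
        res = variation_partitioning(df, "y", ("a", "b", "c", "d"))
        total = sum(res.independent.values()) + res.joint
        assert total == pytest.approx(res.total_adj_r2, abs=1e-10)

    def test_matches_subset_enumeration_oracle(self, rng):
        from itertools import combinations
        n = 300
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        df["y"] = df["a"] + 0.5 * df["b"] + rng.normal(size=n)
        res = variation_partitioning(df, "y", ("a", "b", "c", "d"))

        def adj_r2(cols):
            X = np.column_stack([np.ones(n), df[list(cols)].to_numpy()])
            b, *_ = np.linalg.lstsq(X, df["y"], rcond=None)
            r = df["y"] - X @ b
            rss = float(r @ r)
            tss = float(((df["y"] - df["y"].mean()) ** 2).sum())
            p = len(cols)
            return 1 - (rss / (n - p - 1)) / (tss / (n - 1))

        for v in "abcd":
            rest = [w for w in "abcd" if w != v]
            oracle = adj_r2(list("abcd")) - adj_r2(rest)
            assert res.independent[v] == pytest.approx(oracle, abs=1e-10)

    def test_unexplained_response_flagged(self, rng):
        n = 100
        df = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("abcd"))
        df["y"] = rng.normal(size=n)
        with pytest.raises(FitError, match="undefined"):
            variation_partitioning(df, "y", ("a", "b", "c", "d"))


class TestRobustnessFits:
    def test_lognormal_response_detected_and_log_restores_normality(self, rng):
        n = 500
        df = pd.DataFrame({p: rng.normal(size=n) for p in DEFAULT_PREDICTORS})
        df["ratio"] = np.exp(rng.normal(0, 0.8, n))
        rep = robustness_fits(df)[None]
        assert rep["normality"]["shapiro_wilk"]["p"] < 0.001
        from scipy import stats
        assert stats.shapiro(np.log(df["ratio"])).pvalue > 0.05

    def test_signs_agree_on_well_specified_model(self, rng):
        n = 600
        df = pd.DataFrame({p: rng.normal(size=n) for p in DEFAULT_PREDICTORS})
        eta = 0.5 * df["lai"] - 0.4 * df["ph"]
        df["ratio"] = np.exp(eta + rng.normal(0, 0.3, n))
        rep = robustness_fits(df)[None]
        strong = {c["variable"]: c for c in rep["coefficients"]
                  if c["variable"] in ("lai", "ph")}
        assert all(c["signs_agree"] for c in strong.values())
        assert strong["lai"]["gaussian_coef"] > 0 > strong["ph"]["gaussian_coef"]

    def test_constant_response_reported_gracefully(self, rng):
        n = 50
        df = pd.DataFrame({p: rng.normal(size=n) for p in DEFAULT_PREDICTORS})
        df["ratio"] = 1.0
        rep = robustness_fits(df)[None]
        assert "zero-variance" in rep["error"]

    def test_nonpositive_rows_excluded_and_counted(self, rng):
        n = 300
        df = pd.DataFrame({p: rng.normal(size=n) for p in DEFAULT_PREDICTORS})
        df["ratio"] = np.exp(rng.normal(size=n))
        df.loc[:9, "ratio"] = -1.0
        rep = robustness_fits(df)[None]
        assert rep["n_nonpositive_excluded"] == 10
        assert rep["n"] == n - 10
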