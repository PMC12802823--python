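"""Segmented-regression, stratified-line and nonlinear-candidate tests."""

import numpy as np
import pandas as pd
import pytest

from soilcue import (FitError, SegmentedRegression, fit_nonlinear_candidates,
                     fit_segmented, fit_stratified_glm)


def brute_force_breakpoint(x, y, min_segment_frac=0.05, min_segment_size=10):
    """Independent oracle: exhaustive scan of every midpoint between
    consecutive distinct sorted x values, plain OLS at each candidate."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xs = np.sort(x)
    n = x.size
    lo, hi = np.quantile(xs, [min_segment_frac, 1 - min_segment_frac])
    m = max(min_segment_size, int(np.ceil(min_segment_frac * n)))
    ux = np.unique(xs)
    best = (np.inf, None)
    for psi in 0.5 * (ux[:-1] + ux[1:]):
        n_left = int(np.searchsorted(xs, psi, side="right"))
        if not (lo <= psi <= hi and m <= n_left <= n - m):
            continue
        X = np.column_stack([np.ones(n), x, np.maximum(x - psi, 0.0)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        sse = float(r @ r)
        if sse < best[0]:
            best = (sse, psi)
    return best


class TestSegmentedFit:
    def test_exact_piecewise_input_recovered(self):
        rh = np.linspace(1, 600, 200)
        cue = np.where(rh < 300, 0.5 - 0.001 * rh, 0.2)
        res = fit_segmented((rh, cue))
        assert res.has_threshold
        assert res.psi == pytest.approx(300.0, abs=(rh[1] - rh[0]))
        assert res.slope_pre == pytest.approx(-0.001, abs=1e-8)
        assert abs(res.slope_post) < 1e-8

    def test_pure_line_flagged_no_threshold(self):
        rh = np.linspace(1, 600, 200)
        res = fit_segmented((rh, 0.5 - 0.0005 * rh))
        assert not res.has_threshold

    def test_noisy_null_flagged_in_most_replicates(self):
        flagged = 0
        for s in range(10):
            rng = np.random.default_rng(s)
            rh = rng.lognormal(5.5, 0.8, 400)
            cue = 0.3 + rng.normal(0, 0.08, 400)
            flagged += not fit_segmented((rh, cue)).has_threshold
        assert flagged >= 8

    def test_matches_brute_force_oracle(self):
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            x = rng.uniform(0, 1000, 150)
            y = np.where(x < 400, 0.45 - 3e-4 * x, 0.33) + rng.normal(0, 0.05, 150)
            res = fit_segmented((x, y))
            sse_oracle, _ = brute_force_breakpoint(x, y)
            assert res.sse <= sse_oracle + 1e-9

    def test_two_segment_sse_never_worse_than_line(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0, 1000, 300)
        y = rng.normal(0.3, 0.1, 300)
        res = fit_segmented((x, y))
        assert res.sse <= res.sse_line + 1e-12

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 1000, 500)
        y = np.where(x < 340, 0.4 - 4e-4 * x, 0.4 - 4e-4 * 340) \
            + rng.normal(0, 0.05, 500)
        base = fit_segmented((x, y))
        shifted = fit_segmented((x, y + 0.7))
        assert shifted.psi == pytest.approx(base.psi, rel=1e-9)
        assert shifted.slope_pre == pytest.approx(base.slope_pre, rel=1e-9)
        assert shifted.intercept == pytest.approx(base.intercept + 0.7, rel=1e-9)
        scaled = fit_segmented((x * 3.0, y))
        assert scaled.psi == pytest.approx(3.0 * base.psi, rel=1e-6)

    def test_recovers_synthetic_breakpoint(self):
        from soilcue import SyntheticConfig, generate_paired_dataset
        df = generate_paired_dataset(SyntheticConfig(seed=1))
        res = fit_segmented(df, x="rh_annual_area", y="cue_true")
        assert res.has_threshold
        assert res.psi == pytest.approx(340.0, abs=30.0)
        assert res.slope_pre < 0

    def test_median_recovery_and_flat_plateau_over_replicates(self):
        from soilcue import SyntheticConfig, generate_paired_dataset
        errs, flat = [], 0
        for s in range(100):
            df = generate_paired_dataset(SyntheticConfig(seed=s))
            res = fit_segmented(df, x="rh_annual_area", y="cue_true")
            errs.append(abs(res.psi - 340.0))
            flat += res.p_post > 0.05
        assert np.median(errs) <= 30.0
        assert flat >= 80

    def test_too_few_points_rejected(self):
        with pytest.raises(FitError):
            fit_segmented((np.arange(10.0), np.arange(10.0)))

    def test_degenerate_x_rejected(self):
        x = np.repeat([1.0, 2.0], 15)
        with pytest.raises(FitError):
            fit_segmented((x, np.random.default_rng(0).normal(size=30)))


class TestBootstrap:
    def test_noiseless_breakpoint_gives_narrow_ci(self):
        rh = np.linspace(1, 600, 240)
        cue = np.where(rh < 300, 0.5 - 0.001 * rh, 0.2)
        res = fit_segmented((rh, cue))
        boot = res.bootstrap_ci(n_boot=100, seed=1)
        grid_step = rh[1] - rh[0]
        # degenerate bootstrap: psi moves by at most one grid gap each way
        assert boot.psi_ci_high - boot.psi_ci_low <= 2 * grid_step + 1e-9

    def test_single_resample_rejected(self):
        rh = np.linspace(1, 600, 100)
        res = fit_segmented((rh, np.where(rh < 300, 0.5 - 0.001 * rh, 0.2)))
        with pytest.raises(FitError):
            res.bootstrap_ci(n_boot=1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1000, 300)
        y = np.where(x < 340, 0.4 - 4e-4 * x, 0.264) + rng.normal(0, 0.06, 300)
        res = fit_segmented((x, y))
        b1 = res.bootstrap_ci(n_boot=50, seed=99)
        b2 = res.bootstrap_ci(n_boot=50, seed=99)
        assert np.array_equal(b1.psis, b2.psis)


class TestStratifiedGlm:
    def test_exact_line_per_stratum(self):
        rh = np.linspace(10, 500, 40)
        df = pd.DataFrame({"rh": rh, "cue": 0.4 - 0.0005 * rh, "zone": "arid"})
        out = fit_stratified_glm(df, "zone")
        assert out.loc[0, "slope"] == pytest.approx(-0.0005, rel=1e-9)
        assert out.loc[0, "r2"] == pytest.approx(1.0)

    def test_permuted_response_not_significant(self):
        rng = np.random.default_rng(12)
        rh = rng.uniform(0, 1000, 200)
        cue = rng.permutation(0.2 + 0.3 * rh / 1000)
        out = fit_stratified_glm(
            pd.DataFrame({"rh": rh, "cue": cue, "zone": "cold"}), "zone")
        assert out.loc[0, "p"] > 0.05

    def test_small_stratum_skipped_with_reason(self):
        df = pd.DataFrame({
            "rh": list(np.linspace(1, 100, 20)) + [1.0, 2.0, 3.0],
            "cue": list(np.linspace(0.5, 0.2, 20)) + [0.3, 0.31, 0.29],
            "zone": ["big"] * 20 + ["tiny"] * 3})
        out = fit_stratified_glm(df, "zone").set_index("stratum")
        assert out.loc["big", "skipped"] == ""
        assert "n=3" in out.loc["tiny", "skipped"]
        assert len(out) == 2


class TestNonlinearCandidates:
    def test_logarithmic_data_prefers_logarithmic(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(10, 1000, 300)
        y = 0.6 - 0.05 * np.log(x) + rng.normal(0, 0.003, 300)
        out = fit_nonlinear_candidates((x, y))
        assert out.loc[0, "form"] == "logarithmic"

    def test_quadratic_data_prefers_quadratic(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 300)
        y = 1.0 - 0.5 * x + 0.04 * x ** 2 + rng.normal(0, 0.01, 300)
        out = fit_nonlinear_candidates((x, y))
        assert out.loc[0, "form"] == "quadratic"

    def test_flat_data_gives_near_zero_slopes(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(10, 1000, 2000)
        y = np.full(2000, 0.3) + rng.normal(0, 1e-6, 2000)
        out = fit_nonlinear_candidates((x, y)).set_index("form")
        assert abs(out.loc["logarithmic", "coefficients"]["b"]) < 1e-6
        assert abs(out.loc["quadratic", "coefficients"]["b"]) < 1e-6
        assert abs(out.loc["exponential", "coefficients"]["b"]) < 1e-6

    def test_nonpositive_x_flags_logarithmic_only(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(-5, 10, 100)
        y = 0.1 * x + rng.normal(0, 0.1, 100)
        out = fit_nonlinear_candidates((x, y)).set_index("form")
        assert not out.loc["logarithmic", "converged"]
        assert out.loc["quadratic", "converged"]
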