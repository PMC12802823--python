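"""Synthetic global-style CUE/R_h dataset generator.

Emulates the statistical structure the threshold and driver analyses
assume, so the whole pipeline can be exercised without any external data:

* four climate zones with zone-specific heterotrophic respiration (R_h,
  lognormal; arid/cold mass mostly below the breakpoint, tropical/
  temperate mostly above) and leaf area index (LAI; arid/cold almost
  entirely below the productivity cutoff of 3, tropical/temperate above);
* a piecewise-linear true CUE mean: declining with R_h below the
  breakpoint, flat at a low plateau above it, plus truncated Gaussian
  noise and planted covariate effects (strong in the low-productivity
  stratum, weak in the high-productivity stratum);
* enzyme, biomass and nutrient pools derived from each row's CUE by exact
  closed-form inversion of the stoichiometric model, so running the
  forward estimator on the generated pools reproduces the target CUE to
  floating-point accuracy.

All randomness flows from a single ``numpy.random.default_rng`` (PCG64)
seeded from the config; a fixed seed gives a bit-identical table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ConfigError, EmptyInputError, InvalidRecordError
from .stoichiometry import CLIMATE_ZONES, CueParameters, invert_scalar

__all__ = ["SyntheticConfig", "generate_paired_dataset", "invert_cue_to_pools",
           "write_fixture", "CSV_COLUMNS"]

#: Shared CSV schema (header order) for generated fixtures.
CSV_COLUMNS = [
    "site_id", "latitude", "longitude", "climate_zone", "depth_m",
    "bulk_density", "soc", "tn", "tp", "mbc", "mbn", "mbp",
    "bg", "nag", "lap", "ap",
    "mat", "soil_mat", "map_mm", "lai", "agb", "bgb", "ph", "cec", "clay",
    "rh_annual_area", "rh_daily_area", "productivity_class", "cue_true",
]

# zone-specific generator settings: lognormal R_h (median, sigma of log),
# scaled-Beta LAI (lo, hi, alpha, beta), mean annual temperature (mean, sd),
# rough latitude band
_ZONE_SETTINGS = {
    "tropical": {"rh": (950.0, 0.40), "lai": (3.00, 5.69, 3.0, 1.5),
                 "mat": (24.0, 2.0), "lat": (0.0, 15.0)},
    "temperate": {"rh": (650.0, 0.45), "lai": (2.20, 5.69, 3.0, 2.0),
                  "mat": (9.0, 4.0), "lat": (45.0, 8.0)},
    "arid": {"rh": (150.0, 0.55), "lai": (0.06, 2.50, 2.0, 2.5),
             "mat": (14.0, 6.0), "lat": (30.0, 8.0)},
    "cold": {"rh": (170.0, 0.55), "lai": (0.06, 3.30, 2.0, 2.5),
             "mat": (-3.0, 4.0), "lat": (60.0, 6.0)},
}


@dataclass
class SyntheticConfig:
    """Settings of the synthetic dataset.

    Defaults mirror the global study conditions: 1094 sites, a breakpoint
    at 340 g C m^-2 yr^-1 with pre-threshold slope -4e-4 per flux unit and
    a flat post-threshold plateau at CUE 0.27, LAI spanning 0.06-5.69 with
    the productivity cutoff at 3, and a roughly 56/44 low/high-productivity
    split.  ``cue_noise_sd`` is measurement-scale noise and ``site_sd``
    unexplained between-site heterogeneity; together they set the plateau
    spread (~0.1).  ``covariate_effects`` are planted per-SD effects on CUE
    applied at full strength in the low-productivity stratum and scaled by
    ``high_productivity_effect_scale`` in the high stratum.
    """

    n_sites: int = 1094
    seed: int | None = None
    zone_proportions: dict = field(default_factory=lambda: {
        "tropical": 0.17, "temperate": 0.27, "arid": 0.28, "cold": 0.28})
    true_breakpoint: float = 340.0
    slope_pre: float = -4.0e-4
    slope_post: float = 0.0
    cue_plateau: float = 0.27
    cue_cap: float = 0.50
    cue_noise_sd: float = 0.08
    site_sd: float = 0.05
    cue_bounds: tuple = (0.05, 0.6)
    lai_cutoff: float = 3.0
    covariate_effects: dict = field(default_factory=lambda: {
        "ph": 0.030, "cec": -0.030, "clay": 0.030})
    high_productivity_effect_scale: float = 0.3
    daily_annual_ratio: float = 6.4
    depth_m: float = 0.1
    params: CueParameters = field(default_factory=CueParameters)

    def validate(self):
        if self.n_sites <= 0:
            raise ConfigError(f"n_sites must be positive, got {self.n_sites}")
        if set(self.zone_proportions) != set(CLIMATE_ZONES):
            raise ConfigError(f"zone_proportions must cover {CLIMATE_ZONES}")
        total = sum(self.zone_proportions.values())
        if abs(total - 1.0) > 1e-9 or any(p < 0 for p in self.zone_proportions.values()):
            raise ConfigError(f"zone proportions must be nonnegative and sum to 1, got {total}")
        lo, hi = self.cue_bounds
        if not (0 < lo < self.cue_plateau < hi <= self.params.cue_max):
            raise ConfigError("cue_bounds must bracket the plateau within (0, cue_max]")
        if self.true_breakpoint <= 0 or self.cue_noise_sd < 0 or self.site_sd < 0:
            raise ConfigError("breakpoint must be positive and noise SDs nonnegative")
        return self


def invert_cue_to_pools(cue_target, params: CueParameters = CueParameters(),
                        seed=None, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Derive enzyme/biomass/nutrient pools that reproduce target CUE values.

    Solves the stoichiometric model for the common saturation scalar
    s = s_cn = s_cp of each target, draws biomass and resource molar
    ratios lognormally around literature-plausible centres (microbial
    C:N ~ 8, C:P ~ 60; soil C:N ~ 12, C:P ~ 186), and sets the enzyme
    activity ratios so the identity s = (B/L)/EEA holds exactly.  The
    forward model applied to the returned pools recovers every target to
    ~1e-10.

    Returns a DataFrame with columns soc, tn, tp, mbc, mbn, mbp, bg, nag,
    lap, ap (one row per target).
    """
    cue = np.atleast_1d(np.asarray(cue_target, dtype=float))
    if np.any(~np.isfinite(cue)) or np.any(cue <= 0) or np.any(cue >= params.cue_max):
        raise InvalidRecordError(
            "cue_target", f"targets must lie strictly inside (0, cue_max={params.cue_max})")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = cue.size
    s = np.array([invert_scalar(c, params) for c in cue])

    b_cn = rng.lognormal(np.log(8.0), 0.25, n)
    l_cn = rng.lognormal(np.log(12.0), 0.30, n)
    b_cp = rng.lognormal(np.log(60.0), 0.30, n)
    l_cp = rng.lognormal(np.log(186.0), 0.35, n)
    eea_cn = (b_cn / l_cn) / s
    eea_cp = (b_cp / l_cp) / s

    mc, mn, mp = params.atomic_mass_c, params.atomic_mass_n, params.atomic_mass_p
    soc = rng.lognormal(np.log(20.0), 0.5, n)          # g kg^-1
    tn = soc * (mn / mc) / l_cn
    tp = soc * (mp / mc) / l_cp
    mbc = rng.lognormal(np.log(400.0), 0.5, n)          # mg kg^-1
    mbn = mbc * (mn / mc) / b_cn
    mbp = mbc * (mp / mc) / b_cp
    bg = rng.lognormal(np.log(100.0), 0.4, n)           # nmol g^-1 h^-1
    nag_lap = bg / eea_cn
    nag = 0.7 * nag_lap
    lap = 0.3 * nag_lap
    ap = bg / eea_cp
    return pd.DataFrame({"soc": soc, "tn": tn, "tp": tp, "mbc": mbc,
                         "mbn": mbn, "mbp": mbp, "bg": bg, "nag": nag,
                         "lap": lap, "ap": ap})


def _truncated_normal(rng, mean, sd, lo, hi):
    """Row-wise truncated-normal draws (keeps n exact, no boundary atoms)."""
    a = (lo - mean) / sd
    b = (hi - mean) / sd
    u = rng.random(np.shape(mean))
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def generate_paired_dataset(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Generate the full synthetic paired table.

    Draws zone -> R_h, LAI, covariates -> true CUE (piecewise in R_h plus
    planted covariate effects and truncated noise) -> pools by exact model
    inversion.  Returns a DataFrame in the shared CSV schema plus the
    ``cue_true`` column.
    """
    config = (config or SyntheticConfig()).validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_sites
    zones = rng.choice(CLIMATE_ZONES, size=n,
                       p=[config.zone_proportions[z] for z in CLIMATE_ZONES])

    rh = np.empty(n)
    lai = np.empty(n)
    mat = np.empty(n)
    lat = np.empty(n)
    for z in CLIMATE_ZONES:
        m = zones == z
        cnt = int(m.sum())
        st = _ZONE_SETTINGS[z]
        med, sig = st["rh"]
        rh[m] = rng.lognormal(np.log(med), sig, cnt)
        lo, hi, a, b = st["lai"]
        lai[m] = lo + (hi - lo) * rng.beta(a, b, cnt)
        mu, sd = st["mat"]
        mat[m] = rng.normal(mu, sd, cnt)
        lmu, lsd = st["lat"]
        lat[m] = rng.normal(lmu, lsd, cnt) * rng.choice([-1, 1], cnt)

    soil_mat = mat + rng.normal(1.5, 1.0, n)
    map_mm = np.clip(200.0 + 1.1 * rh + rng.normal(0, 150.0, n), 30.0, None)
    agb = np.clip(200.0 + 800.0 * lai + rng.normal(0, 300.0, n), 10.0, None)
    bgb = np.clip(0.35 * agb + rng.normal(0, 80.0, n), 5.0, None)
    ph = np.clip(rng.normal(6.5, 1.0, n), 3.5, 9.5)
    clay = np.clip(rng.normal(25.0, 12.0, n), 2.0, 70.0)
    cec = np.clip(2.0 + 0.2 * clay + rng.normal(0, 6.0, n), 1.0, None)
    bulk_density = np.clip(rng.normal(1.3, 0.15, n), 0.8, 1.8)

    # piecewise true mean in R_h
    psi = config.true_breakpoint
    mean_cue = np.where(
        rh < psi,
        config.cue_plateau + config.slope_pre * (rh - psi),
        config.cue_plateau + config.slope_post * (rh - psi))
    mean_cue = np.minimum(mean_cue, config.cue_cap)

    # planted covariate effects (per standardized covariate, scaled down in
    # the high-productivity stratum)
    covs = {"mat": mat, "soil_mat": soil_mat, "map_mm": map_mm, "lai": lai,
            "agb": agb, "bgb": bgb, "ph": ph, "cec": cec, "clay": clay}
    scale = np.where(lai < config.lai_cutoff, 1.0,
                     config.high_productivity_effect_scale)
    for name, gamma in config.covariate_effects.items():
        v = covs[name]
        z = (v - v.mean()) / v.std(ddof=1)
        mean_cue = mean_cue + gamma * scale * z

    total_sd = float(np.hypot(config.cue_noise_sd, config.site_sd))
    lo, hi = config.cue_bounds
    if total_sd > 0:
        cue = _truncated_normal(rng, mean_cue, total_sd, lo, hi)
    else:
        cue = np.clip(mean_cue, lo, hi)

    pools = invert_cue_to_pools(cue, config.params, rng=rng)

    df = pd.DataFrame({
        "site_id": [f"S{i:04d}" for i in range(1, n + 1)],
        "latitude": np.clip(lat, -89.9, 89.9),
        "longitude": rng.uniform(-180.0, 180.0, n),
        "climate_zone": zones,
        "depth_m": np.full(n, config.depth_m),
        "bulk_density": bulk_density,
    })
    df = pd.concat([df, pools], axis=1)
    df["mat"] = mat
    df["soil_mat"] = soil_mat
    df["map_mm"] = map_mm
    df["lai"] = lai
    df["agb"] = agb
    df["bgb"] = bgb
    df["ph"] = ph
    df["cec"] = cec
    df["clay"] = clay
    df["rh_annual_area"] = rh
    df["rh_daily_area"] = rh * config.daily_annual_ratio / 365.0
    df["productivity_class"] = np.where(lai < config.lai_cutoff, "low", "high")
    df["cue_true"] = cue
    return df[CSV_COLUMNS]


def write_fixture(dataset: pd.DataFrame, path) -> None:
    """Write a generated table to CSV in the shared schema.

    Floats are written with shortest round-trip repr, so re-reading the
    file reproduces every numeric field exactly.
    """
    if dataset is None or len(dataset) == 0:
        raise EmptyInputError("refusing to write an empty fixture")
    missing = [c for c in CSV_COLUMNS if c not in dataset.columns]
    if missing:
        raise ConfigError(f"dataset lacks schema columns: {missing}")
    dataset[CSV_COLUMNS].to_csv(path, index=False)
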