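"""Validated table I/O, run configuration, and the end-to-end pipeline.

The pipeline chains the package's stages in analysis order:
CUE estimation from pools -> respiration unit conversion -> pairing and
stratification -> threshold detection -> driver attribution -> removal
sensitivity.  Every stage keeps an explicit accept/reject ledger so that
accepted + rejected always equals the input row count, and all randomness
descends from the single run seed via ``numpy.random.SeedSequence``
spawning (one child stream per stochastic stage, in a fixed order).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import drivers as drv
from . import units
from .exceptions import ConfigError, SchemaError
from .segmented import fit_segmented, fit_stratified_glm
from .sensitivity import stratified_removal_test
from .stoichiometry import CLIMATE_ZONES, CueParameters, cue_pipeline

__all__ = ["RunConfig", "read_table", "build_paired_table",
           "run_full_pipeline", "write_json"]

logger = logging.getLogger("soilcue")

#: Columns that must be present in an input table.
MANDATORY_COLUMNS = ["site_id", "climate_zone", "soc", "tn", "tp",
                     "mbc", "mbn", "mbp", "bg", "nag", "lap", "ap",
                     "rh_annual_area", "lai"]

_RUNCONFIG_RANGES = {
    "n_boot": (2, 10**6), "min_segment_frac": (0.0, 0.5),
    "lai_cutoff": (0.0, 20.0), "removal_frac": (0.0, 1.0),
    "n_reps": (1, 10**6),
}


@dataclass
class RunConfig:
    """Settings of a full pipeline run."""

    seed: int = 20260114
    n_boot: int = 1000
    min_segment_frac: float = 0.05
    lai_cutoff: float = 3.0
    removal_frac: float = 0.2
    n_reps: int = 1000
    x: str = "rh_annual_area"
    y: str = "cue_st"
    allow_missing_lap: bool = False
    log_level: str = "INFO"
    out_dir: str | None = None
    params: CueParameters = field(default_factory=CueParameters)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def validate(self) -> "RunConfig":
        for name, (lo, hi) in _RUNCONFIG_RANGES.items():
            v = getattr(self, name)
            if not (lo < v <= hi) and not (name == "n_reps" and lo <= v <= hi):
                raise ConfigError(f"{name}={v} outside ({lo}, {hi}]")
        return self

    def config_hash(self) -> str:
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_table(path, mandatory=MANDATORY_COLUMNS):
    """Read and validate the shared CSV schema.

    Returns ``(accepted, rejects)`` where ``rejects`` lists row index and
    reason for every row-level violation (non-positive bulk density or
    depth, unknown climate zone, negative fluxes/LAI).  Missing cells are
    permitted (they surface later as per-stage rejects); missing mandatory
    *columns* raise a :class:`SchemaError` naming them.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")
    reasons = pd.Series("", index=df.index, dtype=object)

    def flag(mask, reason):
        mask = mask & (reasons == "")
        reasons[mask] = reason

    if "bulk_density" in df:
        flag(df["bulk_density"].notna() & (df["bulk_density"] <= 0),
             "bulk_density must be positive")
    if "depth_m" in df:
        flag(df["depth_m"].notna() & (df["depth_m"] <= 0), "depth_m must be positive")
    flag(df["climate_zone"].notna() & ~df["climate_zone"].isin(CLIMATE_ZONES),
         f"climate_zone not in {CLIMATE_ZONES}")
    flag(df["rh_annual_area"].notna() & (df["rh_annual_area"] < 0),
         "rh_annual_area must be non-negative")
    flag(df["lai"].notna() & (df["lai"] < 0), "lai must be non-negative")

    bad = reasons != ""
    rejects = pd.DataFrame({"row": df.index[bad],
                            "site_id": df.loc[bad, "site_id"],
                            "reason": reasons[bad]})
    accepted = df[~bad].reset_index(drop=True)
    assert len(accepted) + len(rejects) == len(df)
    logger.info("read %d rows (%d accepted, %d rejected)",
                len(df), len(accepted), len(rejects))
    return accepted, rejects


def build_paired_table(data: pd.DataFrame, config: RunConfig):
    """CUE estimation, unit conversion and pairing in one pass.

    Returns ``(paired, cue_table)``: the per-site CUE table with reject
    reasons, and the paired analysis table restricted to rows with a valid
    CUE and positive R_h, carrying the stratification columns and the
    CUE/R_h ratio.
    """
    cue_tab = cue_pipeline(data, config.params,
                           allow_missing_lap=config.allow_missing_lap)
    merged = data.reset_index(drop=True).copy()
    merged["cue_st"] = cue_tab["cue_st"].to_numpy()
    merged["reject_reason"] = cue_tab["reject_reason"].to_numpy()
    if "bulk_density" in merged:
        bd = merged["bulk_density"].to_numpy(dtype=float)
        h = merged["depth_m"].to_numpy(dtype=float) if "depth_m" in merged \
            else units.DEFAULT_DEPTH_M
        with np.errstate(invalid="ignore", divide="ignore"):
            merged["rh_annual_mass"] = np.where(
                bd > 0, merged["rh_annual_area"] / (bd * np.asarray(h) * 1000.0),
                np.nan)
    if "rh_daily_area" in merged:
        merged["rh_annual_from_daily"] = merged["rh_daily_area"] * units.DAYS_PER_YEAR
    merged["productivity_class"] = np.where(
        merged["lai"] < config.lai_cutoff, "low", "high")
    ok = merged["cue_st"].notna() & (merged["rh_annual_area"] > 0)
    paired = merged[ok].reset_index(drop=True).copy()
    paired["ratio"] = paired["cue_st"] / paired["rh_annual_area"]
    logger.info("paired table: %d of %d rows usable", len(paired), len(merged))
    return paired, merged


def run_full_pipeline(data, config: RunConfig | None = None) -> dict:
    """Execute every analysis stage on an input table (path or DataFrame).

    Returns a results bundle with per-stage outputs, the config hash and
    the seed; identical config and input give identical output.
    """
    config = (config or RunConfig()).validate()
    logging.basicConfig(level=config.log_level)
    stage = "read"
    try:
        if isinstance(data, (str, Path)):
            accepted, rejects = read_table(data)
        else:
            accepted, rejects = data.copy(), pd.DataFrame(columns=["row", "site_id", "reason"])

        stage = "pairing"
        paired, cue_table = build_paired_table(accepted, config)

        # independent child streams, spawned in fixed order
        ss = np.random.SeedSequence(config.seed)
        seed_boot, seed_sens = [int(s.generate_state(1)[0]) % (2**31)
                                for s in ss.spawn(2)]

        stage = "threshold"
        seg = fit_segmented(paired, x=config.x, y=config.y,
                            min_segment_frac=config.min_segment_frac)
        boot = seg.bootstrap_ci(n_boot=config.n_boot, seed=seed_boot)
        threshold = seg.to_dict()
        threshold.update({"psi_ci_low": boot.psi_ci_low,
                          "psi_ci_high": boot.psi_ci_high,
                          "psi_se": boot.psi_se, "n_boot": boot.n_boot,
                          "n_boot_failures": boot.n_failures})
        zone_fits = fit_stratified_glm(paired, "climate_zone",
                                       x=config.x, y=config.y)
        prod_fits = fit_stratified_glm(paired, "productivity_class",
                                       x=config.x, y=config.y)

        stage = "drivers"
        driver_out = {}
        for label, grp in paired.groupby("productivity_class", sort=True):
            try:
                imp = drv.all_subsets_aicc(grp, response="ratio")
                driver_out[label] = {
                    "importance": imp.importance,
                    "essential": list(imp.essential_set()),
                    "model_count": imp.model_count,
                    "total_r2": imp.total_r2, "n": imp.nobs}
            except Exception as exc:
                driver_out[label] = {"error": str(exc)}
        pv = drv.per_variable_glm(paired, "productivity_class")
        pcors = {}
        for v in drv.KEY_VARIABLES:
            ctrl = [w for w in drv.KEY_VARIABLES if w != v]
            r, p = drv.partial_correlation(paired, v, config.y, ctrl)
            pcors[v] = {"r_partial": r, "p": p, "controls": ctrl}
        try:
            part = drv.variation_partitioning(paired, config.y)
            partition = {"total_adj_r2": part.total_adj_r2,
                         "independent": part.independent, "joint": part.joint,
                         "independent_relative": part.independent_relative,
                         "joint_relative": part.joint_relative,
                         "has_negative_fractions": part.has_negative_fractions}
        except Exception as exc:
            partition = {"error": str(exc)}
        robust = drv.robustness_fits(paired, response="ratio",
                                     stratum="productivity_class")

        stage = "sensitivity"
        sens = stratified_removal_test(
            paired, "climate_zone", x=config.x, y=config.y,
            removal_frac=config.removal_frac, n_reps=config.n_reps,
            seed=seed_sens)
        sens_out = {str(k): {kk: vv for kk, vv in dataclasses.asdict(v).items()
                             if kk != "slopes"}
                    for k, v in sens.items()}
    except Exception as exc:
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc

    bundle = {
        "config_hash": config.config_hash(), "seed": config.seed,
        "n_input": len(accepted) + len(rejects),
        "n_rejected_schema": len(rejects),
        "cue_table": cue_table,
        "paired": paired,
        "threshold": threshold,
        "zone_fits": zone_fits, "productivity_fits": prod_fits,
        "drivers": {"importance": driver_out,
                    "per_variable": pv,
                    "partial_correlations": pcors,
                    "variation_partitioning": partition,
                    "robustness": robust},
        "sensitivity": sens_out,
    }
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        cue_table.to_csv(out / "cue_table.csv", index=False)
        paired.to_csv(out / "paired.csv", index=False)
        write_json(threshold, out / "threshold.json")
        write_json({"importance": driver_out, "partial_correlations": pcors,
                    "variation_partitioning": partition},
                   out / "drivers.json")
        write_json(sens_out, out / "sensitivity.json")
        zone_fits.to_csv(out / "zone_fits.csv", index=False)
        prod_fits.to_csv(out / "productivity_fits.csv", index=False)
    return bundle


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def write_json(obj, path) -> None:
    """JSON dump tolerant of numpy scalar/array values."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder, default=str)
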