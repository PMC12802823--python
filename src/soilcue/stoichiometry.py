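"""Ecoenzymatic-stoichiometry model of microbial carbon use efficiency.

Microbial carbon use efficiency (CUE) is the fraction of carbon taken up
that is allocated to growth rather than respired.  The stoichiometric
estimator (CUE_ST) infers CUE from the balance between the elemental
composition of soil resources, the composition of microbial biomass, and
the allocation of extracellular enzyme activity (EEA) toward C-, N- and
P-acquisition:

    EEA_C:N = BG / (NAG + LAP)        EEA_C:P = BG / AP
    S_C:N   = (B_C:N / L_C:N) / EEA_C:N
    S_C:P   = (B_C:P / L_C:P) / EEA_C:P
    CUE_ST  = CUE_max * sqrt( (S_C:N * S_C:P)
                              / ((K_C:N + S_C:N) * (K_C:P + S_C:P)) )

where B are molar microbial-biomass ratios (MBC:MBN, MBC:MBP), L are molar
resource ratios (SOC:TN, SOC:TP), K are half-saturation constants
(default 0.5) and CUE_max is the thermodynamic ceiling (default 0.6).
The geometric mean of the two Michaelis-Menten saturation terms keeps
CUE_ST bounded in (0, CUE_max) for any positive scalars.

Enzyme abbreviations: BG = beta-1,4-glucosidase (C acquisition),
NAG = beta-1,4-N-acetylglucosaminidase and LAP = L-leucine aminopeptidase
(N acquisition), AP = acid/alkaline phosphatase (P acquisition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, InvalidRecordError

__all__ = [
    "CueParameters",
    "StoichiometricScalars",
    "CLIMATE_ZONES",
    "compute_molar_ratios",
    "compute_scalars",
    "estimate_cue_st",
    "invert_scalar",
    "cue_pipeline",
]

CLIMATE_ZONES = ("tropical", "temperate", "arid", "cold")


@dataclass(frozen=True)
class CueParameters:
    """Parameters of the stoichiometric CUE model.

    cue_max : thermodynamic maximum CUE (fraction, default 0.6)
    k_cn, k_cp : half-saturation constants for the C:N and C:P
        saturation terms (unitless, default 0.5)
    atomic_mass_* : g mol^-1, used to convert mass ratios to molar ratios
    """

    cue_max: float = 0.6
    k_cn: float = 0.5
    k_cp: float = 0.5
    atomic_mass_c: float = 12.011
    atomic_mass_n: float = 14.007
    atomic_mass_p: float = 30.974

    def __post_init__(self):
        if not (0 < self.cue_max <= 1):
            raise ValueError(f"cue_max must be in (0, 1], got {self.cue_max}")
        if self.k_cn <= 0 or self.k_cp <= 0:
            raise ValueError("half-saturation constants must be positive")


@dataclass(frozen=True)
class StoichiometricScalars:
    """Intermediate quantities of the stoichiometric model (all unitless)."""

    eea_cn: float
    eea_cp: float
    b_cn: float
    b_cp: float
    l_cn: float
    l_cp: float
    s_cn: float
    s_cp: float

    def __post_init__(self):
        for name in ("eea_cn", "eea_cp", "b_cn", "b_cp", "l_cn", "l_cp", "s_cn", "s_cp"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise InvalidRecordError(name, f"scalar {name} must be positive and finite, got {v}")


def _require_positive(value, field: str) -> float:
    if value is None:
        raise InvalidRecordError(field, f"missing value for {field}")
    v = float(value)
    if not math.isfinite(v) or v <= 0:
        raise InvalidRecordError(field, f"{field} must be strictly positive, got {value}")
    return v


def compute_molar_ratios(sample, params: CueParameters = CueParameters(), *,
                         molar_inputs: bool = False):
    """Molar resource and biomass C:N and C:P ratios from a sample record.

    `sample` is any mapping with keys soc, tn, tp (g kg^-1) and
    mbc, mbn, mbp (mg kg^-1).  Ratios are unit-free as long as the pools of
    one ratio share units, so only within-element consistency matters.
    With ``molar_inputs=True`` the pools are taken as moles already and the
    atomic-mass conversion is skipped.

    Returns ``(l_cn, l_cp, b_cn, b_cp)``.
    """
    soc = _require_positive(sample["soc"], "soc")
    tn = _require_positive(sample["tn"], "tn")
    tp = _require_positive(sample["tp"], "tp")
    mbc = _require_positive(sample["mbc"], "mbc")
    mbn = _require_positive(sample["mbn"], "mbn")
    mbp = _require_positive(sample["mbp"], "mbp")
    if molar_inputs:
        mc = mn = mp = 1.0
    else:
        mc, mn, mp = params.atomic_mass_c, params.atomic_mass_n, params.atomic_mass_p
    l_cn = (soc / mc) / (tn / mn)
    l_cp = (soc / mc) / (tp / mp)
    b_cn = (mbc / mc) / (mbn / mn)
    b_cp = (mbc / mc) / (mbp / mp)
    return l_cn, l_cp, b_cn, b_cp


def compute_scalars(sample, params: CueParameters = CueParameters(), *,
                    molar_inputs: bool = False,
                    allow_missing_lap: bool = False) -> StoichiometricScalars:
    """All stoichiometric scalars for one sample record.

    ``allow_missing_lap`` treats an absent/NaN LAP activity as zero
    (some studies assay only NAG); by default such rows are invalid.
    """
    l_cn, l_cp, b_cn, b_cp = compute_molar_ratios(sample, params, molar_inputs=molar_inputs)
    bg = _require_positive(sample["bg"], "bg")
    lap_raw = sample.get("lap") if hasattr(sample, "get") else sample["lap"]
    if lap_raw is None or (isinstance(lap_raw, float) and math.isnan(lap_raw)):
        if not allow_missing_lap:
            raise InvalidRecordError("lap", "lap is missing (set allow_missing_lap to treat as 0)")
        lap = 0.0
    else:
        lap = float(lap_raw)
        if lap < 0 or not math.isfinite(lap):
            raise InvalidRecordError("lap", f"lap must be >= 0, got {lap_raw}")
    nag = sample["nag"]
    if nag is None or not math.isfinite(float(nag)) or float(nag) < 0:
        raise InvalidRecordError("nag", f"nag must be >= 0, got {nag}")
    nag = float(nag)
    if nag + lap <= 0:
        raise InvalidRecordError("nag", "nag + lap must be positive")
    ap = _require_positive(sample["ap"], "ap")

    eea_cn = bg / (nag + lap)
    eea_cp = bg / ap
    s_cn = (b_cn / l_cn) / eea_cn
    s_cp = (b_cp / l_cp) / eea_cp
    return StoichiometricScalars(eea_cn=eea_cn, eea_cp=eea_cp,
                                 b_cn=b_cn, b_cp=b_cp, l_cn=l_cn, l_cp=l_cp,
                                 s_cn=s_cn, s_cp=s_cp)


def estimate_cue_st(scalars, params: CueParameters = CueParameters()):
    """CUE_ST from the saturation scalars.

    Accepts a :class:`StoichiometricScalars` or any object/mapping with
    ``s_cn`` and ``s_cp``; also works on numpy arrays of scalars.
    The estimate is the geometric mean of two Michaelis-Menten terms scaled
    by CUE_max, hence strictly inside (0, cue_max) for positive scalars and
    equal to cue_max/2 exactly at S = K on both axes.
    """
    if isinstance(scalars, StoichiometricScalars):
        s_cn, s_cp = scalars.s_cn, scalars.s_cp
    elif isinstance(scalars, tuple):
        s_cn, s_cp = scalars
    else:
        s_cn, s_cp = scalars["s_cn"], scalars["s_cp"]
    s_cn = np.asarray(s_cn, dtype=float)
    s_cp = np.asarray(s_cp, dtype=float)
    if np.any(~np.isfinite(s_cn)) or np.any(~np.isfinite(s_cp)) \
            or np.any(s_cn <= 0) or np.any(s_cp <= 0):
        raise InvalidRecordError("s_cn/s_cp", "saturation scalars must be positive and finite")
    ratio = (s_cn * s_cp) / ((params.k_cn + s_cn) * (params.k_cp + s_cp))
    out = params.cue_max * np.sqrt(ratio)
    return float(out) if out.ndim == 0 else out


def invert_scalar(cue_target: float, params: CueParameters = CueParameters()) -> float:
    """Solve the symmetric case s_cn = s_cp = s for a target CUE.

    With equal half-saturation constants k and s_cn = s_cp = s the model
    reduces to cue = cue_max * s / (k + s), because
    sqrt(s^2 / (k + s)^2) = s / (k + s).  Inverting gives
    s = k * q / (1 - q) with q = cue / cue_max.
    Requires k_cn == k_cp and 0 < cue_target < cue_max.
    """
    if params.k_cn != params.k_cp:
        raise ValueError("closed-form inversion requires k_cn == k_cp")
    if not (0 < cue_target < params.cue_max):
        raise InvalidRecordError(
            "cue_target", f"cue_target must be in (0, cue_max={params.cue_max}), got {cue_target}")
    q = cue_target / params.cue_max
    return params.k_cn * q / (1.0 - q)


#: Output columns of :func:`cue_pipeline`, in order.
PIPELINE_COLUMNS = ["site_id", "cue_st", "s_cn", "s_cp", "eea_cn", "eea_cp", "reject_reason"]


def cue_pipeline(samples: pd.DataFrame, params: CueParameters = CueParameters(), *,
                 molar_inputs: bool = False,
                 allow_missing_lap: bool = False) -> pd.DataFrame:
    """Compute CUE_ST for every row of a sample table.

    Returns one output row per input row; rows that fail validation get a
    NaN ``cue_st`` and a ``reject_reason`` naming the offending field, so
    no row is silently dropped (accepted + rejected == input).
    """
    if samples is None or len(samples) == 0:
        raise EmptyInputError("cue_pipeline received an empty sample table")
    records = []
    for _, row in samples.iterrows():
        site = row.get("site_id", None)
        try:
            sc = compute_scalars(row, params, molar_inputs=molar_inputs,
                                 allow_missing_lap=allow_missing_lap)
            cue = estimate_cue_st(sc, params)
            records.append((site, cue, sc.s_cn, sc.s_cp, sc.eea_cn, sc.eea_cp, ""))
        except InvalidRecordError as exc:
            records.append((site, np.nan, np.nan, np.nan, np.nan, np.nan, exc.field))
    return pd.DataFrame.from_records(records, columns=PIPELINE_COLUMNS)
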