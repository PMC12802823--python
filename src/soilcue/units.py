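"""Heterotrophic-respiration unit conversions.

Soil heterotrophic respiration (R_h) is reported either per ground area
(g C m^-2 yr^-1) or per soil mass (g C kg^-1 yr^-1).  The two are linked
through the mass of the soil column under 1 m^2 down to sampling depth h:
bulk density in g cm^-3 equals t m^-3, so that column holds bd * h * 1000 kg.
Daily fluxes are annualised with a flat 365-day year.
"""

from __future__ import annotations

import numpy as np

from .exceptions import ConversionError

__all__ = ["area_to_mass", "mass_to_area", "daily_to_annual", "annual_to_daily",
           "threshold_ratio", "DEFAULT_DEPTH_M", "DAYS_PER_YEAR"]

#: Default sampling depth in metres (mean reported depth is close to 0.1 m).
DEFAULT_DEPTH_M = 0.1
DAYS_PER_YEAR = 365.0

# kg of soil under 1 m^2 per (g cm^-3 of bulk density x m of depth)
_KG_PER_M2 = 1000.0


def _check_rate(rh, name="rh"):
    rh = np.asarray(rh, dtype=float)
    if np.any(rh < 0):
        raise ConversionError(f"{name} must be non-negative")
    return rh


def area_to_mass(rh_area, bd, h: float = DEFAULT_DEPTH_M):
    """Convert R_h from g C m^-2 yr^-1 to g C kg^-1 yr^-1.

    ``bd`` is bulk density in g cm^-3 and ``h`` the soil depth in metres;
    the divisor bd*h*1000 is the soil mass (kg) under one square metre.
    """
    rh_area = _check_rate(rh_area, "rh_area")
    bd = np.asarray(bd, dtype=float)
    if np.any(bd <= 0) or h <= 0:
        raise ConversionError("bulk density and depth must be positive")
    out = rh_area / (bd * h * _KG_PER_M2)
    return float(out) if out.ndim == 0 else out


def mass_to_area(rh_mass, bd, h: float = DEFAULT_DEPTH_M):
    """Inverse of :func:`area_to_mass` (g C kg^-1 yr^-1 -> g C m^-2 yr^-1)."""
    rh_mass = _check_rate(rh_mass, "rh_mass")
    bd = np.asarray(bd, dtype=float)
    if np.any(bd <= 0) or h <= 0:
        raise ConversionError("bulk density and depth must be positive")
    out = rh_mass * bd * h * _KG_PER_M2
    return float(out) if out.ndim == 0 else out


def daily_to_annual(rh_daily):
    """g C m^-2 day^-1 -> g C m^-2 yr^-1 (x 365, leap years ignored)."""
    out = _check_rate(rh_daily, "rh_daily") * DAYS_PER_YEAR
    return float(out) if out.ndim == 0 else out


def annual_to_daily(rh_annual):
    """g C m^-2 yr^-1 -> g C m^-2 day^-1 (/ 365)."""
    out = _check_rate(rh_annual, "rh_annual") / DAYS_PER_YEAR
    return float(out) if out.ndim == 0 else out


def threshold_ratio(annual_equivalent: float, annual_threshold: float) -> float:
    """Ratio of an annualised daily threshold to an annual threshold.

    Used to compare a growing-season daily R_h threshold (annualised by
    x365) against a whole-year annual R_h threshold; a ratio well above 1
    reflects that daily fluxes are typically measured in the growing season
    while annual values integrate the full year.
    """
    if annual_threshold <= 0:
        raise ConversionError("annual_threshold must be positive")
    return float(annual_equivalent) / float(annual_threshold)
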