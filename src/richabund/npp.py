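"""Climatological net primary productivity from the Miami model.

The Miami model estimates annual net primary productivity (NPP, grams of
dry matter per m² per year) from long-term mean annual temperature ``T``
(°C) and annual precipitation ``P`` (mm/yr) as the Liebig minimum of a
temperature-limited and a precipitation-limited component, each saturating
at 3000 gDM/m²/yr::

    NPP_T = 3000 / (1 + exp(1.315 - 0.119 * T))
    NPP_P = 3000 * (1 - exp(-0.000664 * P))
    NPP   = min(NPP_T, NPP_P)

Used here as the region-level productivity index for the cross-region
analysis of causal direction; regions may alternatively supply an NPP
column directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MiamiConstants",
    "NppValue",
    "npp_temperature",
    "npp_precipitation",
    "npp",
    "npp_table",
]


@dataclass(frozen=True)
class MiamiConstants:
    """Coefficients of the Miami model; perturb for sensitivity runs."""

    saturation: float = 3000.0  # gDM/m²/yr
    t_intercept: float = 1.315
    t_slope: float = 0.119  # per °C
    p_rate: float = 0.000664  # per mm/yr


DEFAULT_CONSTANTS = MiamiConstants()


@dataclass(frozen=True)
class NppValue:
    """Temperature- and precipitation-limited components and their minimum."""

    npp_t: float
    npp_p: float
    npp: float


def _check_finite(x: float, name: str) -> float:
    x = float(x)
    if not np.isfinite(x):
        raise ValueError(f"{name} must be finite, got {x!r}")
    return x


def npp_temperature(t: float, constants: MiamiConstants = DEFAULT_CONSTANTS) -> float:
    """Temperature-limited NPP component (gDM/m²/yr), strictly increasing in ``t``."""
    t = _check_finite(t, "temperature")
    return constants.saturation / (1.0 + np.exp(constants.t_intercept - constants.t_slope * t))


def npp_precipitation(p: float, constants: MiamiConstants = DEFAULT_CONSTANTS) -> float:
    """Precipitation-limited NPP component (gDM/m²/yr); 0 at p=0, saturating."""
    p = _check_finite(p, "precipitation")
    if p < 0:
        raise ValueError(f"precipitation must be >= 0, got {p}")
    return constants.saturation * (1.0 - np.exp(-constants.p_rate * p))


def npp(t: float, p: float, constants: MiamiConstants = DEFAULT_CONSTANTS) -> NppValue:
    """Miami-model NPP: the minimum of the two limiting components."""
    npp_t = npp_temperature(t, constants)
    npp_p = npp_precipitation(p, constants)
    return NppValue(npp_t=npp_t, npp_p=npp_p, npp=min(npp_t, npp_p))


def npp_table(
    climate: pd.DataFrame, constants: MiamiConstants = DEFAULT_CONSTANTS
) -> pd.DataFrame:
    """Append npp_t, npp_p, npp columns to a table with temperature_c and
    precipitation_mm columns."""
    missing = {"temperature_c", "precipitation_mm"} - set(climate.columns)
    if missing:
        raise ValueError(f"climate table missing columns: {sorted(missing)}")
    t = climate["temperature_c"].to_numpy(dtype=float)
    p = climate["precipitation_mm"].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("non-finite temperature values")
    if np.any(p < 0) or not np.all(np.isfinite(p)):
        raise ValueError("precipitation values must be finite and >= 0")
    out = climate.copy()
    out["npp_t"] = constants.saturation / (1.0 + np.exp(constants.t_intercept - constants.t_slope * t))
    out["npp_p"] = constants.saturation * (1.0 - np.exp(-constants.p_rate * p))
    out["npp"] = np.minimum(out["npp_t"], out["npp_p"])
    return out
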