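"""Gas-transfer velocity and areal air–water CO₂ flux.

F = kₜ · K₀ · (pCO₂ʷ − pCO₂ᵃ)                  (positive = efflux to air)
kₜ = k₆₀₀ · (Sc/600)^(−1/2)
k₆₀₀ = a + b·U₁₀^c                              (coefficients are config)

Units contract: kₜ in cm h⁻¹ (×0.24 → m d⁻¹), K₀ in mol L⁻¹ atm⁻¹
(numerically equal to mmol m⁻³ µatm⁻¹), ΔpCO₂ in µatm, F in
mmol m⁻² d⁻¹.

The shipped k₆₀₀ parameterizations:

``lake``              Cole & Caraco (1998), SF₆ in a low-wind lake:
                      k₆₀₀ = 2.07 + 0.215·U₁₀^1.7 — the default.
``small_water_body``  Crusius & Wanninkhof (2003) linear low-wind fit,
                      k₆₀₀ = 0.72·U₁₀ — a sheltered/small-system
                      alternative lying below the lake curve.
``ocean``             Wanninkhof (1992) quadratic; the long-term
                      (averaged-wind) coefficient k = 0.39·U₁₀² at Sc 660
                      is the published choice for time-ensemble-averaged
                      wind inputs; rescaled to Sc 600: k₆₀₀ = 0.409·U₁₀².
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "K600_PARAMETERIZATIONS",
    "TransferVelocity",
    "DailyFluxRecord",
    "wind_to_10m",
    "spatial_wind_ensemble",
    "schmidt_number",
    "k600",
    "kt_from_k600",
    "areal_flux",
    "compare_parameterizations",
]

#: k600 = a + b * u10**c, cm h-1 with u10 in m s-1.  Configuration data.
K600_PARAMETERIZATIONS: dict[str, dict[str, float]] = {
    "lake": {"a": 2.07, "b": 0.215, "c": 1.7},
    "small_water_body": {"a": 0.0, "b": 0.72, "c": 1.0},
    "ocean": {"a": 0.0, "b": 0.39 * math.sqrt(660.0 / 600.0), "c": 2.0},
}

DEFAULT_PARAMETERIZATION = "lake"

#: Neutral-stability 10-m drag coefficient used for wind-height adjustment.
DRAG_COEFFICIENT = 1.3e-3
VON_KARMAN = 0.40

# Schmidt number polynomials for CO2 (Wanninkhof 1992), fresh and marine
# endmembers; Sc(20 degC, S=0) = 600 within a fraction of a percent.
SCHMIDT_FRESH = (1911.1, -118.11, 3.4527, -0.041320)
SCHMIDT_SEA35 = (2073.1, -125.62, 3.6276, -0.043219)

_CM_PER_H_TO_M_PER_D = 0.24


@dataclass(frozen=True)
class TransferVelocity:
    k600_cm_h: float
    kt_cm_h: float
    schmidt: float
    parameterization_id: str


@dataclass(frozen=True)
class DailyFluxRecord:
    site_id: str
    date: object
    kt_cm_h: float
    k0_mol_l_atm: float
    pco2_water_uatm: float
    pco2_atm_uatm: float
    flux_mmol_m2_d: float


def wind_to_10m(u_z, sensor_height_m: float,
                drag_coefficient: float = DRAG_COEFFICIENT):
    """Adjust wind measured at height z to 10 m, neutral log profile.

    u(z) = u10·(1 + √C_d/κ · ln(z/10)); a single fixed drag coefficient,
    no stability iteration (daily-mean winds do not support one).
    """
    if sensor_height_m <= 0 or sensor_height_m > 30:
        raise ValueError("sensor_height_m must be in (0, 30]")
    u_z = np.asarray(u_z, dtype=float)
    if np.any(u_z < 0):
        raise ValueError("wind speed must be >= 0")
    factor = 1.0 + math.sqrt(drag_coefficient) / VON_KARMAN * math.log(sensor_height_m / 10.0)
    out = u_z / factor
    return float(out) if out.ndim == 0 else out


def spatial_wind_ensemble(station_series: list[pd.Series]) -> pd.Series:
    """Per-day arithmetic mean over stations.

    Each input series is one station's daily mean wind indexed by date.
    Days missing at a station are ignored for that day; a day with no
    station at all propagates as NaN (never zero-filled).
    """
    if len(station_series) == 0:
        raise ValueError("at least one station series required")
    frame = pd.concat(station_series, axis=1)
    return frame.mean(axis=1, skipna=True)


def _sc_poly(coeffs, t):
    a, b, c, d = coeffs
    return a + b * t + c * t**2 + d * t**3


def schmidt_number(temp_c, salinity=0.0):
    """Schmidt number of CO₂ at in-situ temperature and salinity.

    Cubic polynomials in T for the S=0 and S=35 endmembers with linear
    interpolation in salinity between (and extrapolation above) them.
    """
    t = np.asarray(temp_c, dtype=float)
    if np.any(t < 0) or np.any(t > 40):
        raise ValueError("temp_c outside [0, 40]")
    s = np.asarray(salinity, dtype=float)
    fresh = _sc_poly(SCHMIDT_FRESH, t)
    sea = _sc_poly(SCHMIDT_SEA35, t)
    sc = fresh + (sea - fresh) * s / 35.0
    return float(sc) if np.ndim(sc) == 0 else sc


def k600(u10, parameterization_id: str = DEFAULT_PARAMETERIZATION,
         parameterizations: dict | None = None):
    """Wind-based gas-transfer velocity normalized to Sc = 600, cm h⁻¹."""
    table = parameterizations if parameterizations is not None else K600_PARAMETERIZATIONS
    if parameterization_id not in table:
        raise KeyError(
            f"unknown parameterization {parameterization_id!r}; "
            f"valid ids: {sorted(table)}")
    u10 = np.asarray(u10, dtype=float)
    if np.any(u10 < 0):
        raise ValueError("u10 must be >= 0")
    p = table[parameterization_id]
    out = p["a"] + p["b"] * u10 ** p["c"]
    return float(out) if out.ndim == 0 else out


def kt_from_k600(k600_cm_h, schmidt):
    """In-situ transfer velocity: kₜ = k₆₀₀·(Sc/600)^(−1/2), exactly."""
    k = np.asarray(k600_cm_h, dtype=float)
    sc = np.asarray(schmidt, dtype=float)
    if np.any(k <= 0) or np.any(sc <= 0):
        raise ValueError("k600 and Sc must be positive")
    out = k * (sc / 600.0) ** -0.5
    return float(out) if out.ndim == 0 else out


def transfer_velocity(u10, temp_c, salinity=0.0,
                      parameterization_id: str = DEFAULT_PARAMETERIZATION) -> TransferVelocity:
    """Convenience: k₆₀₀, Sc and kₜ for one daily wind/temperature pair."""
    sc = schmidt_number(temp_c, salinity)
    k6 = k600(u10, parameterization_id)
    return TransferVelocity(k600_cm_h=k6, kt_cm_h=kt_from_k600(k6, sc),
                            schmidt=sc, parameterization_id=parameterization_id)


def areal_flux(kt_cm_h, k0_mol_l_atm, pco2_water_uatm, pco2_atm_uatm):
    """Areal CO₂ flux, mmol m⁻² d⁻¹, positive = efflux to the atmosphere.

    F = kₜ[cm h⁻¹]·0.24 [→ m d⁻¹] · K₀[mol L⁻¹ atm⁻¹ ≡ mmol m⁻³ µatm⁻¹]
        · (pCO₂ʷ − pCO₂ᵃ)[µatm]
    """
    kt = np.asarray(kt_cm_h, dtype=float)
    k0 = np.asarray(k0_mol_l_atm, dtype=float)
    if np.any(kt <= 0) or np.any(k0 <= 0):
        raise ValueError("kt and K0 must be positive")
    dp = np.asarray(pco2_water_uatm, dtype=float) - np.asarray(pco2_atm_uatm, dtype=float)
    out = kt * _CM_PER_H_TO_M_PER_D * k0 * dp
    return float(out) if out.ndim == 0 else out


def compare_parameterizations(daily_inputs: pd.DataFrame,
                              ids=("lake", "small_water_body", "ocean"),
                              reference_id: str = "lake") -> pd.DataFrame:
    """Annual flux per k₆₀₀ parameterization and % difference vs the default.

    ``daily_inputs`` needs columns u10_m_s, schmidt, k0_mol_l_atm,
    pco2_water_uatm, pco2_atm_uatm (one row per wet day).  Returns one row
    per id with annual_flux_mol_m2_y and pct_diff_vs_reference.
    """
    ids = list(ids)
    if reference_id not in ids:
        ids = [reference_id] + ids
    annual = {}
    for pid in ids:
        kt = kt_from_k600(k600(daily_inputs["u10_m_s"].to_numpy(), pid),
                          daily_inputs["schmidt"].to_numpy())
        flux = areal_flux(kt, daily_inputs["k0_mol_l_atm"].to_numpy(),
                          daily_inputs["pco2_water_uatm"].to_numpy(),
                          daily_inputs["pco2_atm_uatm"].to_numpy())
        annual[pid] = np.nansum(flux) / 1000.0   # mol m-2 y-1
    ref = annual[reference_id]
    rows = [
        {"parameterization_id": pid,
         "annual_flux_mol_m2_y": annual[pid],
         "pct_diff_vs_reference": 0.0 if pid == reference_id
         else 100.0 * (annual[pid] - ref) / abs(ref)}
        for pid in ids
    ]
    return pd.DataFrame(rows)
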