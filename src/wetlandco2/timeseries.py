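"""Monthly site samples → daily flux series → annual areal fluxes.

Daily values of water temperature, salinity, alkalinity, pH and nutrients
are linear interpolations of the ~monthly samples; water-side pCO₂ is
recomputed each day from the interpolated pH–A_T pair.  Periods when a
site was dry (water too shallow to sample) are hydroperiod gaps, not
missing-at-random data: interpolation never bridges a declared dry
interval and no flux is counted inside one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sstats

from . import carbonate, gas_exchange

__all__ = [
    "SiteDailySeries",
    "SiteAnnualSummary",
    "interpolate_daily",
    "daily_fluxes",
    "annual_areal_flux",
    "summary_stats",
]

log = logging.getLogger(__name__)

_INTERP_VARS = ("temp_c", "salinity", "ph_nbs", "alk_umol_l",
                "po4_umol_l", "sioh4_umol_l")


@dataclass
class SiteDailySeries:
    """Contiguous daily calendar of interpolated conditions for one site.

    ``data`` is indexed by day and carries the interpolated variables,
    the recomputed ``pco2_water_uatm`` and a boolean ``wet_flag``; dry
    days hold NaN.
    """

    site_id: str
    data: pd.DataFrame


@dataclass
class SiteAnnualSummary:
    site_id: str
    annual_flux_mol_m2_y: float
    n_wet_days: int
    daily_stats: dict = field(default_factory=dict)


def _in_dry_interval(day, dry_intervals) -> bool:
    return any(start <= day <= end for start, end in dry_intervals)


def interpolate_daily(samples: pd.DataFrame, site_id: str | None = None,
                      dry_intervals=()) -> SiteDailySeries:
    """Piecewise-linear daily interpolation of monthly samples for one site.

    ``samples`` needs a ``date`` column plus the measured variables
    (temp_c, salinity, ph_nbs, alk_umol_l, po4_umol_l, sioh4_umol_l),
    strictly increasing in date.  ``dry_intervals`` is a sequence of
    (start, end) dates (inclusive) during which the site held no water:
    consecutive samples separated by a dry interval form distinct wet
    segments and days between them carry no value.  No extrapolation
    beyond the first/last sample.
    """
    if site_id is None:
        site_id = str(samples["site_id"].iloc[0]) if "site_id" in samples else "site"
    samples = samples.sort_values("date").reset_index(drop=True)
    dates = pd.to_datetime(samples["date"]).dt.normalize()
    if dates.duplicated().any() or not dates.is_monotonic_increasing:
        raise ValueError("sample dates must be strictly increasing")
    dry_intervals = [(pd.Timestamp(a).normalize(), pd.Timestamp(b).normalize())
                     for a, b in dry_intervals]

    if len(samples) == 0:
        raise ValueError("no samples")
    if len(samples) == 1:
        warnings.warn(f"{site_id}: single sample; degenerate one-day series",
                      stacklevel=2)

    # Split into wet segments wherever a dry interval falls between
    # consecutive sampling dates.
    segments: list[list[int]] = [[0]]
    for i in range(1, len(samples)):
        gap_broken = any(dates[i - 1] < start and end < dates[i] or
                         (dates[i - 1] < start <= dates[i]) or
                         (dates[i - 1] <= end < dates[i])
                         for start, end in dry_intervals)
        if gap_broken:
            segments.append([i])
        else:
            segments[-1].append(i)

    grid = pd.date_range(dates.iloc[0], dates.iloc[-1], freq="D")
    out = pd.DataFrame(index=grid, columns=list(_INTERP_VARS), dtype=float)
    wet = pd.Series(False, index=grid)

    for seg in segments:
        seg_dates = dates.iloc[seg]
        seg_grid = pd.date_range(seg_dates.iloc[0], seg_dates.iloc[-1], freq="D")
        x = seg_dates.astype("int64").to_numpy(dtype=float)
        xg = seg_grid.astype("int64").to_numpy(dtype=float)
        for var in _INTERP_VARS:
            y = samples[var].to_numpy(dtype=float)[seg]
            out.loc[seg_grid, var] = np.interp(xg, x, y)
        wet.loc[seg_grid] = True

    # Any day explicitly inside a declared dry interval is never wet.
    for start, end in dry_intervals:
        inside = (grid >= start) & (grid <= end)
        wet[inside] = False
        out.loc[inside, :] = np.nan

    pco2 = np.full(len(grid), np.nan)
    m = wet.to_numpy()
    if m.any():
        pco2[m] = carbonate.pco2_from_ta_ph(
            out["temp_c"].to_numpy()[m], out["salinity"].to_numpy()[m],
            out["alk_umol_l"].to_numpy()[m], out["ph_nbs"].to_numpy()[m],
            out["po4_umol_l"].to_numpy()[m], out["sioh4_umol_l"].to_numpy()[m])
    out["pco2_water_uatm"] = pco2
    out["wet_flag"] = wet
    return SiteDailySeries(site_id=site_id, data=out)


def daily_fluxes(site_series: SiteDailySeries, meteo_days: pd.DataFrame,
                 parameterization_id: str = gas_exchange.DEFAULT_PARAMETERIZATION,
                 ) -> pd.DataFrame:
    """Per-wet-day kₜ, K₀, ΔpCO₂ and areal flux for one site.

    ``meteo_days`` is indexed by day with columns ``u10_m_s`` and
    ``pco2_atm_uatm`` (daily ensemble values).  Wet days missing from the
    meteorology are dropped with a logged count, never zero-filled.
    """
    d = site_series.data
    wet = d.index[d["wet_flag"]]
    have = wet.intersection(meteo_days.index)
    n_gap = len(wet) - len(have)
    if n_gap:
        log.warning("%s: %d wet day(s) without meteorology dropped",
                    site_series.site_id, n_gap)
    if len(have) == 0:
        return pd.DataFrame(columns=[
            "site_id", "date", "kt_cm_h", "k0_mol_l_atm",
            "pco2_water_uatm", "pco2_atm_uatm", "flux_mmol_m2_d"])

    t = d.loc[have, "temp_c"].to_numpy()
    s = d.loc[have, "salinity"].to_numpy()
    consts = carbonate.equilibrium_constants(t, s)
    sc = gas_exchange.schmidt_number(t, s)
    u10 = meteo_days.loc[have, "u10_m_s"].to_numpy()
    kt = gas_exchange.kt_from_k600(
        gas_exchange.k600(u10, parameterization_id), sc)
    pw = d.loc[have, "pco2_water_uatm"].to_numpy()
    pa = meteo_days.loc[have, "pco2_atm_uatm"].to_numpy()
    flux = gas_exchange.areal_flux(kt, consts.k0, pw, pa)

    return pd.DataFrame({
        "site_id": site_series.site_id,
        "date": have,
        "kt_cm_h": kt,
        "k0_mol_l_atm": consts.k0,
        "pco2_water_uatm": pw,
        "pco2_atm_uatm": pa,
        "flux_mmol_m2_d": flux,
    })


def annual_areal_flux(daily_records: pd.DataFrame) -> float:
    """Annual areal flux, mol m⁻² y⁻¹ — the sum of daily mmol values /1000.

    Dry days are simply absent from the records and contribute zero.
    """
    if len(daily_records) == 0:
        return 0.0
    if daily_records["date"].nunique() > 366:
        raise ValueError("records span more than one year")
    return float(np.nansum(daily_records["flux_mmol_m2_d"].to_numpy()) / 1000.0)


def summary_stats(values) -> dict:
    """Descriptive statistics of a daily series.

    Moment-based skewness and raw (Pearson) kurtosis — a normal sample
    reads ≈3, not 0.  IQR uses linear interpolation between order
    statistics.  With n<2 (or a constant vector, for the shape moments)
    the undefined entries are NaN and ``flagged`` says why.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    out = {"n": n, "flagged": None}
    if n == 0:
        out["flagged"] = "empty"
        out.update({k: np.nan for k in (
            "mean", "median", "sd", "min", "max", "range", "iqr",
            "skewness", "kurtosis")})
        return out
    out.update({
        "mean": float(np.mean(v)),
        "median": float(np.median(v)),
        "min": float(np.min(v)),
        "max": float(np.max(v)),
        "range": float(np.max(v) - np.min(v)),
        "iqr": float(np.percentile(v, 75) - np.percentile(v, 25)),
    })
    if n < 2:
        out["flagged"] = "n<2: sd/skewness/kurtosis undefined"
        out.update({"sd": np.nan, "skewness": np.nan, "kurtosis": np.nan})
        return out
    out["sd"] = float(np.std(v, ddof=1))
    if np.all(v == v[0]):
        out["flagged"] = "constant: skewness/kurtosis undefined"
        out.update({"skewness": np.nan, "kurtosis": np.nan})
    else:
        out["skewness"] = float(_sstats.skew(v, bias=True))
        out["kurtosis"] = float(_sstats.kurtosis(v, fisher=False, bias=True))
    return out
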