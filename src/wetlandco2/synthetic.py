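"""Seeded synthetic inputs with Mediterranean-wetland structure.

The generator emulates one hydrological year (March→February) of a
mosaic of water bodies: managed estuarine ponds (mesohaline, mostly
under-saturated in CO₂, one with abrupt salinity swings), semi-permanent
oligohaline ponds and a stream (winter–spring super-saturation of
10³–10⁴ µatm, autumn drawdown to tens of µatm), and temporal marshes
(wet only in winter–spring, strongly super-saturated).  Meteorology is
hourly multi-station wind (daily means 1.3–7.2 m s⁻¹, median ≈2.5),
atmospheric pCO₂ (369–398 µatm) and air temperature.  Scenes are toy NIR
rasters in which a seasonally flooding disc per region sits below the
0.2 water threshold, with per-scene gain/offset distortions recoverable
by PIF normalization.

Every generated table is reproducible from one integer seed; a ground
truth object accompanies each output so the full pipeline can be tested
against closed-form expectations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from shapely.geometry import Point, box

from . import carbonate, gas_exchange
from .upscaling import ReflectanceScene

__all__ = [
    "SiteArchetype",
    "SyntheticConfig",
    "SiteTruth",
    "MeteoTruth",
    "RegionTruth",
    "ScenesBundle",
    "generate_sites",
    "generate_meteorology",
    "generate_scenes",
    "expected_annual_flux",
    "expected_regional_transport",
    "DEFAULT_SITES",
    "DEFAULT_REGIONS",
]

# ----------------------------------------------------------------------
# Stated world
# ----------------------------------------------------------------------

#: Measurement-noise levels: Gaussian for pH/temperature, lognormal
#: (multiplicative) for concentrations.  Magnitudes are analytical error
#: only — the monthly spot sample *defines* the site state in this
#: method (spatial patchiness is not modelled, matching the up-scaling
#: premise that one sample represents the water body).
NOISE = {
    "ph_sd": 0.01,            # pH units (electrode accuracy)
    "ta_rel_sd": 0.003,       # CRM-anchored titration
    "pco2_rel_sd": 0.02,      # implied-pCO2 consistency of the pH-TA pair
    "temp_sd": 0.2,           # degC
    "sal_rel_sd": 0.02,
    "nutrient_rel_sd": 0.3,   # nutrient analytics (weak influence on pCO2)
    "station_wind_rel_sd": 0.06,
    "hourly_wind_rel_sd": 0.10,
    "pco2_atm_sd": 1.0,       # uatm, hourly
    "pif_sd": 0.003,          # reflectance, PIF stability
}


@dataclass(frozen=True)
class SiteArchetype:
    """Per-site seasonal regime: salinity, alkalinity, pCO₂ curve, hydroperiod."""

    site_id: str
    kind: str
    region_id: str
    salinity_base: float
    ta_umol_l: float
    pco2_points: tuple          # (day-of-study, uatm) control points
    wet_intervals: tuple        # (first_day, last_day) inclusive, day-of-study
    po4_median: float
    si_median: float
    salinity_swings: bool = False


# pCO2 seasonal shapes (log-linear between control points; features kept
# >~2 months wide so ~monthly sampling resolves them).  Day 0 = 1 March.
_PCO2_SEMIPERM = ((0, 150), (60, 1800), (90, 5200), (110, 6500), (130, 5200),
                  (190, 900), (230, 40), (300, 1800), (364, 4000))
_PCO2_TEMPORAL = ((0, 2500), (60, 1000), (120, 5000),
                  (270, 3500), (310, 7000), (364, 5000))
_PCO2_SINK = ((0, 250), (60, 380), (120, 170), (180, 95),
              (240, 130), (300, 220), (364, 280))
_PCO2_MILD_SOURCE = ((0, 600), (60, 1100), (120, 520), (180, 640),
                     (240, 560), (300, 800), (364, 1200))


def _scale(points, f):
    return tuple((d, v * f) for d, v in points)


DEFAULT_SITES: tuple[SiteArchetype, ...] = (
    # Managed estuarine ponds (mesohaline; mostly sinks, one mild source).
    SiteArchetype("VP1", "managed_pond", "managed_ponds", 3.1, 3000,
                  _PCO2_MILD_SOURCE, ((0, 364),), 0.4, 46),
    SiteArchetype("VP2", "managed_pond", "managed_ponds", 2.0, 3700,
                  _PCO2_SINK, ((0, 364),), 0.6, 23),
    SiteArchetype("VP3", "managed_pond", "managed_ponds", 25.0, 3400,
                  _scale(_PCO2_SINK, 0.7), ((0, 364),), 0.4, 33,
                  salinity_swings=True),
    SiteArchetype("VP4", "managed_pond", "managed_ponds", 5.5, 3200,
                  _scale(_PCO2_MILD_SOURCE, 0.8), ((0, 330),), 0.5, 81),
    # Semi-permanent oligohaline ponds (extreme seasonal cycle; one dries
    # out for a month in early autumn).
    SiteArchetype("SP1", "semi_permanent", "marsh", 0.8, 4400,
                  _PCO2_SEMIPERM, ((0, 175), (205, 364)), 6.0, 148),
    SiteArchetype("SP2", "semi_permanent", "marsh", 1.0, 4700,
                  _scale(_PCO2_SEMIPERM, 0.6), ((0, 364),), 1.4, 80),
    # Temporal marshes: wet only in spring carry-over and winter re-flood.
    SiteArchetype("TW1", "temporal_marsh", "marsh", 0.5, 3100,
                  _PCO2_TEMPORAL, ((0, 120), (270, 364)), 12.8, 218),
    SiteArchetype("TW2", "temporal_marsh", "marsh", 1.0, 4600,
                  _scale(_PCO2_TEMPORAL, 0.7), ((0, 120), (270, 364)), 1.6, 160),
    SiteArchetype("TW3", "temporal_marsh", "marsh", 1.2, 5900,
                  _scale(_PCO2_TEMPORAL, 0.5), ((0, 120), (270, 364)), 1.4, 168),
    # Dune pond and stream.
    SiteArchetype("DP1", "semi_permanent", "dune_ponds", 0.5, 2600,
                  _scale(_PCO2_SEMIPERM, 0.8), ((0, 364),), 1.2, 242),
    SiteArchetype("ST1", "stream", "stream", 0.2, 1800,
                  _scale(_PCO2_SEMIPERM, 0.5), ((0, 364),), 2.0, 370),
)

#: Regions: bounding box (map metres) for the flood disc, member sites and
#: the seasonal water-area control points (km², log-linear in between).
DEFAULT_REGIONS: dict[str, dict] = {
    "marsh": {
        "site_ids": ["SP1", "SP2", "TW1", "TW2", "TW3"],
        "bbox": (0.0, 0.0, 3000.0, 5400.0),
        "area_points": ((0, 3.0), (60, 1.5), (120, 0.3), (180, 0.06),
                        (240, 0.4), (300, 5.0), (335, 8.0), (364, 7.0)),
    },
    "managed_ponds": {
        "site_ids": ["VP1", "VP2", "VP3", "VP4"],
        "bbox": (3000.0, 2700.0, 4500.0, 5400.0),
        "area_points": ((0, 1.2), (120, 1.0), (240, 0.9), (364, 1.4)),
    },
    "dune_ponds": {
        "site_ids": ["DP1"],
        "bbox": (3000.0, 0.0, 4500.0, 2700.0),
        "area_points": ((0, 0.35), (120, 0.12), (210, 0.05), (300, 0.5),
                        (364, 0.45)),
    },
    "stream": {
        "site_ids": ["ST1"],
        "bbox": (4500.0, 0.0, 5400.0, 5400.0),
        "area_points": ((0, 0.25), (150, 0.08), (240, 0.05), (320, 0.40),
                        (364, 0.35)),
    },
}


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    start: _date = _date(2010, 3, 1)
    n_days: int = 365
    sites: tuple = DEFAULT_SITES
    regions: dict = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    n_stations: int = 3
    sensor_height_m: float = 2.0
    sample_interval_d: int = 30
    first_sample_day: int = 10
    scene_interval_d: int = 30
    first_scene_day: int = 2
    pixel_size_m: float = 30.0
    grid_shape: tuple = (180, 180)

    def days(self) -> pd.DatetimeIndex:
        return pd.date_range(pd.Timestamp(self.start), periods=self.n_days,
                             freq="D")

    def sample_days(self) -> np.ndarray:
        d = np.arange(self.first_sample_day, self.n_days,
                      self.sample_interval_d)
        if d[-1] < self.n_days - 1:
            d = np.append(d, self.n_days - 1)
        return d

    def scene_days(self) -> np.ndarray:
        d = np.arange(self.first_scene_day, self.n_days, self.scene_interval_d)
        if d[-1] < self.n_days - 3:
            d = np.append(d, self.n_days - 1)
        return d


# ----------------------------------------------------------------------
# Truth containers
# ----------------------------------------------------------------------

@dataclass
class SiteTruth:
    """Noiseless daily curves plus the effective flux window for one site."""

    site_id: str
    days: pd.DatetimeIndex
    temp_c: np.ndarray
    salinity: np.ndarray
    ta_umol_l: np.ndarray
    pco2_uatm: np.ndarray
    po4_umol_l: float
    si_umol_l: float
    wet_mask: np.ndarray            # hydroperiod
    flux_window_mask: np.ndarray    # wet AND inside per-segment sample span
    dry_intervals: list
    sample_days: np.ndarray


@dataclass
class MeteoTruth:
    days: pd.DatetimeIndex
    u10_m_s: np.ndarray             # regional daily truth (post-clip)
    pco2_atm_uatm: np.ndarray
    air_temp_c: np.ndarray


@dataclass
class RegionTruth:
    region_id: str
    site_ids: list
    polygon: object
    area_km2_daily: pd.Series       # analytic truth, full year


@dataclass
class ScenesBundle:
    scenes: list
    reference_index: int
    pif_pixels: list
    regions: dict                   # region_id -> RegionTruth
    distortions: list               # (gain, offset) per scene


# ----------------------------------------------------------------------
# Helper curves
# ----------------------------------------------------------------------

def _doy(days: pd.DatetimeIndex) -> np.ndarray:
    return days.dayofyear.to_numpy(dtype=float)


def _water_temp(days) -> np.ndarray:
    """Seasonal water temperature, 13.6–31.7 °C, peaking early August."""
    doy = _doy(days)
    return 22.65 - 9.05 * np.cos(2.0 * np.pi * (doy - 213.0) / 365.0)


def _air_temp(days) -> np.ndarray:
    doy = _doy(days)
    return 17.55 - 8.25 * np.cos(2.0 * np.pi * (doy - 213.0) / 365.0)


def _pco2_atm(days) -> np.ndarray:
    """Seasonal atmospheric pCO₂: min ~369 in February, max ~398 in August."""
    doy = _doy(days)
    return 383.5 - 14.5 * np.cos(2.0 * np.pi * (doy - 213.0) / 365.0)


def _log_interp(day_idx: np.ndarray, points) -> np.ndarray:
    d, v = np.asarray(points, dtype=float).T
    return 10.0 ** np.interp(day_idx, d, np.log10(v))


def _site_salinity(arch: SiteArchetype, day_idx: np.ndarray) -> np.ndarray:
    if arch.salinity_swings:
        # Managed estuarine pumping: fresh in winter, hypersaline in
        # summer, with steep ~40-unit ramps (a near-full swing between
        # consecutive monthly samples).  Plateaus dominate, so monthly
        # sampling still tracks the curve.
        return np.clip(
            2.0 + 22.0 * (np.tanh((day_idx - 70.0) / 22.0)
                          - np.tanh((day_idx - 255.0) / 22.0)), 0.0, 50.0)
    return np.clip(arch.salinity_base
                   * (1.0 + 0.3 * np.sin(2.0 * np.pi * (day_idx - 90) / 365.0)),
                   0.05, 50.0)


def _site_ta(arch: SiteArchetype, day_idx: np.ndarray) -> np.ndarray:
    return arch.ta_umol_l * (1.0 + 0.15 * np.sin(2.0 * np.pi * (day_idx - 60)
                                                 / 365.0))


def _wet_mask(arch: SiteArchetype, n_days: int) -> np.ndarray:
    mask = np.zeros(n_days, dtype=bool)
    for a, b in arch.wet_intervals:
        mask[a:b + 1] = True
    return mask


def _dry_intervals(arch: SiteArchetype, days: pd.DatetimeIndex) -> list:
    """Date pairs of the gaps between wet intervals (inclusive)."""
    out = []
    ivs = sorted(arch.wet_intervals)
    for (a0, b0), (a1, b1) in zip(ivs, ivs[1:]):
        out.append((days[b0 + 1], days[a1 - 1]))
    return out


def _solve_ph(temp_c, salinity, ta_umol_l, target_pco2, po4, si) -> float:
    """NBS pH at which the (pH, A_T) pair reproduces a target pCO₂."""
    def f(ph):
        v = carbonate.pco2_from_ta_ph(temp_c, salinity, ta_umol_l, ph, po4, si)
        # carbonate alkalinity <= 0 (possible only at the alkaline end of
        # the bracket) means vanishing CO2*
        return (v if np.isfinite(v) else 0.0) - target_pco2
    return brentq(f, 5.5, 11.0, xtol=1e-8)


# ----------------------------------------------------------------------
# Generators
# ----------------------------------------------------------------------

def _streams(seed: int):
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    return (np.random.default_rng(kids[0]),   # sites
            np.random.default_rng(kids[1]),   # meteorology
            np.random.default_rng(kids[2]))   # scenes


def generate_sites(config: SyntheticConfig):
    """Monthly water-sample tables plus per-site ground truth.

    Returns ``(samples, truths)``: a DataFrame of WaterSample rows
    (nutrients deliberately missing for one site-month and for every
    site's final month, mirroring field-campaign practice) and a dict of
    :class:`SiteTruth`.
    """
    rng, _, _ = _streams(config.seed)
    days = config.days()
    day_idx = np.arange(config.n_days, dtype=float)
    schedule = config.sample_days()

    rows = []
    truths: dict[str, SiteTruth] = {}
    for arch in config.sites:
        temp = _water_temp(days)
        sal = _site_salinity(arch, day_idx)
        ta = _site_ta(arch, day_idx)
        pco2 = _log_interp(day_idx, arch.pco2_points)
        wet = _wet_mask(arch, config.n_days)

        site_sample_days = np.array([d for d in schedule if wet[d]])
        flux_window = np.zeros(config.n_days, dtype=bool)
        for a, b in arch.wet_intervals:
            seg = site_sample_days[(site_sample_days >= a)
                                   & (site_sample_days <= b)]
            if len(seg) >= 2:
                flux_window[seg[0]:seg[-1] + 1] = True
        flux_window &= wet

        truths[arch.site_id] = SiteTruth(
            site_id=arch.site_id, days=days, temp_c=temp, salinity=sal,
            ta_umol_l=ta, pco2_uatm=pco2, po4_umol_l=arch.po4_median,
            si_umol_l=arch.si_median, wet_mask=wet,
            flux_window_mask=flux_window,
            dry_intervals=_dry_intervals(arch, days),
            sample_days=site_sample_days)

        for d in site_sample_days:
            t_obs = temp[d] + rng.normal(0.0, NOISE["temp_sd"])
            s_obs = float(np.clip(sal[d] * rng.lognormal(0.0, NOISE["sal_rel_sd"]),
                                  0.0, 50.0))
            ta_obs = ta[d] * rng.lognormal(0.0, NOISE["ta_rel_sd"])
            pco2_target = pco2[d] * rng.lognormal(0.0, NOISE["pco2_rel_sd"])
            po4 = arch.po4_median * rng.lognormal(0.0, NOISE["nutrient_rel_sd"])
            si = arch.si_median * rng.lognormal(0.0, NOISE["nutrient_rel_sd"])
            ph = _solve_ph(t_obs, s_obs, ta_obs, pco2_target, po4, si)
            ph += rng.normal(0.0, NOISE["ph_sd"])

            # Field-campaign nutrient gaps: one site-month and the final
            # month region-wide.
            missing = (arch.site_id == "VP3" and d == schedule[2]) or \
                      (d == schedule[-2] if len(schedule) >= 2 else False)
            rows.append({
                "site_id": arch.site_id, "date": days[d].date(),
                "temp_c": round(float(t_obs), 2),
                "salinity": round(s_obs, 2),
                "ph_nbs": round(float(ph), 3),
                "alk_umol_l": round(float(ta_obs), 1),
                "po4_umol_l": None if missing else round(float(po4), 2),
                "sioh4_umol_l": None if missing else round(float(si), 2),
            })
    samples = pd.DataFrame(rows)
    return samples, truths


def generate_meteorology(config: SyntheticConfig):
    """Hourly multi-station records plus the regional daily truth.

    Station winds share a regional AR(1) daily signal (median ≈2.5,
    clipped to 1.3–7.2 m s⁻¹ with semi-annual spring/autumn maxima) with
    per-station multiplicative noise; hourly values carry a diurnal
    cycle renormalized so daily station means are exact.  Winds are
    reported at ``sensor_height_m`` following the neutral log profile.
    """
    _, rng, _ = _streams(config.seed)
    days = config.days()
    doy = _doy(days)

    # Regional daily wind: lognormal AR(1) around a semi-annual cycle.
    phi, sd = 0.70, 0.30
    z = np.empty(config.n_days)
    z[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, sd * np.sqrt(1.0 - phi**2), size=config.n_days)
    for i in range(1, config.n_days):
        z[i] = phi * z[i - 1] + eps[i]
    # Storm-driven winter-spring winds (the same Atlantic fronts that
    # flood the marsh), calm sea-breeze summer-autumn.
    seasonal = 1.0 + 0.35 * np.cos(2.0 * np.pi * (doy - 60.0) / 365.0)
    u10 = np.clip(2.5 * seasonal * np.exp(z - sd**2 / 2.0), 1.3, 7.2)

    pa_day = _pco2_atm(days)
    ta_day = _air_temp(days)

    height_factor = 1.0 + (np.sqrt(gas_exchange.DRAG_COEFFICIENT)
                           / gas_exchange.VON_KARMAN
                           * np.log(config.sensor_height_m / 10.0))
    hours = np.arange(24)
    diurnal_wind = 1.0 + 0.25 * np.sin(2.0 * np.pi * (hours - 9.0) / 24.0)
    diurnal_temp = 4.0 * np.sin(2.0 * np.pi * (hours - 9.0) / 24.0)

    recs = []
    for st in range(config.n_stations):
        station = f"ST{st + 1:02d}"
        st_noise = rng.lognormal(0.0, NOISE["station_wind_rel_sd"],
                                 size=config.n_days)
        u_station = np.clip(u10 * st_noise, 1.3, 7.2)
        for i, day in enumerate(days):
            hf = diurnal_wind * rng.lognormal(0.0, NOISE["hourly_wind_rel_sd"],
                                              size=24)
            hf = hf / hf.mean()                     # exact daily station mean
            winds = u_station[i] * height_factor * hf
            pa_noise = rng.normal(0.0, NOISE["pco2_atm_sd"], size=24)
            pa = pa_day[i] + (pa_noise - pa_noise.mean())
            temps = ta_day[i] + diurnal_temp + rng.normal(0.0, 0.5, size=24)
            ts = day + pd.to_timedelta(hours, unit="h")
            recs.append(pd.DataFrame({
                "timestamp": ts, "station_id": station,
                "wind_m_s": winds,
                "sensor_height_m": config.sensor_height_m,
                "air_temp_c": temps, "pco2_atm_uatm": pa,
            }))
    hourly = pd.concat(recs, ignore_index=True)
    truth = MeteoTruth(days=days, u10_m_s=u10, pco2_atm_uatm=pa_day,
                       air_temp_c=ta_day)
    return hourly, truth


def daily_meteo_from_hourly(hourly: pd.DataFrame) -> pd.DataFrame:
    """Station-hourly records → regional daily ensemble (u10, pCO₂ᵃᵗᵐ).

    Per station: daily time-average, wind adjusted to 10 m; then the
    spatial ensemble mean across stations.
    """
    df = hourly.copy()
    df["day"] = pd.to_datetime(df["timestamp"]).dt.normalize()
    wind_series = []
    for (_, z), grp in df.groupby(["station_id", "sensor_height_m"]):
        daily = grp.groupby("day")["wind_m_s"].mean()
        wind_series.append(pd.Series(
            gas_exchange.wind_to_10m(daily.to_numpy(), float(z)),
            index=daily.index))
    u10 = gas_exchange.spatial_wind_ensemble(wind_series)
    pa = df.groupby("day")["pco2_atm_uatm"].mean()
    return pd.DataFrame({"u10_m_s": u10, "pco2_atm_uatm": pa})


def generate_scenes(config: SyntheticConfig) -> ScenesBundle:
    """Toy NIR reflectance series, region polygons and PIF pixels.

    Each region floods as a disc whose area follows its seasonal truth
    curve.  Water pixels sit at 0.05–0.15 reflectance, land at
    0.28–0.55; every non-reference scene gets a gain/offset distortion
    (gain 0.85–1.30, offset ±0.04) that pushes pixels across the 0.2
    threshold until PIF normalization undoes it.
    """
    _, _, rng = _streams(config.seed)
    days = config.days()
    day_idx = np.arange(config.n_days, dtype=float)
    nrow, ncol = config.grid_shape
    px = config.pixel_size_m

    regions: dict[str, RegionTruth] = {}
    for rid, spec in config.regions.items():
        x0, y0, x1, y1 = spec["bbox"]
        d, v = np.asarray(spec["area_points"], dtype=float).T
        area = np.interp(day_idx, d, v)   # piecewise-linear flood curve
        regions[rid] = RegionTruth(
            region_id=rid, site_ids=list(spec["site_ids"]),
            polygon=box(x0, y0, x1, y1),
            area_km2_daily=pd.Series(area, index=days))

    # Pixel-center coordinates (origin at top-left, y down the rows).
    xs = (np.arange(ncol) + 0.5) * px
    ys = (nrow - np.arange(nrow) - 0.5) * px
    xx, yy = np.meshgrid(xs, ys)
    origin = (0.0, nrow * px)

    n_pif = 15
    pif_rows = rng.integers(0, nrow, size=n_pif)
    pif_cols = rng.integers(0, ncol, size=n_pif)
    pif_vals = np.linspace(0.05, 0.75, n_pif)

    scene_days = config.scene_days()
    scenes, distortions = [], []
    for k, d in enumerate(scene_days):
        nir = 0.28 + 0.27 * rng.random((nrow, ncol))     # land
        for rid, rt in regions.items():
            cx, cy = rt.polygon.centroid.x, rt.polygon.centroid.y
            a_m2 = rt.area_km2_daily.iloc[d] * 1e6
            r = np.sqrt(a_m2 / np.pi)
            disc = (xx - cx) ** 2 + (yy - cy) ** 2 < r**2
            nir[disc] = 0.05 + 0.10 * rng.random(int(disc.sum()))
        nir[pif_rows, pif_cols] = np.clip(
            pif_vals + rng.normal(0.0, NOISE["pif_sd"], size=n_pif), 0.0, 1.0)
        if k == 0:
            gain, offset = 1.0, 0.0
        else:
            gain = rng.uniform(0.85, 1.30)
            offset = rng.uniform(-0.04, 0.04)
        distorted = np.clip(gain * nir + offset, 0.0, 1.0)
        scenes.append(ReflectanceScene(date=days[d], nir=distorted,
                                       pixel_size_m=px, origin=origin))
        distortions.append((gain, offset))

    return ScenesBundle(scenes=scenes, reference_index=0,
                        pif_pixels=list(zip(pif_rows.tolist(), pif_cols.tolist())),
                        regions=regions, distortions=distortions)


# ----------------------------------------------------------------------
# Closed-form expectations (generator ground truth)
#
# Two flavours.  The *truth-curve* expectation integrates the continuous
# noiseless daily curves: it is the estimand.  The *pipeline* expectation
# is the noise-free value of the estimator itself — the truth sampled at
# the known monthly schedule, pH solved exactly, then interpolated and
# integrated exactly as the analysis does.  Monthly sampling of a
# strongly peaked seasonal cycle carries an inherent discretization bias
# (chords in log space undercut a log-concave maximum), so the two
# flavours differ by up to several percent for the extreme archetypes;
# recovery tests compare the pipeline against its own expectation, and
# the discretization bias is asserted separately as a bounded property.
# ----------------------------------------------------------------------

def _truth_daily_flux(truth: SiteTruth, meteo: MeteoTruth,
                      parameterization_id: str = "lake") -> np.ndarray:
    """Noiseless daily flux (mmol m⁻² d⁻¹); NaN outside the flux window."""
    m = truth.flux_window_mask
    out = np.full(truth.days.size, np.nan)
    if not m.any():
        return out
    consts = carbonate.equilibrium_constants(truth.temp_c[m], truth.salinity[m])
    sc = gas_exchange.schmidt_number(truth.temp_c[m], truth.salinity[m])
    kt = gas_exchange.kt_from_k600(
        gas_exchange.k600(meteo.u10_m_s[m], parameterization_id), sc)
    out[m] = gas_exchange.areal_flux(kt, consts.k0, truth.pco2_uatm[m],
                                     meteo.pco2_atm_uatm[m])
    return out


def expected_annual_flux(truth: SiteTruth, meteo: MeteoTruth,
                         parameterization_id: str = "lake") -> float:
    """Generator expectation of annual areal flux, mol m⁻² y⁻¹."""
    return float(np.nansum(_truth_daily_flux(truth, meteo,
                                             parameterization_id)) / 1000.0)


def expected_regional_transport(region: RegionTruth, truths: dict,
                                meteo: MeteoTruth,
                                parameterization_id: str = "lake",
                                day_window: pd.DatetimeIndex | None = None,
                                ) -> float:
    """Truth-curve expectation of annual regional transport, Gg C y⁻¹.

    Mean of member-site truth fluxes over wet sites × analytic water
    area, optionally restricted to ``day_window`` (e.g. the scene-covered
    calendar used by the pipeline).
    """
    fluxes = np.vstack([_truth_daily_flux(truths[s], meteo, parameterization_id)
                        for s in region.site_ids])
    with np.errstate(invalid="ignore"):
        mean_flux = np.nanmean(fluxes, axis=0)
    mean_flux = np.nan_to_num(mean_flux, nan=0.0)
    area_m2 = region.area_km2_daily.to_numpy() * 1e6
    grams = mean_flux * area_m2 * 12.011e-3
    series = pd.Series(grams, index=region.area_km2_daily.index)
    if day_window is not None:
        series = series.loc[series.index.intersection(day_window)]
    return float(series.sum() / 1e9)


# -- pipeline (estimator) expectations ---------------------------------

def noiseless_samples(truth: SiteTruth) -> pd.DataFrame:
    """The monthly sample table the campaign would record with zero noise."""
    rows = []
    for d in truth.sample_days:
        ph = _solve_ph(truth.temp_c[d], truth.salinity[d], truth.ta_umol_l[d],
                       truth.pco2_uatm[d], truth.po4_umol_l, truth.si_umol_l)
        rows.append({
            "site_id": truth.site_id, "date": truth.days[d],
            "temp_c": truth.temp_c[d], "salinity": truth.salinity[d],
            "ph_nbs": ph, "alk_umol_l": truth.ta_umol_l[d],
            "po4_umol_l": truth.po4_umol_l, "sioh4_umol_l": truth.si_umol_l})
    return pd.DataFrame(rows)


def expected_pipeline_daily_fluxes(truth: SiteTruth, meteo: MeteoTruth,
                                   parameterization_id: str = "lake",
                                   ) -> pd.DataFrame:
    """Noise-free expectation of the per-site daily flux records."""
    from . import timeseries
    meteo_days = pd.DataFrame({"u10_m_s": meteo.u10_m_s,
                               "pco2_atm_uatm": meteo.pco2_atm_uatm},
                              index=meteo.days)
    series = timeseries.interpolate_daily(
        noiseless_samples(truth), site_id=truth.site_id,
        dry_intervals=truth.dry_intervals)
    return timeseries.daily_fluxes(series, meteo_days, parameterization_id)


def expected_pipeline_annual_flux(truth: SiteTruth, meteo: MeteoTruth,
                                  parameterization_id: str = "lake") -> float:
    """Noise-free expectation of the annual areal flux estimator."""
    from . import timeseries
    return timeseries.annual_areal_flux(
        expected_pipeline_daily_fluxes(truth, meteo, parameterization_id))


def expected_pixel_area_km2(config: SyntheticConfig, region: RegionTruth,
                            day: int) -> float:
    """Deterministic pixel-counted disc area for a region on one day."""
    nrow, ncol = config.grid_shape
    px = config.pixel_size_m
    xs = (np.arange(ncol) + 0.5) * px
    ys = (nrow - np.arange(nrow) - 0.5) * px
    xx, yy = np.meshgrid(xs, ys)
    cx, cy = region.polygon.centroid.x, region.polygon.centroid.y
    a_m2 = region.area_km2_daily.iloc[day] * 1e6
    r = np.sqrt(a_m2 / np.pi)
    disc = (xx - cx) ** 2 + (yy - cy) ** 2 < r**2
    return float(disc.sum()) * px**2 / 1e6


def expected_pipeline_regional_transport(config: SyntheticConfig,
                                         region: RegionTruth, truths: dict,
                                         meteo: MeteoTruth,
                                         parameterization_id: str = "lake",
                                         ) -> float:
    """Noise-free expectation of the regional annual-transport estimator.

    Uses pixel-counted (undistorted) scene areas linearly interpolated to
    days, and the noise-free site flux records, combined exactly as the
    pipeline combines them.
    """
    from . import upscaling
    scene_days = config.scene_days()
    areas = [expected_pixel_area_km2(config, region, d) for d in scene_days]
    daily_area = upscaling.interpolate_area_daily(
        [truths[next(iter(truths))].days[d] for d in scene_days], areas)
    recs = pd.concat([expected_pipeline_daily_fluxes(truths[s], meteo,
                                                     parameterization_id)
                      for s in region.site_ids], ignore_index=True)
    fluxes = recs.pivot_table(index="date", columns="site_id",
                              values="flux_mmol_m2_d", aggfunc="first")
    grams = upscaling.regional_daily_transport(fluxes, daily_area)
    return upscaling.annual_transport(grams)


def regional_gross_transport_scale(region: RegionTruth, truths: dict,
                                   meteo: MeteoTruth,
                                   parameterization_id: str = "lake") -> float:
    """Gross transport magnitude of a region, Gg C y⁻¹.

    Σ_days mean(|site flux|)·area — the natural error scale for the
    signed annual transport of a region whose member sites nearly cancel
    (relative error against the signed total is ill-posed there).
    """
    fluxes = np.vstack([np.abs(_truth_daily_flux(truths[s], meteo,
                                                 parameterization_id))
                        for s in region.site_ids])
    with np.errstate(invalid="ignore"):
        mean_abs = np.nanmean(fluxes, axis=0)
    mean_abs = np.nan_to_num(mean_abs, nan=0.0)
    grams = mean_abs * region.area_km2_daily.to_numpy() * 1e6 * 12.011e-3
    return float(grams.sum() / 1e9)
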