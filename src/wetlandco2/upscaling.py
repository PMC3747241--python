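"""Remote-sensing water extent and regional carbon-transport up-scaling.

Scenes are single-band NIR surface-reflectance grids (north-up, square
pixels).  The multi-date series is radiometrically normalized against a
reference scene using a symmetric line fit on pseudo-invariant features
(PIFs), water is classified by a simple NIR threshold (< 0.2), region
water area is pixel counting inside a polygon, and regional transport is
mean site flux × water area, summed over the year.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import shape as _shape, mapping as _mapping

__all__ = [
    "ReflectanceScene",
    "RegionSeries",
    "normalize_scene",
    "classify_water",
    "region_water_area",
    "interpolate_area_daily",
    "regional_daily_transport",
    "annual_transport",
    "npp_comparison",
    "MOLAR_MASS_C",
]

log = logging.getLogger(__name__)

MOLAR_MASS_C = 12.011          # g mol-1
DEFAULT_NIR_THRESHOLD = 0.2


@dataclass
class ReflectanceScene:
    """NIR surface reflectance on a north-up grid.

    ``origin`` is the map coordinate of the top-left corner of pixel
    (0, 0); pixel centers are at
    x = x0 + (col + 0.5)·px,  y = y0 − (row + 0.5)·px.
    NaN marks nodata.
    """

    date: object
    nir: np.ndarray
    pixel_size_m: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.nir = np.asarray(self.nir, dtype=float)
        if self.pixel_size_m <= 0:
            raise ValueError("pixel_size_m must be positive")
        valid = self.nir[np.isfinite(self.nir)]
        if valid.size and (valid.min() < 0 or valid.max() > 1):
            raise ValueError("reflectance must lie in [0, 1] or be NaN")

    def pixel_centers(self):
        nrow, ncol = self.nir.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.pixel_size_m
        ys = y0 - (np.arange(nrow) + 0.5) * self.pixel_size_m
        return np.meshgrid(xs, ys)


@dataclass
class RegionSeries:
    region_id: str
    site_ids: list[str]
    area_km2_by_day: pd.Series = field(default=None)
    daily_transport_g_c: pd.Series = field(default=None)
    annual_transport_gg_c: float = float("nan")


def normalize_scene(scene: ReflectanceScene, reference: ReflectanceScene,
                    pif_pixels) -> ReflectanceScene:
    """Relative radiometric normalization against a reference scene.

    Fits a symmetric (geometric-mean / reduced-major-axis) line to the
    (scene, reference) reflectance pairs at the PIF pixels —
    slope = sign(cov)·√(var_ref/var_scene), intercept through the means —
    and applies it to the whole scene, clipping to [0, 1].  At least 3
    valid PIF pixels are required.
    """
    rows, cols = np.asarray(pif_pixels).T
    x = scene.nir[rows, cols]
    y = reference.nir[rows, cols]
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        raise ValueError("need >= 3 PIF pixels valid in both scenes")
    x, y = x[ok], y[ok]
    var_x = np.var(x)
    var_y = np.var(y)
    if var_x == 0 or var_y == 0:
        raise ValueError("zero variance in PIF reflectances")
    cov = np.cov(x, y)[0, 1]
    slope = np.sign(cov) * np.sqrt(var_y / var_x)
    intercept = y.mean() - slope * x.mean()
    nir = np.clip(slope * scene.nir + intercept, 0.0, 1.0)
    nir[~np.isfinite(scene.nir)] = np.nan
    return ReflectanceScene(date=scene.date, nir=nir,
                            pixel_size_m=scene.pixel_size_m, origin=scene.origin)


def classify_water(scene: ReflectanceScene,
                   threshold: float = DEFAULT_NIR_THRESHOLD) -> np.ndarray:
    """Binary water mask: water iff NIR < threshold (strict) and not nodata."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    return np.isfinite(scene.nir) & (scene.nir < threshold)


def region_water_area(mask: np.ndarray, region_polygon, pixel_size_m: float,
                      origin: tuple[float, float] = (0.0, 0.0)) -> float:
    """Water area (km²) inside a polygon: pixel-center containment count.

    ``region_polygon`` is a shapely geometry or a GeoJSON-like mapping in
    the same coordinate frame as the mask.
    """
    poly = region_polygon if hasattr(region_polygon, "geom_type") else _shape(region_polygon)
    nrow, ncol = mask.shape
    x0, y0 = origin
    xs = x0 + (np.arange(ncol) + 0.5) * pixel_size_m
    ys = y0 - (np.arange(nrow) + 0.5) * pixel_size_m
    xx, yy = np.meshgrid(xs, ys)
    inside = contains_xy(poly, xx.ravel(), yy.ravel()).reshape(mask.shape)
    if not inside.any():
        warnings.warn("region polygon is disjoint from the raster", stacklevel=2)
        return 0.0
    n_water = int(np.count_nonzero(mask & inside))
    return n_water * pixel_size_m**2 / 1e6


def interpolate_area_daily(scene_dates, areas_km2) -> pd.Series:
    """Daily water-area series: linear interpolation between scene dates.

    Exact at scene dates; a single scene yields a constant one-day series
    with a warning.  (Same contract as the monthly-variable
    interpolation; the areas are already per-region scalars.)
    """
    idx = pd.to_datetime(pd.Index(scene_dates)).normalize()
    areas = np.asarray(areas_km2, dtype=float)
    if len(idx) != len(areas):
        raise ValueError("dates and areas differ in length")
    if len(idx) == 0:
        raise ValueError("no scenes")
    order = np.argsort(idx.asi8)
    idx, areas = idx[order], areas[order]
    if len(idx) == 1:
        warnings.warn("single scene; constant area series", stacklevel=2)
        return pd.Series(areas, index=idx)
    grid = pd.date_range(idx[0], idx[-1], freq="D")
    vals = np.interp(grid.asi8.astype(float), idx.asi8.astype(float), areas)
    return pd.Series(vals, index=grid)


def regional_daily_transport(site_fluxes: pd.DataFrame,
                             area_km2: pd.Series) -> pd.Series:
    """Daily carbon transport of a region, grams C per day.

    ``site_fluxes`` is a day × site table of areal fluxes
    (mmol m⁻² d⁻¹) for the region's member sites, NaN where a site is
    dry; ``area_km2`` the daily water area.  Transport = mean flux over
    wet member sites × area(m²) × 12.011×10⁻³ g mmol⁻¹ (one mmol CO₂
    carries one mmol C).  Days when every member site is dry but water
    area is positive log an inconsistency and count zero.
    """
    days = site_fluxes.index.intersection(area_km2.index)
    mean_flux = site_fluxes.loc[days].mean(axis=1, skipna=True)
    area_m2 = area_km2.loc[days] * 1e6
    all_dry = mean_flux.isna()
    n_bad = int((all_dry & (area_m2 > 0)).sum())
    if n_bad:
        log.warning("%d day(s) with water area but no wet member site; "
                    "transport counted as 0", n_bad)
    grams = mean_flux.fillna(0.0) * area_m2 * (MOLAR_MASS_C * 1e-3)
    return grams


def annual_transport(daily_transport_g_c: pd.Series) -> float:
    """Annual transport, Gg C y⁻¹ = Σ grams / 10⁹ (≤366 daily values)."""
    if len(daily_transport_g_c) > 366:
        raise ValueError("more than one year of daily values")
    return float(np.nansum(np.asarray(daily_transport_g_c, dtype=float)) / 1e9)


def npp_comparison(npp_mol_m2_y: float, region_area_km2: float,
                   total_transport_gg: float) -> dict:
    """Compare regional NPP (areal rate × area) against annual transport.

    Returns ``npp_gg_c_y`` and the ratio NPP/transport; the ratio is NaN
    with a flag when transport is not positive.
    """
    if npp_mol_m2_y <= 0 or region_area_km2 <= 0:
        raise ValueError("npp and area must be positive")
    npp_gg = npp_mol_m2_y * MOLAR_MASS_C * region_area_km2 * 1e6 / 1e9
    out = {"npp_gg_c_y": npp_gg, "ratio": np.nan, "flagged": None}
    if total_transport_gg > 0:
        out["ratio"] = npp_gg / total_transport_gg
    else:
        out["flagged"] = "transport <= 0: ratio undefined"
    return out


def polygon_to_geojson(polygon) -> dict:
    """GeoJSON mapping for a shapely geometry (text-serializable)."""
    return _mapping(polygon)


def scene_to_ascii(scene: ReflectanceScene) -> str:
    """ESRI ASCII grid text for a scene (plain-text raster interchange)."""
    nrow, ncol = scene.nir.shape
    x0, y0 = scene.origin
    header = (f"ncols {ncol}\nnrows {nrow}\n"
              f"xllcorner {x0}\nyllcorner {y0 - nrow * scene.pixel_size_m}\n"
              f"cellsize {scene.pixel_size_m}\nNODATA_value -9999\n")
    body = np.where(np.isfinite(scene.nir), scene.nir, -9999.0)
    lines = "\n".join(" ".join(f"{v:.4f}" for v in row) for row in body)
    return header + lines + "\n"


def scene_from_ascii(text: str, date=None) -> ReflectanceScene:
    """Parse an ESRI ASCII grid produced by :func:`scene_to_ascii`."""
    lines = text.strip().splitlines()
    hdr = {}
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
        k, v = lines[i].split()
        hdr[k.lower()] = float(v)
        i += 1
    arr = np.loadtxt(lines[i:], dtype=float)
    arr = arr.reshape(int(hdr["nrows"]), int(hdr["ncols"]))
    nodata = hdr.get("nodata_value", -9999.0)
    arr = np.where(arr == nodata, np.nan, arr)
    px = hdr["cellsize"]
    origin = (hdr["xllcorner"], hdr["yllcorner"] + int(hdr["nrows"]) * px)
    return ReflectanceScene(date=date, nir=arr, pixel_size_m=px, origin=origin)
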