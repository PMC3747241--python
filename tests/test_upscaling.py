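"""Water classification, PIF normalization, areas and carbon transport."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from wetlandco2 import upscaling as up


def scene(nir, px=30.0, origin=None, date="2010-06-01"):
    nir = np.asarray(nir, dtype=float)
    if origin is None:
        origin = (0.0, nir.shape[0] * px)
    return up.ReflectanceScene(date=pd.Timestamp(date), nir=nir,
                               pixel_size_m=px, origin=origin)


class TestNormalizeScene:
    def _pifs(self, n=5):
        return [(0, i) for i in range(n)]

    def test_identity_when_scene_matches_reference(self):
        nir = np.tile(np.linspace(0.1, 0.5, 5), (3, 1))
        out = up.normalize_scene(scene(nir), scene(nir.copy()), self._pifs())
        assert np.allclose(out.nir, nir, atol=1e-12)

    def test_exact_linear_case_halves_doubled_scene(self):
        ref = np.tile(np.linspace(0.1, 0.4, 5), (3, 1))
        out = up.normalize_scene(scene(2.0 * ref), scene(ref), self._pifs())
        assert np.allclose(out.nir, ref, atol=1e-12)

    def test_slope_is_sqrt_variance_ratio_not_ols(self):
        # 5-point toy set with var_scene = 4*var_ref; the pairing is
        # shuffled so the OLS slope differs from the major-axis slope 0.5
        x = np.array([0.1, 0.3, 0.5, 0.7, 0.9])              # scene PIFs
        y = np.array([0.05, 0.35, 0.15, 0.45, 0.25])         # reference PIFs
        assert np.var(x) == pytest.approx(4.0 * np.var(y))
        sc = np.tile(x, (2, 1))
        rf = np.tile(y, (2, 1))
        out = up.normalize_scene(scene(sc), scene(rf), self._pifs())
        # recover the applied slope from two transformed scene values
        applied = (out.nir[0, 1] - out.nir[0, 0]) / (x[1] - x[0])
        assert abs(applied) == pytest.approx(0.5, rel=1e-9)
        ols = np.cov(x, y, bias=True)[0, 1] / np.var(x)
        assert abs(ols) != pytest.approx(0.5, rel=0.05)

    def test_zero_variance_pifs_rejected(self):
        flat = np.full((2, 5), 0.3)
        ref = np.tile(np.linspace(0.1, 0.4, 5), (2, 1))
        with pytest.raises(ValueError, match="variance"):
            up.normalize_scene(scene(flat), scene(ref), self._pifs())

    def test_too_few_valid_pifs_rejected(self):
        nir = np.full((2, 5), np.nan)
        nir[0, :2] = [0.2, 0.4]
        ref = np.tile(np.linspace(0.1, 0.4, 5), (2, 1))
        with pytest.raises(ValueError, match="PIF"):
            up.normalize_scene(scene(nir), scene(ref), self._pifs())


class TestClassifyWater:
    def test_all_zero_scene_is_all_water(self):
        assert up.classify_water(scene(np.zeros((4, 4)))).all()

    def test_threshold_is_strict_less_than(self):
        nir = np.array([[0.1999, 0.2, 0.2001]])
        mask = up.classify_water(scene(nir))
        assert mask.tolist() == [[True, False, False]]

    def test_nodata_excluded_from_both_classes(self):
        nir = np.array([[0.1, np.nan, 0.5]])
        mask = up.classify_water(scene(nir))
        assert mask.tolist() == [[True, False, False]]

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            up.classify_water(scene(np.zeros((2, 2))), threshold=0.0)


class TestRegionWaterArea:
    def test_hundred_pixels_at_30m(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[:10, :10] = True  # 100 water pixels
        poly = box(0.0, 0.0, 600.0, 600.0)
        got = up.region_water_area(mask, poly, 30.0, origin=(0.0, 600.0))
        assert got == pytest.approx(100 * 900 / 1e6)

    def test_empty_mask_zero(self):
        mask = np.zeros((10, 10), dtype=bool)
        poly = box(0, 0, 300, 300)
        assert up.region_water_area(mask, poly, 30.0, (0.0, 300.0)) == 0.0

    def test_full_raster_full_polygon(self):
        mask = np.ones((100, 100), dtype=bool)
        poly = box(0, 0, 3000, 3000)
        got = up.region_water_area(mask, poly, 30.0, (0.0, 3000.0))
        assert got == pytest.approx(9.0)

    def test_disjoint_polygon_warns_and_returns_zero(self):
        mask = np.ones((5, 5), dtype=bool)
        poly = box(10_000, 10_000, 11_000, 11_000)
        with pytest.warns(UserWarning, match="disjoint"):
            assert up.region_water_area(mask, poly, 30.0, (0.0, 150.0)) == 0.0

    def test_geojson_mapping_accepted(self):
        mask = np.ones((4, 4), dtype=bool)
        gj = up.polygon_to_geojson(box(0, 0, 120, 120))
        got = up.region_water_area(mask, gj, 30.0, (0.0, 120.0))
        assert got == pytest.approx(16 * 900 / 1e6)


class TestInterpolateAreaDaily:
    def test_midpoint(self):
        out = up.interpolate_area_daily(["2010-03-01", "2010-03-31"],
                                        [10.0, 40.0])
        assert out.loc["2010-03-16"] == pytest.approx(25.0)

    def test_exact_at_scene_dates_and_nonnegative(self):
        dates = ["2010-03-01", "2010-04-15", "2010-06-01"]
        areas = [5.0, 0.0, 12.0]
        out = up.interpolate_area_daily(dates, areas)
        for d, a in zip(dates, areas):
            assert out.loc[d] == pytest.approx(a)
        assert (out >= 0).all()

    def test_single_scene_constant_with_warning(self):
        with pytest.warns(UserWarning, match="single scene"):
            out = up.interpolate_area_daily(["2010-03-01"], [7.0])
        assert out.iloc[0] == 7.0


class TestRegionalTransport:
    def _days(self, n=3):
        return pd.date_range("2010-03-01", periods=n, freq="D")

    def test_hand_unit_chain_single_site(self):
        days = self._days(1)
        fluxes = pd.DataFrame({"a": [10.0]}, index=days)
        area = pd.Series([1.0], index=days)
        got = up.regional_daily_transport(fluxes, area)
        # 10 mmol/m2/d * 1e6 m2 = 1e7 mmol = 1e4 mol -> 120.11 kg C/d
        assert got.iloc[0] == pytest.approx(120.11e3, rel=1e-12)

    def test_opposite_sites_cancel(self):
        days = self._days(2)
        fluxes = pd.DataFrame({"a": [10.0, 10.0], "b": [-10.0, -10.0]},
                              index=days)
        got = up.regional_daily_transport(fluxes, pd.Series(2.0, index=days))
        assert np.allclose(got.to_numpy(), 0.0)

    def test_zero_area_zero_transport(self):
        days = self._days(2)
        fluxes = pd.DataFrame({"a": [10.0, 5.0]}, index=days)
        got = up.regional_daily_transport(fluxes, pd.Series(0.0, index=days))
        assert np.allclose(got.to_numpy(), 0.0)

    def test_dry_sites_excluded_from_mean(self):
        days = self._days(1)
        fluxes = pd.DataFrame({"a": [10.0], "b": [np.nan]}, index=days)
        got = up.regional_daily_transport(fluxes, pd.Series(1.0, index=days))
        assert got.iloc[0] == pytest.approx(120.11e3, rel=1e-12)

    def test_all_dry_with_area_counts_zero(self, caplog):
        days = self._days(1)
        fluxes = pd.DataFrame({"a": [np.nan]}, index=days)
        with caplog.at_level("WARNING", logger="wetlandco2.upscaling"):
            got = up.regional_daily_transport(fluxes,
                                              pd.Series(1.0, index=days))
        assert got.iloc[0] == 0.0
        assert "no wet member site" in caplog.text

    def test_linear_in_area_and_flux(self):
        rng = np.random.default_rng(3)
        days = self._days(50)
        fluxes = pd.DataFrame(rng.normal(5, 10, size=(50, 3)),
                              index=days, columns=list("abc"))
        area = pd.Series(rng.uniform(0.5, 4.0, 50), index=days)
        base = up.annual_transport(up.regional_daily_transport(fluxes, area))
        assert up.annual_transport(
            up.regional_daily_transport(fluxes, 2.0 * area)
        ) == pytest.approx(2.0 * base, rel=1e-12)
        assert up.annual_transport(
            up.regional_daily_transport(3.0 * fluxes, area)
        ) == pytest.approx(3.0 * base, rel=1e-12)


class TestAnnualTransportAndNPP:
    def test_year_of_constant_grams(self):
        s = pd.Series(1e5, index=pd.date_range("2010-03-01", periods=365,
                                               freq="D"))
        assert up.annual_transport(s) == pytest.approx(0.0365)

    def test_negative_days_propagate(self):
        s = pd.Series([-1e6] * 10)
        assert up.annual_transport(s) < 0

    def test_more_than_a_year_rejected(self):
        s = pd.Series(1.0, index=range(400))
        with pytest.raises(ValueError):
            up.annual_transport(s)

    def test_npp_upper_estimate_from_areal_rate_and_area(self):
        out = up.npp_comparison(27.0, 231.0, 13.1)
        assert out["npp_gg_c_y"] == pytest.approx(74.9, abs=0.05)

    def test_npp_ratio_flagged_for_nonpositive_transport(self):
        out = up.npp_comparison(27.0, 231.0, -1.0)
        assert np.isnan(out["ratio"]) and out["flagged"]

    def test_npp_linear_in_area(self):
        a = up.npp_comparison(27.0, 231.0, 13.1)["npp_gg_c_y"]
        b = up.npp_comparison(27.0, 462.0, 13.1)["npp_gg_c_y"]
        assert b == pytest.approx(2.0 * a, rel=1e-12)


class TestAsciiRoundTrip:
    def test_scene_survives_text_serialization(self):
        nir = np.array([[0.1, 0.5], [np.nan, 0.9]])
        s = scene(nir, px=22.0, origin=(100.0, 300.0))
        back = up.scene_from_ascii(up.scene_to_ascii(s))
        assert back.pixel_size_m == 22.0
        assert back.origin == (100.0, 300.0)
        assert np.isnan(back.nir[1, 0])
        assert np.allclose(back.nir[np.isfinite(nir)], nir[np.isfinite(nir)],
                           atol=1e-4)
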