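"""Carbonate speciation: constants, alkalinity bookkeeping, oracle checks."""

import math
from datetime import date

import numpy as np
import pytest

from wetlandco2 import carbonate as cb

from _oracle import oracle_pco2


def sample(**kw):
    base = dict(site_id="s", date=date(2010, 6, 1), temp_c=20.0, salinity=1.0,
                ph_nbs=8.0, alk_umol_l=3000.0, po4_umol_l=2.84,
                sioh4_umol_l=141.91)
    base.update(kw)
    return cb.WaterSample(**base)


class TestConstants:
    def test_freshwater_literature_anchors(self):
        """25 °C freshwater: pK1≈6.35, pK2≈10.33, K0≈0.0339 mol/L/atm."""
        c = cb.equilibrium_constants(25.0, 0.0)
        assert -math.log10(c.k1) == pytest.approx(6.35, abs=0.02)
        assert -math.log10(c.k2) == pytest.approx(10.33, abs=0.02)
        assert c.k0 == pytest.approx(0.0339, rel=0.02)

    @pytest.mark.parametrize("salinity", [0.0, 18.0, 35.0])
    def test_k0_decreases_with_temperature(self, salinity):
        t = np.arange(0.5, 35.0, 0.5)
        k0 = np.array([cb.equilibrium_constants(ti, salinity).k0 for ti in t])
        assert np.all(np.diff(k0) < 0)

    def test_k1_exceeds_k2_by_orders(self):
        c = cb.equilibrium_constants(25.0, 35.0)
        assert 2.5 < math.log10(c.k1 / c.k2) < 4.0

    def test_totals_vanish_in_freshwater(self):
        c = cb.equilibrium_constants(20.0, 0.0)
        assert c.total_borate == 0.0 and c.total_sulfate == 0.0

    def test_out_of_envelope_warns_not_fails(self):
        with pytest.warns(UserWarning):
            c = cb.equilibrium_constants(25.0, 45.0)
        assert c.k1 > c.k2 > 0


class TestFillMissingNutrients:
    def test_both_missing_filled_with_dataset_averages(self):
        s = cb.fill_missing_nutrients(sample(po4_umol_l=None, sioh4_umol_l=None))
        assert s.po4_umol_l == 2.84
        assert s.sioh4_umol_l == 141.91
        assert s.nutrient_provenance == "filled"

    def test_complete_sample_unchanged(self):
        s0 = sample()
        assert cb.fill_missing_nutrients(s0) is s0
        assert s0.nutrient_provenance == "measured"

    def test_partial_fill_only_missing_field(self):
        s = cb.fill_missing_nutrients(sample(sioh4_umol_l=None))
        assert s.po4_umol_l == 2.84 and s.sioh4_umol_l == 141.91
        assert s.nutrient_provenance == "partial"


class TestNoncarbonateAlkalinity:
    def test_near_zero_at_neutral_freshwater(self):
        c = cb.equilibrium_constants(25.0, 0.0)
        total, _ = cb.noncarbonate_alkalinity(1e-7, c, 0.0, 0.0)
        assert abs(total) < 0.2  # umol/L, ~[OH]-[H] only

    def test_high_ph_positive_oh_borate_dominated(self):
        c = cb.equilibrium_constants(25.0, 35.0)
        total, comp = cb.noncarbonate_alkalinity(1e-10, c, 1.0, 10.0)
        assert total > 0
        assert comp["water"] + comp["borate"] > 0.9 * total

    def test_decomposition_identity(self):
        c = cb.equilibrium_constants(15.0, 5.0)
        total, comp = cb.noncarbonate_alkalinity(10**-8.2, c, 2.84, 141.91)
        assert total == pytest.approx(sum(comp.values()), rel=1e-12)


class TestSpeciate:
    def test_ph_equal_pk1_gives_equal_co2_and_hco3(self):
        c = cb.equilibrium_constants(20.0, 0.0)
        st = cb.speciate(sample(salinity=0.0, ph_nbs=-math.log10(c.k1),
                                po4_umol_l=0.0, sioh4_umol_l=0.0), c)
        assert st.co2_star_umol_l == pytest.approx(st.hco3_umol_l, rel=1e-9)

    def test_pco2_linear_in_alkalinity_at_fixed_ph(self):
        # with no borate/nutrients the non-carbonate terms are ~[OH]-[H],
        # so doubling A_T doubles carbonate alkalinity and hence pCO2
        a = cb.speciate(sample(salinity=0.0, po4_umol_l=0.0, sioh4_umol_l=0.0,
                               alk_umol_l=2000.0))
        b = cb.speciate(sample(salinity=0.0, po4_umol_l=0.0, sioh4_umol_l=0.0,
                               alk_umol_l=4000.0))
        assert b.pco2_uatm / a.pco2_uatm == pytest.approx(2.0, rel=1e-3)

    def test_dic_is_sum_of_species(self):
        st = cb.speciate(sample())
        assert st.dic_umol_l == pytest.approx(
            st.co2_star_umol_l + st.hco3_umol_l + st.co3_umol_l, rel=1e-12)

    def test_pco2_strictly_decreasing_in_ph(self):
        phs = np.arange(6.0, 9.6, 0.1)
        p = [cb.speciate(sample(ph_nbs=ph)).pco2_uatm for ph in phs]
        assert np.all(np.diff(p) < 0)

    def test_nonpositive_carbonate_alkalinity_flagged_not_nan(self):
        # tiny A_T at very high pH: OH/borate exceed total alkalinity
        st = cb.speciate(sample(salinity=35.0, ph_nbs=10.8, alk_umol_l=50.0))
        assert not st.valid
        assert st.carb_alk_umol_l <= 0
        assert np.isfinite(st.pco2_uatm)
        assert "noncarbonate_alk_umol_l" in st.diagnostics

    def test_requires_filled_nutrients(self):
        with pytest.raises(ValueError, match="nutrients"):
            cb.speciate(sample(po4_umol_l=None))

    @pytest.mark.parametrize("t,s,ph,ta", [
        (t, s, ph, ta)
        for t in (10.0, 20.0, 30.0)
        for s in (0.0, 5.0, 18.0, 35.0)
        for ph in (7.0, 8.0, 9.0)
        for ta in (1800.0, 3000.0, 6000.0)
    ])
    def test_alkalinity_reconstruction_exact(self, t, s, ph, ta):
        """Recomputing A_T from the returned species reproduces the input."""
        c = cb.equilibrium_constants(t, s)
        st = cb.speciate(sample(temp_c=t, salinity=s, ph_nbs=ph,
                                alk_umol_l=ta), c)
        if not st.valid:
            pytest.skip("non-carbonate alkalinity exceeds A_T here")
        h = 10.0 ** -ph
        nc, _ = cb.noncarbonate_alkalinity(h, c, 2.84, 141.91)
        ta_back = st.hco3_umol_l + 2.0 * st.co3_umol_l + nc
        assert abs(ta_back - ta) < 0.01  # umol/L


class TestWaterSampleValidation:
    @pytest.mark.parametrize("kw", [
        {"temp_c": -1.0}, {"temp_c": 50.0}, {"salinity": 55.0},
        {"ph_nbs": 3.0}, {"alk_umol_l": 0.0}, {"po4_umol_l": -1.0},
    ])
    def test_invariant_violations_raise(self, kw):
        with pytest.raises(ValueError):
            sample(**kw)


class TestOracleAgreement:
    def test_single_case_within_5pct(self):
        st = cb.speciate(sample())
        ref = oracle_pco2(20.0, 1.0, 3000.0, 8.0, 2.84, 141.91)
        assert st.pco2_uatm == pytest.approx(ref, rel=0.05)

    def test_vectorized_matches_scalar_route(self):
        t = np.array([10.0, 20.0, 30.0])
        s = np.array([0.0, 5.0, 18.0])
        ta = np.array([1800.0, 3000.0, 6000.0])
        ph = np.array([7.5, 8.0, 8.5])
        vec = cb.pco2_from_ta_ph(t, s, ta, ph)
        for i in range(3):
            st = cb.speciate(sample(temp_c=t[i], salinity=s[i],
                                    alk_umol_l=ta[i], ph_nbs=ph[i]))
            assert vec[i] == pytest.approx(st.pco2_uatm, rel=1e-12)
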