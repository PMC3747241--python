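"""Carbonate-system speciation from the pH–total-alkalinity input pair.

Monthly field samples carry in-situ temperature, practical salinity, pH on
the NBS scale and total alkalinity (A_T, µmol L⁻¹), plus dissolved
phosphate and silicate.  With pH and A_T both known the system is closed
without iteration: non-carbonate alkalinity (borate, water, phosphate,
silicate, bisulfate) is evaluated at the measured [H⁺], subtracted from
A_T to give carbonate alkalinity, and the carbonate species follow from
the dissociation constants.

Conventions
-----------
* All proton arithmetic is on the **NBS scale**: [H⁺] = 10^(−pH_NBS).
  The carbonic-acid constants (Cai & Wang 1998, estuarine, valid at low
  salinity) are published directly on the NBS scale.  Constants published
  on the total or seawater scale (borate, water, phosphate, silicate) are
  converted to NBS with the GEOSECS activity-coefficient factor
  fH(T, S) = 1.2948 − 2.036e−3·T_K + (4.607e−4 − 1.475e−6·T_K)·S².
* Concentration basis is volumetric (µmol L⁻¹) throughout, matching the
  reported field units.  Constants published per kg of solution are used
  as per-litre values; the ≤3 % density difference is far inside the
  tolerance of the downstream flux calculation.
* CO₂ solubility K₀ follows Weiss (1974), volumetric coefficients
  (mol L⁻¹ atm⁻¹), so pCO₂ (µatm) = [CO₂*] (µmol L⁻¹) / K₀.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date as _date

import numpy as np

__all__ = [
    "WaterSample",
    "ConstantSet",
    "CarbonateState",
    "equilibrium_constants",
    "fill_missing_nutrients",
    "noncarbonate_alkalinity",
    "speciate",
    "DEFAULT_PO4_UMOL_L",
    "DEFAULT_SIOH4_UMOL_L",
]

# Data-set average nutrient concentrations used when a sample lacks them.
DEFAULT_PO4_UMOL_L = 2.84
DEFAULT_SIOH4_UMOL_L = 141.91

# Validity envelope of the estuarine carbonic-acid constants; exceeding it
# is warned about, not rejected (the field data span S = 0–50).
_CAI_WANG_T_RANGE = (0.2, 35.0)
_CAI_WANG_S_RANGE = (0.0, 40.0)


@dataclass(frozen=True)
class WaterSample:
    """One monthly in-situ observation at a site."""

    site_id: str
    date: _date
    temp_c: float
    salinity: float
    ph_nbs: float
    alk_umol_l: float
    po4_umol_l: float | None = None
    sioh4_umol_l: float | None = None
    pressure_dbar: float = 0.0
    nutrient_provenance: str = "measured"

    def __post_init__(self) -> None:
        if not 0.0 <= self.temp_c <= 45.0:
            raise ValueError(f"temp_c {self.temp_c} outside [0, 45]")
        if not 0.0 <= self.salinity <= 50.0:
            raise ValueError(f"salinity {self.salinity} outside [0, 50]")
        if not 4.0 <= self.ph_nbs <= 11.0:
            raise ValueError(f"ph_nbs {self.ph_nbs} outside [4, 11]")
        if not self.alk_umol_l > 0.0:
            raise ValueError("alk_umol_l must be positive")
        for name in ("po4_umol_l", "sioh4_umol_l"):
            v = getattr(self, name)
            if v is not None and v < 0.0:
                raise ValueError(f"{name} must be >= 0 when present")


@dataclass(frozen=True)
class ConstantSet:
    """Equilibrium constants at in-situ T, S — all on the NBS pH scale.

    First-order constants are mol L⁻¹; totals are µmol L⁻¹.
    """

    k0: float          # CO2 solubility, mol L-1 atm-1
    k1: float          # H2CO3* -> HCO3-
    k2: float          # HCO3- -> CO3--
    kb: float          # boric acid
    kw: float          # water ion product, (mol L-1)^2
    kp1: float
    kp2: float
    kp3: float
    ksi: float
    ks: float          # bisulfate, free scale
    fh: float          # SWS -> NBS activity factor
    total_borate: float    # umol L-1
    total_sulfate: float   # umol L-1
    temp_c: float = field(default=np.nan, compare=False)
    salinity: float = field(default=np.nan, compare=False)


@dataclass(frozen=True)
class CarbonateState:
    """Speciation output on the volumetric (µmol L⁻¹) basis."""

    co2_star_umol_l: float
    hco3_umol_l: float
    co3_umol_l: float
    dic_umol_l: float
    pco2_uatm: float
    carb_alk_umol_l: float
    valid: bool = True
    diagnostics: dict = field(default_factory=dict, compare=False)


def _fh(t_k: float, salinity):
    """GEOSECS activity-coefficient factor for SWS→NBS conversion."""
    return 1.2948 - 2.036e-3 * t_k + (4.607e-4 - 1.475e-6 * t_k) * salinity**2


def equilibrium_constants(temp_c, salinity, pressure_dbar: float = 0.0) -> ConstantSet:
    """Full constant set at in-situ conditions, NBS scale, volumetric basis.

    K0: Weiss (1974) volumetric fit.  K1/K2: Cai & Wang (1998), an
    estuarine formulation valid at low salinity, native NBS.  KB: Dickson
    (1990b).  KW, phosphoric and silicic acid: Millero (1995).  KS:
    Dickson (1990a), free scale.  Surface pressure only (the samples come
    from <1 m depth); ``pressure_dbar`` is accepted for interface
    symmetry and ignored.
    """
    temp_c = np.asarray(temp_c, dtype=float)
    salinity = np.asarray(salinity, dtype=float)
    if np.any(temp_c < _CAI_WANG_T_RANGE[0]) or np.any(temp_c > _CAI_WANG_T_RANGE[1]):
        warnings.warn(
            "temperature outside the carbonic-acid constants' fitted range "
            f"{_CAI_WANG_T_RANGE}; extrapolating", stacklevel=2)
    if np.any(salinity > _CAI_WANG_S_RANGE[1]):
        warnings.warn(
            "salinity above the carbonic-acid constants' fitted range "
            f"{_CAI_WANG_S_RANGE}; extrapolating", stacklevel=2)

    t_k = temp_c + 273.15
    ln_t = np.log(t_k)
    s = salinity
    sqrt_s = np.sqrt(s)
    fh = _fh(t_k, s)

    # Weiss 1974, mol L-1 atm-1 coefficient set.
    ln_k0 = (-58.0931 + 90.5069 * (100.0 / t_k) + 22.2940 * np.log(t_k / 100.0)
             + s * (0.027766 - 0.025888 * (t_k / 100.0)
                    + 0.0050578 * (t_k / 100.0) ** 2))
    k0 = np.exp(ln_k0)

    # Cai & Wang 1998 (NBS scale).
    f1 = 200.1 / t_k + 0.3220
    pk1 = (3404.71 / t_k + 0.032786 * t_k - 14.8435
           - 0.071692 * f1 * sqrt_s + 0.0021487 * s)
    f2 = -129.24 / t_k + 1.4381
    pk2 = (2902.39 / t_k + 0.02379 * t_k - 6.4980
           - 0.3191 * f2 * sqrt_s + 0.0198 * s)
    k1 = 10.0 ** (-pk1)
    k2 = 10.0 ** (-pk2)

    # Dickson 1990b boric acid (total scale -> NBS; the total/SWS offset
    # is the fluoride term, omitted with |error| < 0.2 %).
    ln_kb = ((-8966.90 - 2890.53 * sqrt_s - 77.942 * s
              + 1.728 * s**1.5 - 0.0996 * s**2) / t_k
             + 148.0248 + 137.1942 * sqrt_s + 1.62142 * s
             + (-24.4344 - 25.085 * sqrt_s - 0.2474 * s) * ln_t
             + 0.053105 * sqrt_s * t_k)
    kb = np.exp(ln_kb) * fh

    # Millero 1995 water ion product (SWS -> NBS).
    ln_kw = (148.9802 - 13847.26 / t_k - 23.6521 * ln_t
             + (118.67 / t_k - 5.977 + 1.0495 * ln_t) * sqrt_s - 0.01615 * s)
    kw = np.exp(ln_kw) * fh

    # Yao & Millero phosphoric acid (SWS -> NBS).
    ln_kp1 = (-4576.752 / t_k + 115.525 - 18.453 * ln_t
              + (-106.736 / t_k + 0.69171) * sqrt_s
              + (-0.65643 / t_k - 0.01844) * s)
    ln_kp2 = (-8814.715 / t_k + 172.0883 - 27.927 * ln_t
              + (-160.340 / t_k + 1.3566) * sqrt_s
              + (0.37335 / t_k - 0.05778) * s)
    ln_kp3 = (-3070.75 / t_k - 18.141
              + (17.27039 / t_k + 2.81197) * sqrt_s
              + (-44.99486 / t_k - 0.09984) * s)
    kp1 = np.exp(ln_kp1) * fh
    kp2 = np.exp(ln_kp2) * fh
    kp3 = np.exp(ln_kp3) * fh

    # Silicic acid (Millero 1995; ionic-strength form, SWS -> NBS).
    ion_s = 19.924 * s / (1000.0 - 1.005 * s)
    ln_ksi = (-8904.2 / t_k + 117.385 - 19.334 * ln_t
              + (-458.79 / t_k + 3.5913) * np.sqrt(ion_s)
              + (188.74 / t_k - 1.5998) * ion_s
              + (-12.1652 / t_k + 0.07871) * ion_s**2
              + np.log(1.0 - 0.001005 * s))
    ksi = np.exp(ln_ksi) * fh

    # Dickson 1990a bisulfate (free scale).
    ln_ks = (-4276.1 / t_k + 141.328 - 23.093 * ln_t
             + (-13856.0 / t_k + 324.57 - 47.986 * ln_t) * np.sqrt(ion_s)
             + (35474.0 / t_k - 771.54 + 114.723 * ln_t) * ion_s
             - 2698.0 / t_k * ion_s**1.5 + 1776.0 / t_k * ion_s**2
             + np.log(1.0 - 0.001005 * s))
    ks = np.exp(ln_ks)

    # Salinity-proportional totals (Uppström boron; Morris & Riley sulfate),
    # zero in fresh water.  umol L-1.
    total_borate = 11.877 * s
    total_sulfate = 806.86 * s

    def _f(x):
        return float(x) if np.ndim(x) == 0 else x

    return ConstantSet(
        k0=_f(k0), k1=_f(k1), k2=_f(k2), kb=_f(kb), kw=_f(kw),
        kp1=_f(kp1), kp2=_f(kp2), kp3=_f(kp3), ksi=_f(ksi), ks=_f(ks),
        fh=_f(fh), total_borate=_f(total_borate), total_sulfate=_f(total_sulfate),
        temp_c=_f(temp_c), salinity=_f(salinity),
    )


def fill_missing_nutrients(
    sample: WaterSample,
    po4_default: float = DEFAULT_PO4_UMOL_L,
    si_default: float = DEFAULT_SIOH4_UMOL_L,
) -> WaterSample:
    """Replace absent nutrient fields with the data-set averages.

    The returned sample records provenance: ``measured`` when nothing was
    filled, ``filled`` when both nutrients were absent, ``partial`` when
    only one was.
    """
    fill_po4 = sample.po4_umol_l is None
    fill_si = sample.sioh4_umol_l is None
    if not (fill_po4 or fill_si):
        return sample
    provenance = "filled" if (fill_po4 and fill_si) else "partial"
    return replace(
        sample,
        po4_umol_l=po4_default if fill_po4 else sample.po4_umol_l,
        sioh4_umol_l=si_default if fill_si else sample.sioh4_umol_l,
        nutrient_provenance=provenance,
    )


def noncarbonate_alkalinity(h_conc, constants: ConstantSet, po4_umol_l, si_umol_l):
    """Non-carbonate alkalinity (µmol L⁻¹) at a given [H⁺] (mol L⁻¹, NBS).

    Returns ``(total, components)`` where ``components`` exposes the four
    terms: ``borate``, ``water`` (OH⁻ − H⁺_free − HSO₄⁻), ``phosphate``
    (relative to the H₂PO₄⁻ zero level) and ``silicate``.
    """
    h = np.asarray(h_conc, dtype=float)
    if np.any(h <= 0):
        raise ValueError("h_conc must be positive")
    c = constants
    tb = c.total_borate * 1e-6       # mol L-1
    tsul = c.total_sulfate * 1e-6
    tp = np.asarray(po4_umol_l, dtype=float) * 1e-6
    tsi = np.asarray(si_umol_l, dtype=float) * 1e-6

    borate = tb * c.kb / (c.kb + h)
    oh = c.kw / h
    # Proton terms need the free-scale concentration: NBS -> SWS via fH,
    # SWS -> free via the sulfate factor.
    h_free = (h / c.fh) / (1.0 + tsul / c.ks)
    hso4 = tsul * h_free / (c.ks + h_free)
    water = oh - h_free - hso4

    den = h**3 + c.kp1 * h**2 + c.kp1 * c.kp2 * h + c.kp1 * c.kp2 * c.kp3
    phosphate = tp * (c.kp1 * c.kp2 * h + 2.0 * c.kp1 * c.kp2 * c.kp3 - h**3) / den
    silicate = tsi * c.ksi / (c.ksi + h)

    components = {
        "borate": borate * 1e6,
        "water": water * 1e6,
        "phosphate": phosphate * 1e6,
        "silicate": silicate * 1e6,
    }
    total = sum(components.values())
    return total, components


def speciate(sample: WaterSample, constants: ConstantSet | None = None) -> CarbonateState:
    """Full carbonate speciation of a (pH, A_T) sample.

    Carbonate alkalinity CA = A_T − (non-carbonate terms at the measured
    [H⁺]); then HCO₃⁻ = CA·[H⁺]/([H⁺]+2K₂), CO₃²⁻ = CA·K₂/([H⁺]+2K₂),
    CO₂* = HCO₃⁻·[H⁺]/K₁ and pCO₂ = CO₂*/K₀.

    A sample whose non-carbonate alkalinity exceeds A_T (CA ≤ 0) yields an
    ``invalid`` state carrying diagnostics instead of NaNs.
    """
    if sample.po4_umol_l is None or sample.sioh4_umol_l is None:
        raise ValueError("nutrients must be filled before speciation "
                         "(see fill_missing_nutrients)")
    c = constants if constants is not None else equilibrium_constants(
        sample.temp_c, sample.salinity, sample.pressure_dbar)

    h = 10.0 ** (-sample.ph_nbs)   # mol L-1, NBS
    nc_alk, components = noncarbonate_alkalinity(
        h, c, sample.po4_umol_l, sample.sioh4_umol_l)
    carb_alk = sample.alk_umol_l - nc_alk      # umol L-1

    if carb_alk <= 0.0:
        return CarbonateState(
            co2_star_umol_l=0.0, hco3_umol_l=0.0, co3_umol_l=0.0,
            dic_umol_l=0.0, pco2_uatm=0.0, carb_alk_umol_l=carb_alk,
            valid=False,
            diagnostics={"noncarbonate_alk_umol_l": nc_alk, **components},
        )

    hco3 = carb_alk * h / (h + 2.0 * c.k2)
    co3 = carb_alk * c.k2 / (h + 2.0 * c.k2)
    co2_star = hco3 * h / c.k1
    dic = co2_star + hco3 + co3
    pco2 = co2_star / c.k0         # umol L-1 / (mol L-1 atm-1) = uatm

    return CarbonateState(
        co2_star_umol_l=co2_star, hco3_umol_l=hco3, co3_umol_l=co3,
        dic_umol_l=dic, pco2_uatm=pco2, carb_alk_umol_l=carb_alk,
        valid=True,
        diagnostics={"noncarbonate_alk_umol_l": nc_alk, **components},
    )


def pco2_from_ta_ph(temp_c, salinity, alk_umol_l, ph_nbs,
                    po4_umol_l=DEFAULT_PO4_UMOL_L,
                    si_umol_l=DEFAULT_SIOH4_UMOL_L):
    """Vectorized pCO₂ (µatm) from arrays of T, S, A_T and NBS pH.

    Array counterpart of :func:`speciate` used on daily interpolated
    series; carbonate alkalinity ≤ 0 yields NaN for that element.
    """
    c = equilibrium_constants(temp_c, salinity)
    h = 10.0 ** (-np.asarray(ph_nbs, dtype=float))
    nc_alk, _ = noncarbonate_alkalinity(h, c, po4_umol_l, si_umol_l)
    carb_alk = np.asarray(alk_umol_l, dtype=float) - nc_alk
    hco3 = carb_alk * h / (h + 2.0 * c.k2)
    co2_star = hco3 * h / c.k1
    pco2 = co2_star / c.k0
    return np.where(carb_alk > 0.0, pco2, np.nan)
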