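"""Independent carbonate-chemistry oracle for the test suite.

A self-contained pH–A_T solver that shares no code with the package: the
published constant formulations are re-typed here in pK/log form, and
instead of decomposing carbonate alkalinity in closed form, total DIC is
found by bracketed root-finding on the full alkalinity balance
TA(DIC, [H⁺]); pCO₂ then follows from the DIC speciation fractions.
Agreement with the package therefore checks the algebra through a
genuinely different computational route, while frozen literature anchors
(freshwater pK1/pK2, Weiss K₀) pin the constants themselves.

Conventions mirror the package's declared ones: NBS proton scale,
volumetric (µmol L⁻¹) concentration basis.
"""

from __future__ import annotations

import math

from scipy.optimize import brentq


def oracle_constants(t_c: float, s: float) -> dict:
    tk = t_c + 273.15
    lnt = math.log(tk)
    rs = math.sqrt(s)
    fh = 1.2948 - 2.036e-3 * tk + (4.607e-4 - 1.475e-6 * tk) * s * s

    # Weiss 1974 solubility, volumetric coefficient set (mol/L/atm).
    k0 = math.exp(-58.0931 + 90.5069 * 100.0 / tk
                  + 22.2940 * math.log(tk / 100.0)
                  + s * (0.027766 + (tk / 100.0) * (-0.025888
                                                    + 0.0050578 * tk / 100.0)))

    # Cai & Wang 1998 carbonic acid, NBS scale (pK polynomial form).
    pk1 = (3404.71 / tk + 0.032786 * tk - 14.8435
           - 0.071692 * (200.1 / tk + 0.3220) * rs + 0.0021487 * s)
    pk2 = (2902.39 / tk + 0.02379 * tk - 6.4980
           - 0.3191 * (-129.24 / tk + 1.4381) * rs + 0.0198 * s)
    k1, k2 = 10.0 ** -pk1, 10.0 ** -pk2

    # Dickson 1990b borate (total scale ~ SWS with fluoride omitted).
    kb = fh * math.exp(
        (-8966.90 - 2890.53 * rs - 77.942 * s + 1.728 * s**1.5
         - 0.0996 * s * s) / tk
        + 148.0248 + 137.1942 * rs + 1.62142 * s
        - (24.4344 + 25.085 * rs + 0.2474 * s) * lnt
        + 0.053105 * rs * tk)

    # Millero 1995 water (SWS -> NBS).
    kw = fh * math.exp(148.9802 - 13847.26 / tk - 23.6521 * lnt
                       + (118.67 / tk - 5.977 + 1.0495 * lnt) * rs
                       - 0.01615 * s)

    # Yao & Millero phosphoric / silicic acids (SWS -> NBS).
    kp1 = fh * math.exp(-4576.752 / tk + 115.525 - 18.453 * lnt
                        + (-106.736 / tk + 0.69171) * rs
                        + (-0.65643 / tk - 0.01844) * s)
    kp2 = fh * math.exp(-8814.715 / tk + 172.0883 - 27.927 * lnt
                        + (-160.340 / tk + 1.3566) * rs
                        + (0.37335 / tk - 0.05778) * s)
    kp3 = fh * math.exp(-3070.75 / tk - 18.141
                        + (17.27039 / tk + 2.81197) * rs
                        + (-44.99486 / tk - 0.09984) * s)
    ion = 19.924 * s / (1000.0 - 1.005 * s)
    ksi = fh * math.exp(-8904.2 / tk + 117.385 - 19.334 * lnt
                        + (-458.79 / tk + 3.5913) * math.sqrt(ion)
                        + (188.74 / tk - 1.5998) * ion
                        + (-12.1652 / tk + 0.07871) * ion * ion
                        + math.log(1.0 - 0.001005 * s))
    ks = math.exp(-4276.1 / tk + 141.328 - 23.093 * lnt
                  + (-13856.0 / tk + 324.57 - 47.986 * lnt) * math.sqrt(ion)
                  + (35474.0 / tk - 771.54 + 114.723 * lnt) * ion
                  - 2698.0 / tk * ion**1.5 + 1776.0 / tk * ion * ion
                  + math.log(1.0 - 0.001005 * s))

    return {"k0": k0, "k1": k1, "k2": k2, "kb": kb, "kw": kw,
            "kp1": kp1, "kp2": kp2, "kp3": kp3, "ksi": ksi, "ks": ks,
            "fh": fh, "tb": 11.877 * s * 1e-6, "tso4": 806.86 * s * 1e-6}


def _alkalinity(dic: float, h: float, c: dict, tp: float, tsi: float) -> float:
    """Total alkalinity (mol/L) from DIC and [H⁺] via speciation fractions."""
    d = h * h + c["k1"] * h + c["k1"] * c["k2"]
    carb = dic * (c["k1"] * h + 2.0 * c["k1"] * c["k2"]) / d
    borate = c["tb"] * c["kb"] / (c["kb"] + h)
    oh = c["kw"] / h
    hfree = (h / c["fh"]) / (1.0 + c["tso4"] / c["ks"])
    hso4 = c["tso4"] * hfree / (c["ks"] + hfree)
    pden = (h**3 + c["kp1"] * h * h + c["kp1"] * c["kp2"] * h
            + c["kp1"] * c["kp2"] * c["kp3"])
    phos = tp * (c["kp1"] * c["kp2"] * h
                 + 2.0 * c["kp1"] * c["kp2"] * c["kp3"] - h**3) / pden
    sil = tsi * c["ksi"] / (c["ksi"] + h)
    return carb + borate + oh + phos + sil - hfree - hso4


def oracle_pco2(t_c: float, s: float, ta_umol_l: float, ph_nbs: float,
                po4_umol_l: float = 0.0, si_umol_l: float = 0.0) -> float:
    """pCO₂ (µatm) from the pH–A_T pair by root-finding on DIC."""
    c = oracle_constants(t_c, s)
    h = 10.0 ** -ph_nbs
    ta = ta_umol_l * 1e-6
    tp, tsi = po4_umol_l * 1e-6, si_umol_l * 1e-6

    def resid(dic):
        return _alkalinity(dic, h, c, tp, tsi) - ta

    dic = brentq(resid, 1e-12, 1.0, xtol=1e-15, rtol=1e-14)
    alpha0 = h * h / (h * h + c["k1"] * h + c["k1"] * c["k2"])
    return dic * alpha0 / c["k0"] * 1e6
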