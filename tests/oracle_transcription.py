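"""Straight scalar transcription of the printed equilibrium equations.

This module is an independent oracle used only by the test suite: a literal,
scalar-math re-statement of the hemoglobin O2/CO2/H+ saturation equations
(solubilities, Phi interaction terms, P50 shift polynomials, variable Hill
coefficient, apparent equilibrium constants, saturations).  It deliberately
shares no code with the package and must never import from ``hbcurve``.
"""

import math

W_PL = 0.94

K2P = 21.5      # 1/M, CO2 + HbNH2 binding
K2PP = 1e-6     # M, HbNHCOOH ionization
K3P = 11.3      # 1/M, CO2 + O2HbNH2 binding
K3PP = 1e-6     # M, O2HbNHCOOH ionization
K5PP = 2.4e-8   # M, HbNH3+ ionization
K6PP = 1.2e-8   # M, O2HbNH3+ ionization

HILL_ALPHA = 2.8
HILL_BETA = 1.20
HILL_GAMMA = 29.2  # mmHg

P50_S = 26.8       # mmHg
PCO2_S = 40.0      # mmHg
PH_PL_S = 7.4
DPG_S = 4.65e-3    # M
T_S = 37.0         # degC

GIBBS_DONNAN = 0.69


def alpha_o2(T):
    dT = T - 37.0
    return (1.37 - 1.37e-2 * dT + 5.8e-4 * dT ** 2) * 1e-6 / W_PL


def alpha_co2(T):
    dT = T - 37.0
    return (3.07 - 5.7e-2 * dT + 2e-3 * dT ** 2) * 1e-5 / W_PL


def hill_n(po2):
    return HILL_ALPHA - HILL_BETA * 10.0 ** (-po2 / HILL_GAMMA)


def p50_oracle(ph_rbc, pco2, dpg, T):
    ph_pl = ph_rbc - math.log10(GIBBS_DONNAN)
    dph = ph_pl - PH_PL_S
    p_ph = P50_S - 25.535 * dph + 10.646 * dph ** 2 - 1.764 * dph ** 3
    dc = pco2 - PCO2_S
    p_co2 = P50_S + 1.273e-1 * dc + 1.083e-4 * dc ** 2
    dd = dpg - DPG_S
    p_dpg = P50_S + 795.63 * dd - 19660.89 * dd ** 2
    dt = T - T_S
    p_t = P50_S + 1.435 * dt + 4.163e-2 * dt ** 2 + 6.86e-4 * dt ** 3
    return P50_S * (p_ph / P50_S) * (p_co2 / P50_S) * (p_dpg / P50_S) * (p_t / P50_S)


def saturations_oracle(po2, pco2, ph_rbc, dpg, T):
    """Return (S_HbO2, S_HbCO2) by literal evaluation of the printed model."""
    aO2 = alpha_o2(T)
    aCO2 = alpha_co2(T)
    H = 10.0 ** (-ph_rbc)
    phi1 = 1.0 + K2PP / H
    phi2 = 1.0 + K3PP / H
    phi3 = 1.0 + H / K5PP
    phi4 = 1.0 + H / K6PP
    p50 = p50_oracle(ph_rbc, pco2, dpg, T)
    nh = hill_n(po2)
    cc = aCO2 * pco2
    oo = aO2 * po2
    k4p = (oo ** (nh - 1.0) * (K2P * cc * phi1 + phi3)) / (
        (aO2 * p50) ** nh * (K3P * cc * phi2 + phi4)
    )
    k_hbo2 = k4p * (K3P * cc * phi2 + phi4) / (K2P * cc * phi1 + phi3)
    k_hbco2 = (K2P * phi1 + K3P * k4p * oo * phi2) / (phi3 + k4p * oo * phi4)
    s_o2 = k_hbo2 * oo / (1.0 + k_hbo2 * oo)
    s_co2 = k_hbco2 * cc / (1.0 + k_hbco2 * cc)
    return s_o2, s_co2


def hco3_oracle(ph_plasma, pco2, hb_gdl):
    expo = (
        ph_plasma
        - 7.376 * (1.0 - 0.00305 * hb_gdl)
        + 0.848 * (1.0 - 0.0162 * hb_gdl) * math.log10(pco2)
    )
    return 10.0 ** expo
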