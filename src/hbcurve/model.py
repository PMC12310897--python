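"""Equilibrium O2/CO2/H+ binding model of hemoglobin inside red blood cells.

The model treats each Hb monomer chain as carrying one heme (O2 site) and one
terminal amine that can bind CO2 as an ionizable carbamate or a proton.  Six
coupled mass-action equilibria give closed-form apparent association
constants K_HbO2 and K_HbCO2, from which the O2 and CO2 saturations follow as
simple binding isotherms.  Cooperativity of O2 binding enters through a
PO2-dependent Hill coefficient, and the competing effects of pH, CO2,
2,3-DPG and temperature enter through a multiplicatively-combined shift of
the half-saturation pressure P50 (Bohr effect and friends).

All computational routines broadcast over numpy arrays; saturations are
independent of hematocrit and Hb concentration by construction (those scale
absolute contents only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .constants import HB_MOLAR_MASS_G_PER_MOL, ModelConstants

__all__ = [
    "BloodGasState",
    "SaturationResult",
    "SpeciesDistribution",
    "solubility_O2",
    "solubility_CO2",
    "hill_coefficient",
    "p50",
    "saturations",
    "species_distribution",
    "ph_rbc_from_plasma",
    "ph_plasma_from_rbc",
    "bicarbonate_nomogram",
]

_DEFAULT = ModelConstants()


@dataclass(frozen=True)
class BloodGasState:
    """One physicochemical condition: the model's seven inputs.

    PO2/PCO2 in mmHg, pH referenced to the RBC interior, [2,3-DPG] in M,
    temperature in degC, hematocrit as a volume fraction and Hb concentration
    inside RBCs in M.  Hct and Hb_rbc do not influence saturations; they are
    carried for absolute-concentration scaling only.
    """

    PO2: float
    PCO2: float
    pH_rbc: float
    DPG: float = 4.65e-3
    T: float = 37.0
    Hct: float = 0.45
    Hb_rbc: float = 0.00528

    def __post_init__(self) -> None:
        if not np.isfinite([self.PO2, self.PCO2, self.pH_rbc, self.DPG, self.T]).all():
            raise ValueError("blood-gas state fields must be finite")
        if self.PO2 < 0:
            raise ValueError(f"PO2 must be >= 0 mmHg, got {self.PO2}")
        if self.PCO2 <= 0:
            raise ValueError(f"PCO2 must be > 0 mmHg, got {self.PCO2}")
        if self.DPG <= 0:
            raise ValueError(f"[2,3-DPG] must be > 0 M, got {self.DPG}")
        if not (0 < self.Hct < 1):
            raise ValueError(f"Hct must be a fraction in (0,1), got {self.Hct}")
        if self.Hb_rbc <= 0:
            raise ValueError(f"Hb_rbc must be > 0 M, got {self.Hb_rbc}")
        if not (6.0 <= self.pH_rbc <= 8.0):
            warnings.warn(
                f"pH_rbc={self.pH_rbc:.3f} outside the physiologic sanity range [6, 8]",
                stacklevel=2,
            )
        if not (30.0 <= self.T <= 44.0):
            warnings.warn(
                f"T={self.T:.1f} degC outside the validity range [30, 44] of the "
                "solubility and P50 temperature polynomials",
                stacklevel=2,
            )

    def replace(self, **kw) -> "BloodGasState":
        import dataclasses

        return dataclasses.replace(self, **kw)

    @property
    def hb_gdl(self) -> float:
        """Whole-blood Hb concentration in g/dL (for the HCO3- nomogram)."""
        return self.Hb_rbc * self.Hct * HB_MOLAR_MASS_G_PER_MOL / 10.0


@dataclass(frozen=True)
class SaturationResult:
    """O2 and CO2 saturations with the P50 and Hill coefficient used."""

    S_HbO2: float
    S_HbCO2: float
    P50: float
    nH: float


@dataclass(frozen=True)
class SpeciesDistribution:
    """Fractional abundances of the eight Hb amine/carbamate species.

    Fractions are per Hb amine terminus (one per monomer chain) and sum to 1.
    The four O2-bearing fractions sum to S_HbO2 and the four carbamate
    fractions to S_HbCO2.  HCO3 is plasma bicarbonate in mmol/L from the
    Siggaard-Andersen nomogram (not a Hb species).
    """

    f_HbNH2: float
    f_HbNH3p: float
    f_HbNHCOOH: float
    f_HbNHCOOm: float
    f_O2HbNH2: float
    f_O2HbNH3p: float
    f_O2HbNHCOOH: float
    f_O2HbNHCOOm: float
    HCO3: float

    @property
    def fractions(self) -> np.ndarray:
        return np.array(
            [
                self.f_HbNH2,
                self.f_HbNH3p,
                self.f_HbNHCOOH,
                self.f_HbNHCOOm,
                self.f_O2HbNH2,
                self.f_O2HbNH3p,
                self.f_O2HbNHCOOH,
                self.f_O2HbNHCOOm,
            ]
        )

    def concentrations(self, Hb_rbc: float, Hct: float) -> np.ndarray:
        """Absolute species concentrations (M of amine termini in blood).

        Scaling by 4 chains x [Hb] x Hct is an offset in log space only; all
        curve geometry (inflections, intersections) is invariant to it.
        """
        return self.fractions * 4.0 * Hb_rbc * Hct


def _warn_T_range(T) -> None:
    T = np.asarray(T, dtype=float)
    if np.any(T < 30.0) or np.any(T > 44.0):
        warnings.warn(
            "temperature outside [30, 44] degC: solubility polynomials extrapolated",
            stacklevel=3,
        )


def solubility_O2(T, constants: ModelConstants = _DEFAULT):
    """O2 solubility in plasma water, M/mmHg, as a quadratic in (T - 37)."""
    _warn_T_range(T)
    dT = np.asarray(T, dtype=float) - 37.0
    return (1.37 - 1.37e-2 * dT + 5.8e-4 * dT**2) * 1e-6 / constants.W_pl


def solubility_CO2(T, constants: ModelConstants = _DEFAULT):
    """CO2 solubility in plasma water, M/mmHg, as a quadratic in (T - 37)."""
    _warn_T_range(T)
    dT = np.asarray(T, dtype=float) - 37.0
    return (3.07 - 5.7e-2 * dT + 2e-3 * dT**2) * 1e-5 / constants.W_pl


def hill_coefficient(PO2, constants: ModelConstants = _DEFAULT):
    """Variable-cooperativity Hill coefficient nH(PO2).

    nH rises from alpha - beta at PO2 = 0 towards alpha at high PO2,
    expressing apparent cooperativity that grows with oxygenation.
    """
    PO2 = np.asarray(PO2, dtype=float)
    return constants.hill_alpha - constants.hill_beta * 10.0 ** (-PO2 / constants.hill_gamma)


def ph_rbc_from_plasma(pH_plasma, constants: ModelConstants = _DEFAULT):
    """Intra-RBC pH from plasma pH via the Gibbs-Donnan H+ ratio."""
    return np.asarray(pH_plasma, dtype=float) + np.log10(constants.gibbs_donnan)


def ph_plasma_from_rbc(pH_rbc, constants: ModelConstants = _DEFAULT):
    """Plasma pH from intra-RBC pH (inverse Gibbs-Donnan shift)."""
    return np.asarray(pH_rbc, dtype=float) - np.log10(constants.gibbs_donnan)


def _p50_arrays(pH_plasma, PCO2, DPG, T, c: ModelConstants):
    """P50 (mmHg) with the four normalized shift factors multiplied together."""
    dph = np.asarray(pH_plasma, dtype=float) - c.pH_pl_S
    p_ph = c.P50_S - 25.535 * dph + 10.646 * dph**2 - 1.764 * dph**3
    dc = np.asarray(PCO2, dtype=float) - c.PCO2_S
    p_co2 = c.P50_S + 1.273e-1 * dc + 1.083e-4 * dc**2
    dd = np.asarray(DPG, dtype=float) - c.DPG_S
    p_dpg = c.P50_S + 795.63 * dd - 19660.89 * dd**2
    dt = np.asarray(T, dtype=float) - c.T_S
    p_t = c.P50_S + 1.435 * dt + 4.163e-2 * dt**2 + 6.86e-4 * dt**3
    return c.P50_S * (p_ph / c.P50_S) * (p_co2 / c.P50_S) * (p_dpg / c.P50_S) * (p_t / c.P50_S)


def p50(state: BloodGasState, constants: ModelConstants = _DEFAULT) -> float:
    """Half-saturation PO2 (mmHg) after pH/CO2/DPG/temperature shifts.

    The pH shift is referenced to plasma pH (standard 7.4); the state's
    intra-RBC pH is converted through the Gibbs-Donnan relation first.
    """
    ph_pl = ph_plasma_from_rbc(state.pH_rbc, constants)
    val = float(_p50_arrays(ph_pl, state.PCO2, state.DPG, state.T, constants))
    if val <= 0:
        raise ValueError(
            f"P50 = {val:.3f} mmHg is non-positive: state outside model validity"
        )
    return val


def _saturation_arrays(PO2, PCO2, pH_rbc, DPG, T, c: ModelConstants):
    """Vectorized core: S_HbO2, S_HbCO2, P50, nH over broadcastable inputs.

    Follows the printed closed forms: Phi interaction terms in [H+], K4' from
    the variable-nH Hill closure, apparent constants K_HbO2/K_HbCO2, and the
    two binding isotherms.  PO2 = 0 falls out naturally since nH(0) > 1.
    """
    PO2 = np.asarray(PO2, dtype=float)
    PCO2 = np.asarray(PCO2, dtype=float)
    pH_rbc = np.asarray(pH_rbc, dtype=float)
    if np.any(PO2 < 0):
        raise ValueError("PO2 must be >= 0 mmHg")
    if np.any(PCO2 <= 0):
        raise ValueError("PCO2 must be > 0 mmHg")

    aO2 = solubility_O2(T, c)
    aCO2 = solubility_CO2(T, c)
    H = 10.0 ** (-pH_rbc)
    phi1 = 1.0 + c.K2pp / H
    phi2 = 1.0 + c.K3pp / H
    phi3 = 1.0 + H / c.K5pp
    phi4 = 1.0 + H / c.K6pp

    ph_pl = ph_plasma_from_rbc(pH_rbc, c)
    P50v = _p50_arrays(ph_pl, PCO2, DPG, T, c)
    if np.any(P50v <= 0):
        raise ValueError("non-positive P50 encountered: state outside model validity")
    nH = c.hill_alpha - c.hill_beta * 10.0 ** (-PO2 / c.hill_gamma)

    cc = aCO2 * PCO2
    oo = aO2 * PO2
    deoxy = c.K2p * cc * phi1 + phi3
    oxy = c.K3p * cc * phi2 + phi4
    # oo**(nH-1) is well-defined at PO2=0 because nH(0)-1 = alpha-beta-1 > 0
    K4p = oo ** (nH - 1.0) * deoxy / ((aO2 * P50v) ** nH * oxy)
    K_HbO2 = K4p * oxy / deoxy
    K_HbCO2 = (c.K2p * phi1 + c.K3p * K4p * oo * phi2) / (phi3 + K4p * oo * phi4)

    S_O2 = K_HbO2 * oo / (1.0 + K_HbO2 * oo)
    S_CO2 = K_HbCO2 * cc / (1.0 + K_HbCO2 * cc)
    return S_O2, S_CO2, P50v, nH


def saturations(state: BloodGasState, constants: ModelConstants = _DEFAULT) -> SaturationResult:
    """O2 and CO2 saturations of Hb at one blood-gas state.

    Independent of Hct and Hb_rbc.  At PO2 equal to the state's P50 the O2
    saturation is exactly one half, by construction of the Hill closure.
    """
    s_o2, s_co2, p50v, nh = _saturation_arrays(
        state.PO2, state.PCO2, state.pH_rbc, state.DPG, state.T, constants
    )
    return SaturationResult(float(s_o2), float(s_co2), float(p50v), float(nh))


def _species_arrays(PO2, PCO2, pH_rbc, DPG, T, c: ModelConstants):
    """Eight species fractions via mass-action partitioning of each branch.

    Within the deoxy branch the weights relative to HbNH2 are
    {1, H/K5'', K2' c, K2' c K2''/H}; within the oxy branch relative to
    O2HbNH2 they are {1, H/K6'', K3' c, K3' c K3''/H}.  Each branch is then
    scaled to its share of hemes, (1 - S_HbO2) and S_HbO2.
    """
    s_o2, s_co2, _, _ = _saturation_arrays(PO2, PCO2, pH_rbc, DPG, T, c)
    H = 10.0 ** (-np.asarray(pH_rbc, dtype=float))
    if np.any(H <= 0) or not np.all(np.isfinite(H)):
        raise ValueError("pH out of range: [H+] must be positive and finite")
    cc = solubility_CO2(T, c) * np.asarray(PCO2, dtype=float)

    w_nh2 = np.ones_like(H)
    w_nh3p = H / c.K5pp
    w_cooh = c.K2p * cc * np.ones_like(H)
    w_coom = c.K2p * cc * c.K2pp / H
    tot_d = w_nh2 + w_nh3p + w_cooh + w_coom

    v_nh2 = np.ones_like(H)
    v_nh3p = H / c.K6pp
    v_cooh = c.K3p * cc * np.ones_like(H)
    v_coom = c.K3p * cc * c.K3pp / H
    tot_o = v_nh2 + v_nh3p + v_cooh + v_coom

    deoxy_scale = (1.0 - s_o2) / tot_d
    oxy_scale = s_o2 / tot_o
    return (
        w_nh2 * deoxy_scale,
        w_nh3p * deoxy_scale,
        w_cooh * deoxy_scale,
        w_coom * deoxy_scale,
        v_nh2 * oxy_scale,
        v_nh3p * oxy_scale,
        v_cooh * oxy_scale,
        v_coom * oxy_scale,
        s_o2,
        s_co2,
    )


def species_distribution(
    state: BloodGasState, constants: ModelConstants = _DEFAULT
) -> SpeciesDistribution:
    """Partition Hb amine termini among the eight protonation/carbamate states.

    The partition is exactly consistent with the closed-form saturations: the
    O2-bearing fractions sum to S_HbO2 and the carbamate fractions to
    S_HbCO2.  Plasma HCO3- is attached from the nomogram for convenience.
    """
    out = _species_arrays(
        state.PO2, state.PCO2, state.pH_rbc, state.DPG, state.T, constants
    )
    hco3 = bicarbonate_nomogram(
        float(ph_plasma_from_rbc(state.pH_rbc, constants)), state.PCO2, state.hb_gdl
    )
    return SpeciesDistribution(*(float(x) for x in out[:8]), HCO3=float(hco3))


def bicarbonate_nomogram(pH_plasma, PCO2, Hb_gdl):
    """Plasma bicarbonate (mmol/L) from the Siggaard-Andersen nomogram fit.

    ``Hb_gdl`` is whole-blood hemoglobin in g/dL; PCO2 in mmHg.
    """
    PCO2 = np.asarray(PCO2, dtype=float)
    Hb_gdl = np.asarray(Hb_gdl, dtype=float)
    if np.any(PCO2 <= 0):
        raise ValueError("PCO2 must be > 0 mmHg")
    if np.any(Hb_gdl < 0):
        raise ValueError("Hb concentration must be >= 0 g/dL")
    expo = (
        np.asarray(pH_plasma, dtype=float)
        - 7.376 * (1.0 - 0.00305 * Hb_gdl)
        + 0.848 * (1.0 - 0.0162 * Hb_gdl) * np.log10(PCO2)
    )
    return 10.0**expo
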