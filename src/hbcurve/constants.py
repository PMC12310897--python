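"""Equilibrium constants and standard-state values for the Hb binding model.

All values live in :class:`ModelConstants`; the defaults are the published
parameterization of the red-blood-cell O2/CO2/H+ equilibrium model.  Every
constant can be overridden programmatically or from a YAML/JSON config file
keyed by the symbol names below (see :func:`load_constants`).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

__all__ = ["ModelConstants", "load_constants", "HB_MOLAR_MASS_G_PER_MOL"]

# molar mass of tetrameric human hemoglobin, used only to express whole-blood
# Hb in g/dL for the bicarbonate nomogram
HB_MOLAR_MASS_G_PER_MOL = 64458.0


@dataclass(frozen=True)
class ModelConstants:
    """Equilibrium/ionization constants, Hill parameters and standard state.

    Attributes
    ----------
    K1p, K1pp
        Equilibrium and ionization constants of the bicarbonate buffer
        reaction (CO2 hydration).  Kept for completeness; plasma bicarbonate
        is computed from the Siggaard-Andersen nomogram instead, so these do
        not enter any saturation equation.
    K2p, K2pp
        CO2 binding to deoxy HbNH2 (1/M) and HbNHCOOH ionization (M).
    K3p, K3pp
        CO2 binding to oxygenated O2HbNH2 (1/M) and O2HbNHCOOH ionization (M).
    K5pp, K6pp
        Ionization constants of HbNH3+ and O2HbNH3+ (M).
    hill_alpha, hill_beta, hill_gamma
        Parameters of the PO2-dependent (variable-cooperativity) Hill
        coefficient nH(PO2) = alpha - beta * 10^(-PO2/gamma); gamma in mmHg.
    P50_S
        PO2 at 50% O2 saturation at the standard state (mmHg).
    PO2_S, PCO2_S, pH_pl_S, DPG_S, T_S
        Standard partial pressures (mmHg), plasma pH, 2,3-DPG concentration
        (M) and temperature (degC).
    W_pl
        Fractional water space of plasma (dimensionless, in (0, 1]).
    gibbs_donnan
        H+ Gibbs-Donnan ratio across the RBC membrane, relating plasma and
        intra-RBC pH.
    """

    K1p: float = 1.4e-3
    K1pp: float = 5.5e-4
    K2p: float = 21.5
    K2pp: float = 1e-6
    K3p: float = 11.3
    K3pp: float = 1e-6
    K5pp: float = 2.4e-8
    K6pp: float = 1.2e-8
    hill_alpha: float = 2.8
    hill_beta: float = 1.20
    hill_gamma: float = 29.2
    P50_S: float = 26.8
    PO2_S: float = 100.0
    PCO2_S: float = 40.0
    pH_pl_S: float = 7.4
    DPG_S: float = 4.65e-3
    T_S: float = 37.0
    W_pl: float = 0.94
    gibbs_donnan: float = 0.69

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (v > 0):
                raise ValueError(f"constant {f.name} must be strictly positive, got {v}")
        if not (0 < self.W_pl <= 1):
            raise ValueError(f"W_pl must lie in (0, 1], got {self.W_pl}")

    def replace(self, **overrides: float) -> "ModelConstants":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_constants(path: str | Path | None = None, **overrides: float) -> ModelConstants:
    """Build a :class:`ModelConstants`, optionally from a YAML/JSON file.

    The file maps symbol names (``K2p``, ``P50_S``, ...) to numbers; keys not
    present keep their defaults.  Keyword overrides win over the file.
    """
    values: dict = {}
    if path is not None:
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in {".yaml", ".yml"}:
            import yaml

            values = yaml.safe_load(text) or {}
        else:
            values = json.loads(text)
        unknown = set(values) - {f.name for f in dataclasses.fields(ModelConstants)}
        if unknown:
            raise KeyError(f"unknown constant name(s) in {path}: {sorted(unknown)}")
    values.update(overrides)
    return ModelConstants(**values)
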