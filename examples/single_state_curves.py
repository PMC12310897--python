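"""Dissociation curves at one fixed blood chemistry.

Computes O2 and CO2 saturations of hemoglobin at the standard physiological
state, the half-saturation pressure P50, the oxygen dissociation curve (ODC)
and its inflection point, and the partitioning of Hb amine termini among the
eight protonation/carbamate species.
"""

from hbcurve import (
    BloodGasState,
    find_inflection,
    find_p50,
    in_vitro_curve,
    ph_rbc_from_plasma,
    saturations,
    species_distribution,
)

# standard state: PCO2 40 mmHg, plasma pH 7.4, [2,3-DPG] 4.65 mM, 37 degC
state = BloodGasState(
    PO2=40.0,  # a mixed-venous oxygen tension
    PCO2=40.0,
    pH_rbc=float(ph_rbc_from_plasma(7.4)),
    DPG=4.65e-3,
    T=37.0,
)

res = saturations(state)
print(f"At PO2 = {state.PO2:.0f} mmHg: S_HbO2 = {100 * res.S_HbO2:.1f}%  "
      f"S_HbCO2 = {100 * res.S_HbCO2:.1f}%  (nH = {res.nH:.2f})")
print(f"P50 (root search on the full model) = {find_p50(state):.2f} mmHg")

odc = in_vitro_curve(state, "ODC")
infl = find_inflection(odc)
print(f"ODC inflection: PO2 = {infl.PO2:.2f} mmHg at {100 * infl.value:.0f}% saturation")
# below this PO2 the curve is convex (concave-up): each further mmHg of PO2
# drop releases less O2, which is what the Bohr shift during exercise offsets

sp = species_distribution(state)
print("\nSpecies fractions (per Hb amine terminus):")
for name in ("f_HbNH2", "f_HbNH3p", "f_HbNHCOOH", "f_HbNHCOOm",
             "f_O2HbNH2", "f_O2HbNH3p", "f_O2HbNHCOOH", "f_O2HbNHCOOm"):
    print(f"  {name:14s} {getattr(sp, name):.4f}")
print(f"Plasma HCO3- (Siggaard-Andersen nomogram): {sp.HCO3:.1f} mmol/L")
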