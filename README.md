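# hbcurve

Mechanistic blood-gas analysis for incremental-exercise physiology: a
closed-form equilibrium model of O₂, CO₂ and H⁺ binding to hemoglobin inside
red blood cells, numerical dissociation-curve analysis (inflection points,
curve intersections), and an end-to-end pipeline for femoral-venous
blood-gas series sampled during cardiopulmonary exercise testing.

## Who this is for

Exercise physiologists and modellers who want to ask *where* on the oxygen
dissociation curve (ODC) a subject is operating as exercise intensity rises,
how the Bohr effect (acidosis, CO₂, temperature) reshapes the curve along the
way, and how the curve's **inflection point** — the PO₂ at which its
concavity changes, near 36 % O₂Hb saturation — relates to whole-body
thresholds such as the gas exchange threshold.

## The model

Each Hb monomer chain carries one heme (O₂ site) and one terminal amine that
binds CO₂ as an ionizable carbamate or a proton. Six mass-action equilibria
give apparent association constants, and the saturations are simple binding
isotherms:

```
S_HbO2  = K_HbO2 · α_O2 · PO2  / (1 + K_HbO2 · α_O2 · PO2)
S_HbCO2 = K_HbCO2 · α_CO2 · PCO2 / (1 + K_HbCO2 · α_CO2 · PCO2)
```

with temperature-corrected solubilities α, H⁺-interaction terms
Φ₁…Φ₄ built from the carbamate and amine ionization constants, and an O₂
association constant closed through a **variable-cooperativity Hill
relation**: `nH(PO2) = α − β·10^(−PO2/γ)` (1.6 at PO₂ = 0, →2.8 at high
PO₂). The half-saturation pressure is shifted multiplicatively from its
standard value P50,S = 26.8 mmHg by plasma pH, PCO₂, [2,3-DPG] and
temperature (empirical cubic/quadratic shift polynomials), so that
`K_HbO2·α_O2·PO2 = (PO2/P50)^nH` exactly. Intra-RBC pH follows plasma pH
through the Gibbs-Donnan ratio (0.69); plasma bicarbonate comes from the
Siggaard-Andersen nomogram. Saturations are provably independent of
hematocrit and Hb concentration, which scale absolute contents only.

On top of the state model:

* `curves` — sampled ODC / CDC (carbamate) / HDC (protonated-amine) curves on
  a uniform PO₂ grid (0–100 mmHg, 0.05 mmHg step), central-difference
  inflection detection with bracketed root refinement, linear-interpolant
  curve intersections, and P50 by root search.
* `pipeline` — cubic trajectory fits of PO₂/PCO₂/pH/SO₂ vs %V̇O₂max
  (degree for PCO₂/pH chosen by corrected AIC), per-sample blood-gas states
  with a 37→38 °C femoral temperature ramp, composite **in vivo** curves
  swept along the fitted chemistry, [2,3-DPG] calibration that zeroes the
  Bland–Altman bias between simulated and measured saturations, and a
  fixed-temperature sensitivity analysis.
* `synthetic` — a seeded generator of 12-sample exercise series (logistic
  PO₂ decline to a plateau, rising PCO₂, pH plunge past a threshold,
  model-generated "measured" SO₂ at a known true [2,3-DPG]) with a
  brute-force ground-truth inflection for recovery testing.

## Worked example

```bash
python examples/synthetic_exercise_analysis.py
```

prints (seed 1):

```
calibrated [2,3-DPG]: 0.00328 M (truth 0.00290 M)
Bland-Altman (simulated - measured SO2): bias -0.00 pp, LoA [-2.08, +2.08] pp, n = 12
sample 4 in vitro ODC inflection: 22.92 mmHg at 36% saturation
in vivo ODC inflection: 22.28 mmHg (generator truth 22.37 mmHg, error -0.096)
in vivo HDC inflection: 26.48 mmHg
```

Reading: the calibration finds the 2,3-DPG level at which the model's
saturations are unbiased against the (noisy) measured ones; each sample's
momentary ODC inflects near 36 % saturation; and the composite in vivo ODC —
the curve actually traversed as chemistry changes — inflects at ≈22 mmHg,
within 0.1 mmHg of the generator's noise-free truth. The other examples
(`single_state_curves.py`, `temperature_sensitivity.py`) show the
fixed-chemistry API and the temperature-ramp robustness check. A thin CLI
(`hbcurve simulate | curves | analyze | sensitivity`) wraps the same
functions for shell use.

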