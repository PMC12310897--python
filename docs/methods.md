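# Methods

## The equilibrium binding model

The model describes one Hb monomer chain as a heme site plus a terminal
amine, coupled through six mass-action equilibria inside the red blood cell:
CO₂ binding to the deoxy amine (K₂′, ionization K₂″), CO₂ binding to the oxy
amine (K₃′, K₃″), single-step O₂ binding (K₄′), and protonation of the deoxy
and oxy amines (ionization constants K₅″, K₆″). Solving the equilibria gives
apparent association constants K_HbO2 and K_HbCO2 and the two saturation
isotherms; the H⁺ dependence enters through four interaction terms

Φ₁ = 1 + K₂″/[H⁺], Φ₂ = 1 + K₃″/[H⁺], Φ₃ = 1 + [H⁺]/K₅″, Φ₄ = 1 + [H⁺]/K₆″

with [H⁺] = 10^(−pH_rbc) in M. (Dimensional analysis forces the
concentration reading: the ionization constants are molar, so dividing by a
bare pH number would be meaningless.)

O₂ cooperativity is closed phenomenologically: K₄′ is chosen so that
K_HbO2·α_O2·PO2 = (PO2/P50)^nH with a PO₂-dependent Hill coefficient
nH = α − β·10^(−PO2/γ) (α = 2.8, β = 1.20, γ = 29.2 mmHg). Two useful exact
consequences: S_HbO2(P50) = 1/2 identically, and S_HbO2(0) = 0 without any
special-casing because nH(0) − 1 = 0.6 > 0.

P50 combines four empirical shift polynomials multiplicatively,
P50 = P50,S·Π(P50,Δx/P50,S) over x ∈ {pH, CO₂, DPG, T}, from the standard
state P50,S = 26.8 mmHg at PCO₂ 40 mmHg, plasma pH 7.40, [2,3-DPG]
4.65·10⁻³ M, 37 °C. The pH argument of the pH shift is **plasma-referenced**
(the standard value is a plasma pH); the model state carries intra-RBC pH
and converts through the Gibbs-Donnan relation pH_pl = pH_rbc − log10(0.69).
Solubilities are quadratics in (T − 37) divided by the plasma water fraction
W_pl = 0.94 (α_O2 = 1.46·10⁻⁶, α_CO2 = 3.27·10⁻⁵ M/mmHg at 37 °C). All
constants live in `ModelConstants` and can be overridden from YAML/JSON.

Species partitioning distributes amine termini within each oxygenation
branch by the branch weights {1, [H⁺]/K₅″, K₂′c, K₂′cK₂″/[H⁺]} (deoxy) and
{1, [H⁺]/K₆″, K₃′c, K₃′cK₃″/[H⁺]} (oxy), c = α_CO2·PCO₂, each branch scaled
to (1 − S_HbO2) and S_HbO2. This partition is algebraically consistent with
the closed-form saturations (the carbamate fractions sum exactly to
S_HbCO2), which the tests verify to 1e-8 on random states. Fractions are
reported per amine terminus; absolute concentrations (×4·[Hb]·Hct) are an
optional scaling that never affects curve geometry. Plasma HCO₃⁻ uses the
Siggaard-Andersen nomogram fit (inputs: plasma pH, PCO₂, whole-blood Hb in
g/dL); the bicarbonate-buffer constants K₁′/K₁″ are stored for completeness
but feed no computation.

Assumptions: pure equilibrium chemistry (no kinetics, no blood–tissue
transport), pooled whole-blood values, fixed Gibbs-Donnan ratio, validity of
the empirical shift polynomials roughly over pH 6.8–7.8, PCO₂ 10–90 mmHg,
T 30–44 °C (states outside sanity bounds warn rather than fail).

## Curve analysis

Curves are sampled on a uniform PO₂ grid, default 0–100 mmHg in 0.05 mmHg
steps (2001 points) — fine enough that discretization is far below the
0.01 mmHg scale of reported results. The second derivative uses the
three-point central stencil; an inflection is a crossing of that curvature
from positive to negative (concave-up → concave-down), located by linear
interpolation and refined by bracketed root solving (tolerance 1e-6 mmHg,
deterministic). Curvature smaller than the round-off floor of the stencil is
treated as zero, so straight lines report "no inflection" instead of noise
crossings. With multiple candidates, the crossing whose curve value lies in
[0.2, 0.6] is preferred (the physiological ODC inflection sits near 36 %
saturation); remaining ties go to the lowest PO₂ with a warning.
Intersections are roots of the difference of the two linear interpolants on
the union of the grids; with several crossings the highest-PO₂ one is
returned (the first encountered as PO₂ falls during exercise). Halving the
grid step moves located points by well under 0.01 mmHg (tested).

## Exercise pipeline

Inputs are pooled per-sample femoral-venous measurements vs %V̇O₂max: PO₂,
PCO₂, plasma pH, O₂Hb saturation. PO₂ and SO₂ are fitted with cubic
polynomials (S-shaped channels need two curvature changes); PCO₂ and pH
select degree 1–3 by corrected AIC (k = degree + 2 counting the residual
variance; residuals are floored at the data's round-off so exact fits tie
toward the lowest degree). Per-sample states fix Hct = 0.45 and
[Hb]_rbc = 0.00528 M (irrelevant to saturations), convert pH, and warm
linearly from 37.0 °C (first sample) to 38.0 °C (last) — femoral blood
warms about 1 °C across an incremental test; trajectory evaluation ramps
linearly in %V̇O₂max between the first and last sample.

In vivo curves sweep the model along the fitted chemistry on a fine
%V̇O₂max grid (2001 points), yielding parametric traces (PO₂(v), value(v)).
For differentiation the trace is trimmed to the maximal prefix on which PO₂
strictly decreases — the near-plateau tail at the critical capillary PO₂
would otherwise make the second derivative ill-conditioned — and resampled
onto the uniform PO₂ grid.

[2,3-DPG] calibration: the mean Bland–Altman bias of (simulated − measured)
saturation is monotone decreasing in [2,3-DPG] (more DPG → higher P50 →
lower simulated saturation), so plain bisection on [0.0005, 0.00465] M
(upper bound = the model's default concentration) with tolerance 1e-5 M
finds the unbiased value. Limits of agreement are mean ± 1.96·SD (n−1
denominator). The sensitivity analysis re-runs everything with temperature
fixed at 37 °C and [2,3-DPG] re-calibrated, and reports PO₂ shifts of the
inflection/intersection quantities.

Two construction choices were genuinely open and are worth recording:

* **HDC definition.** The proton curve defaults to the total protonated
  amine fraction (f_HbNH3⁺ + f_O2HbNH3⁺); a config switch (`hdc =
  "deoxy_only"`) restricts to the deoxy species. With either definition the
  protonated fraction exceeds the carbamate fraction (CDC = S_HbCO2)
  several-fold throughout the physiological range, so the CDC–HDC
  intersection does not exist on these normalizations for the synthetic
  data; `run_analysis` then reports a flag rather than a number. Plots that
  show the two curves crossing must place them on per-curve scales.
* **Which composite inflects.** The composite ODC evaluated along smooth
  analytic trajectories is dominated at low PO₂ by the along-path Bohr term
  (the curve keeps steepening into the plateau), so whether an in vivo
  inflection exists depends on the trajectory's foot. The pipeline computes
  the inflection of the composite built from the *fitted* trajectories —
  the object the analysis actually constructs — and the synthetic ground
  truth is defined as the same construction applied to noise-free samples
  (independent code path: plain `np.polyfit` cubics and a brute-force
  1e-3 mmHg curvature scan). Recovery error then measures noise
  propagation through the whole chain, not polynomial-approximation bias.

## Synthetic data

The generator emulates pooled femoral-venous sampling over a 12-point
incremental test (rest → 100 %V̇O₂max): logistic PO₂ decline (asymptote
42 mmHg, plateau 15 mmHg, midpoint 35 %, width 10 %), PCO₂ rising 46 →
72 mmHg with mild convexity, pH drifting from 7.38 with an accelerating
quadratic drop past 60 %V̇O₂max (reaching ≈7.07), temperature ramping 37 →
38 °C. The plateau sits at the lower end of reported end-exercise values so
the composite curve retains a convex foot — and therefore an inflection
(≈22.4 mmHg at ≈34 % saturation, the scale at which the phenomenon is
reported) — below the Bohr-steepened mid-section. "Measured" SO₂ is the
model's own saturation at a true [2,3-DPG] of 0.0029 M, so calibration has
a recoverable truth; additive independent Gaussian noise (SDs 0.5 mmHg PO₂,
1 mmHg PCO₂, 0.008 pH, 1 pp SO₂) is seed-controlled.

What passing tests do **not** show about real data: real measured
saturations flatten near the extraction floor at high intensity (a
microcirculatory transport effect outside this equilibrium model), real
trajectories are not exactly logistic/polynomial, and pooled means hide
between-subject variance. The generator reproduces the statistical shape
and the recovery problem, not those mechanisms.

## Numerical and scale choices

Root refinement everywhere is bracketed (bisection/Brent), absolute
tolerance 1e-6 mmHg (1e-9 for P50), fully deterministic; identical inputs
give bit-identical reports. Closed-form identities are asserted at 1e-10
absolute (species sums at 1e-8, totals at 1e-12); the independent scalar
transcription of the printed equations agrees with the vectorized
implementation to 1e-12 relative on 1000 random states. Default problem
sizes — 2001-point curves, 12-sample series, 20-seed recovery batches —
were chosen so the entire suite runs in a few seconds while keeping
discretization error two orders of magnitude below reported precision.

## Limitations

Equilibrium only: no O₂/CO₂ stores, no transport, no kinetics, no
whole-blood content calculations. The shift polynomials are empirical fits
with limited extrapolation validity. The CDC–HDC intersection requires a
normalization choice (see above). Reproduction of the published
incremental-exercise numbers requires the deposited 12-sample dataset,
which is not redistributed; the corresponding test and the headline-value
checks run only once that file is supplied locally.
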