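# Methods

## Mechanical model

The culture channel is a soft PDMS tube loaded under displacement
control by an axial nominal strain ε and a total twist Ψ. Because the
loading is kinematically prescribed and the elastomer is isotropic,
homogeneous and effectively incompressible, the deformation of the
hollow tube coincides with that of a solid incompressible cylinder:
axial stretch λ = 1 + ε, twist rate ψ = Ψ_rad/L, radial map
r = λ^(−1/2)R. The closed-form deformation gradient, right Cauchy–Green
tensor and principal stretches implemented in `neurochip.mechanics`
follow directly; `principal_stretches_eigen` provides an independent
numerical eigen-decomposition route used as a cross-check in the test
suite (agreement to 1e-10 relative over randomized loads, except within
~1e-5 of the degenerate static point, where the discriminant cancels
below machine precision and the property is tested exactly at ψR = 0
instead).

Assumptions inherited by every downstream number:

* **Incompressibility** — det F = 1 identically; the volumetric Ogden
  compliance D is stored but never used.
* **Passive coating** — the polydopamine/collagen/cell layer carries no
  load; inner-wall strains of the bulk PDMS are what the neurons feel.
* **Zero radial stress** — the tube surface is traction free, so the
  Lagrange pressure is eliminated by σ_r = 0 and the in-plane stresses
  are reported as differences from the radial stress.
* **Homogeneous fields** — no end effects. This matters: see
  *Limitations*.

The one-term Ogden energy uses the convention
W = (2μ/α²) Σ(λᵢ^α − 3), the form under which the default parameters
(μ = 19.14 kPa, α = 1.5) were originally fitted, giving
σᵢ = (2μ/α)(λᵢ^α − λ_r^α). Sanity limits recovered by the tests: the
small-strain uniaxial modulus is 3μ (incompressible Young's modulus)
and the small-twist first principal stretch is 1 + ψR/2.

### Geometry and evaluation radius

Defaults: internal radius 0.75 mm, external radius 2.5 mm (1.5 mm
casting rod inside a 5 mm syringe bore), gauge length L = 50 mm. The
fabricated chip length is ambiguous at the source (an 8 cm casting rod
versus a 5 mm chip), so L is configurable everywhere; since only the
product ψR enters the kinematics, changing L rescales the torsional
contribution linearly. Stresses are evaluated at the inner wall by
default (the cells line it); the evaluation radius is configurable
because torsional strain grows with R.

### Damage metric and severity

σ̂ = ‖(σ₁, σ₂, σ_r)‖₂ with strict inequality σ̂ > threshold defining
"suprathreshold". The default threshold is 750 kPa, the scale at which
finite-element maxima (which include end-constraint stress
concentrations) separate strongly apoptotic conditions. The analytic
homogeneous solution with μ = 19.14 kPa tops out near 11 kPa at 20%
extension, so under the analytic model every default condition is
subthreshold; the threshold is a configurable parameter precisely
because the two stress scales differ by two orders of magnitude.

## Biosensor calibration

Signal definition: ΔI = I₀ − I_c, the DPV peak-current drop of the
antibody electrode relative to its BSA-blocked baseline (72.2 µA for
T-Tau, 75.7 µA for NFL). The response is modelled as
ΔI = a·X + b with X = log₁₀(concentration in fg/mL). The log base and
unit are a deliberate package choice: with X in log₁₀ fg/mL the four
published lines are positive over the full calibrated range
(100 fg/mL → X = 2) and predict ≈47 µA at 10 ng/mL, consistent with the
measured ≈43 µA drops. Fits are per-replicate ordinary least squares
(scipy's linear regression); preconditions require ≥3 points spanning
≥2 decades from a single analyte/matrix pair. Inversion
c = 10^((ΔI − b)/a) round-trips with prediction to machine precision;
signals outside the fitted range still return a value but emit an
`ExtrapolationWarning`, since post-injury time courses can dip below
the calibrated floor. A 3σ_blank limit-of-detection helper is provided
as a convenience; it is not part of the calibrated surface.

## Injury-response model

The measured release curves are reported only at
{15, 30, 60, 90, 120} min, peak at 15 min and decay progressively
without vanishing by 2 h. The mean model is a log-normal-in-time bump,

    c(t) = c₀ + A·exp(−ln²(t/tₚ)/(2w²)),  tₚ = 15 min, w = 1, c₀ = 2 pg/mL,

chosen because it is positive, unimodal with its maximum exactly at tₚ,
and decays slowly enough to stay above baseline at 120 min. Amplitudes
A are a per-condition, per-analyte table (not a fitted continuous law —
no such law is available), constrained to the ordinal structure of the
measurements:

* combined 12% + 90° exceeds every single-axis condition for both
  analytes;
* T-Tau rises for extension above 8%, NFL only at ≥12%;
* pure torsion stays near baseline through 90° and rises markedly from
  150°;
* T-Tau peaks in the low-hundreds pg/mL, NFL in the tens-to-hundreds.

Gene expression is handled through the ΔΔCt method
(fold = 2^(−ΔΔCt), Gapdh reference, static control). Default
fold-change tables: Mapt reaches 2.75-fold at 20% extension (midpoint
of the reported ≈2.5–3-fold band) and 3.2-fold at 12% + 90°; Gap-43 is
elevated at 20% extension, 300° torsion and the strongest combined
loads; Tubb3 is flat at 1.0 (identity marker stability). Apoptosis
probabilities: static 3%, pure extension ≤5%, 300° torsion 15%,
combined 8–12% + 60–90° between 20% and 25% with the maximum 25% at
12% + 90%.

Bimodal reporting of the NFL peak time exists in the source material
(one statement has NFL rising later); the package implements the
condition-independent 15-min peak for both analytes, which is the
statement the quantitative time-course analysis relies on.

## Synthetic-data generators

`neurochip.synthetic_data` emulates the instruments, not the biology:

| measurement | noise family | default scale |
|---|---|---|
| DPV calibration currents | additive Gaussian | σ = 0.5 µA (baseline jitter 0.3 µA) |
| biomarker concentrations | multiplicative log-normal, unit mean | CV = 0.15 |
| qPCR Ct values | additive Gaussian per Ct | σ = 0.15 cycles |
| Caspase-3⁺ counts | binomial | n = 500 cells/field |

Replication defaults mirror the study design: 8 decade-spaced
calibration levels (100 fg/mL–1 µg/mL) in triplicate, five biological
replicates per time course. The per-field cell count (500) is a chosen
default; the source reports no per-condition counts. Every generator
derives an independent child stream from (seed, generator name,
condition/analyte key) via a CRC32-keyed `SeedSequence`, so output is
byte-identical under a fixed seed and inserting an extra generator call
cannot perturb other streams. Zero-noise settings reproduce the mean
models exactly, which the tests exploit as oracles.

What the generators do **not** emulate — and hence what green tests do
not show about real data: inter-chip variability beyond the stated
noise families, sensor drift/fouling across a time course, matrix
effects beyond the published DMEM slopes, non-stationary apoptosis
(counts are a single binomial per field), and any mechanistic coupling
between σ̂ and release (the σ̂→response link is an ordinal table, not a
constitutive law).

## Pipeline

`run_pipeline` composes sweep → synthetic measurements → calibration
(fit from synthetic series, or the published reference lines) →
quantification (inversion of DPV readings in DMEM) → stratified report,
writing CSV/JSON artifacts with units embedded in column names and a
manifest (seed, config hash, package version). Output is a pure
function of (config, seed). The CLI (`neurochip sweep | calibrate |
simulate | quantify | report | run`) is a thin wrapper over these
stages.

## Numerical choices

* Discriminants of the closed-form stretch formula that fall within
  1e-12 of zero are clamped to zero; larger negatives raise.
* In-plane stretches sorted descending; at the degenerate static point
  (λ₁ = λ₂ = 1) the ordering is arbitrary.
* Severity uses strict ">" at the threshold.
* Angles are degrees at every interface and converted to radians once.
* Incompressibility of a supplied stretch triple is enforced to 1e-8
  before stress evaluation.

## Problem sizes

The packaged analyses run at the study's own scale: 25 loading
conditions, 24-point calibration series, five-replicate time courses on
a five-point grid, 500-cell imaging fields. Replicate ensembles used
for distributional checks (200 calibration refits per sensor, 50
apoptosis fields per condition) complete in seconds.

## Known limitations

* The megapascal-scale finite-element stress maxima reported for the
  same loading programme (e.g. ≈1.27 MPa at 20% extension, ≈787 kPa at
  12% + 90°) include end-constraint stress concentrations from the
  fully clamped tube ends and are **not** reproducible by the
  homogeneous analytical solution, which stays at the tens-of-kPa scale
  with the same material parameters. The package documents this gap
  rather than rescaling either side.
* A corollary: no single evaluation radius or gauge length makes the
  analytic σ̂ rank combined 12% + 90° above *both* 20% extension and
  300° torsion — if torsion is mechanically negligible, 20% extension
  dominates; if it is not, 300° torsion does. The synergy of combined
  loading is therefore carried by the response tables (amplitudes,
  apoptosis, fold changes), which encode it for every biological
  readout, not by the homogeneous stress metric.
* The kinetic bump is a descriptive mean model; it is not a secretion/
  transport mechanism and has no claim outside the 15–120 min window.
* No statistical inference (ANOVA/Tukey) is performed; the pipeline
  produces descriptive summaries only.
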