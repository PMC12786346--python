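# neurochip

Computational chain for a neuron-laden elastomer tube under programmed
mechanical insult: closed-form extension–torsion mechanics, Ogden
principal stresses with a damage-metric stratification, log-linear DPV
immunosensor calibration and inversion for the axonal-injury biomarkers
total tau (T-Tau) and neurofilament light chain (NFL), and a
load-dependent injury-response model — with seeded synthetic-data
generators standing in for the wet-lab instruments, so the entire
injury-stratification analysis runs at desk scale.

## Who this is for

Mechanobiologists and neurotrauma modellers who want an executable,
testable version of the analysis pipeline of a tube-based
neuron-injury-on-a-chip experiment: programmed axial extension (4–20%),
torsion (30°–300°), and combined extension–torsion (4–12% × 30°–90°)
applied to a soft cylindrical culture channel, with biomarker release,
gene expression (Mapt, Gap-43, Tubb3) and apoptosis (cleaved Caspase-3)
read out per condition.

## The model

**Mechanics.** For an isotropic, homogeneous, incompressible cylinder
under simultaneous axial stretch λ = 1 + ε and twist ψ = Ψ/L per unit
reference length, the deformation gradient in cylindrical coordinates is

```
F = [[λ^(-1/2), 0,        0        ],
     [0,        λ^(-1/2), ψR λ^(-1/2)],
     [0,        0,        λ        ]],        det F = 1.
```

The radial direction is principal with stretch λ^(−1/2); the in-plane
principal stretches come from the eigenvalues of the 2×2 block of
C = FᵀF:

```
λ²₁,₂ = (T ± sqrt(T² − 4λ³)) / 2λ,   T = λ³ + ψ²R² + 1,
```

so λ₁ > 1 > λ₂ under any non-trivial load. Stresses follow a one-term
incompressible Ogden energy W = (2μ/α²) Σ(λᵢ^α − 3) (μ = 19.14 kPa,
α = 1.5 by default) with the pressure eliminated by the traction-free
radial closure σ_r = 0:

```
σᵢ = (2μ/α)(λᵢ^α − λ_r^α),    σ̂ = sqrt(σ₁² + σ₂² + σ_r²).
```

σ̂ (the Euclidean norm of the principal Cauchy stresses) is the scalar
damage metric used to stratify severity against a configurable
threshold.

**Biosensing.** The DPV immunosensors report a current drop
ΔI = I₀ − I_c that is linear in log₁₀ concentration (fg/mL) over
0.1 pg/mL–1 µg/mL; four reference lines (T-Tau/NFL × PBS/DMEM) are
built in, fits are ordinary least squares, and inversion
c = 10^((ΔI − b)/a) is the exact inverse of prediction.

**Injury response.** Mean biomarker release follows a
log-normal-in-time bump c(t) = c₀ + A·exp(−ln²(t/tₚ)/2w²) peaking at
tₚ = 15 min; per-condition amplitudes, Caspase-3⁺ fractions and ΔΔCt
fold-change tables encode the ordinal structure of the measured
responses (combined 12% + 90° maximal for every readout).

## Worked example

```python
from neurochip import mechanics as mech, biosensing as bs, injury_response as ir

cond = mech.LoadingCondition(epsilon=0.12, Psi_deg=90)   # 12% extension + 90 deg twist
state = mech.deformation_state(cond)                     # evaluated at the inner wall
stress = mech.ogden_principal_stresses(state.lambda_1, state.lambda_2, state.lambda_r)
print(f"lambda1 = {state.lambda_1:.4f}, lambda2 = {state.lambda_2:.4f}")
print(f"sigma1 = {stress.sigma_1:.2f} kPa, sigma2 = {stress.sigma_2:.2f} kPa, "
      f"sigma_hat = {stress.sigma_hat:.2f} kPa")

kin = ir.default_kinetics("T-Tau")
curve = [round(ir.mean_concentration(kin, cond, t), 1) for t in ir.TIME_GRID_MIN]
print(f"mean T-Tau release (pg/mL) at {ir.TIME_GRID_MIN} min: {curve}")

model = bs.reference_model("T-Tau", "DMEM")
conc_fg = bs.invert_concentration(model, I0=72.2, Ic=31.5)
print(f"DPV drop of 40.7 uA -> T-Tau = {conc_fg/1e3:.0f} pg/mL")
```

prints

```
lambda1 = 1.1208, lambda2 = 0.9443
sigma1 = 6.84 kPa, sigma2 = -0.02 kPa, sigma_hat = 6.84 kPa
mean T-Tau release (pg/mL) at (15, 30, 60, 90, 120) min: [182.0, 143.6, 70.9, 38.2, 22.7]
DPV drop of 40.7 uA -> T-Tau = 277 pg/mL
```

The combined load stretches the inner wall by 12.1% along its first
principal direction while compressing the second (λ₂ < 1, the signature
of torsional shear); the biomarker burst peaks at 15 min and decays
over 2 h; and a measured 40.7 µA current drop in culture medium maps to
277 pg/mL of released tau.

The same chain runs end to end from the command line:

```
neurochip run --out study/            # sweep -> simulate -> calibrate -> quantify -> report
neurochip simulate --seed 7 --out study7/
neurochip sweep --out results/
```

`study/report.csv` holds the per-condition stratification (σ̂, severity,
biomarker fold over static, apoptotic fraction) and `heatmap.csv` the
heat-map-ready matrix. Reruns with the same configuration are
byte-identical.

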