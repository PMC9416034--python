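# buccalkinetics

Analysis toolkit for **buccal (transmucosal) drug delivery** development:
ex vivo Franz-diffusion-cell permeation kinetics, in vitro drug-release
model fitting with mechanistic decomposition, formulation quality
metrics for spray-dried tablet matrices, and pharmacokinetics-based
tablet sizing. It is aimed at formulation scientists who characterise
solid buccal dosage forms (matrix tablets, films) and want the whole
quantitative chain — raw acceptor-chamber readings to "how large must
the tablet be" — as tested, reproducible code instead of spreadsheet
arithmetic.

## What it computes

**Permeation (Franz cell).** From per-replicate acceptor concentrations
C(t), with replacement-sampling correction
`Q(t_n) = V_acc·C_n + V_smp·Σ_{i<n} C_i`:

- steady-state flux `Js = slope of Q/A vs t` over the linear window
  (auto-selected by maximising r² over end-anchored windows at least
  half the series long), µg·cm⁻²·h⁻¹;
- lag time `t_lag = −intercept/slope` (min);
- permeability coefficient `Kp = Js/Cd` (cm/h);
- tissue entrapment `De = Q_T/A` (µg/cm²) and accumulation
  `Ac = De/Cd` (cm);
- intrinsic Kp (mean ± SE over donor levels free of dose/saturation
  artefacts), enhancement ratios, and membrane-saturation flagging.

**Release kinetics.** Dose-fraction profiles D(t) (minutes), truncated
at 90% released, are fitted to six models — zero order `D = k·t`,
first order `D = 1−e^(−k·t)`, Higuchi `D = k·√t`, Korsmeyer–Peppas
`D = k·tⁿ`, Hixson–Crowell `D = 1−(1−k·t)³`, and Peppas–Sahlin
`D = k₁·tᵐ + k₂·t²ᵐ` (m fixed, default 0.43) — ranked by r². The
Peppas–Sahlin fit is decomposed into Fickian and Case II relaxational
contributions, `F = 1/(1 + (k₂/k₁)tᵐ)` and `R/F = (k₂/k₁)tᵐ`, and the
power-law exponent n is mapped to a transport-mechanism label.

**Formulation QC.** Process yield, drug loading DL%, loading efficiency
LE%, drug-per-tablet, and batch uniformity (pass when SE/mean is inside
a percent tolerance).

**PK tablet sizing.** `Ke = 0.693/t½`, elimination rate
`DR_E = Cmax·Ke`, required absorption rate `DR_A = DR_E·V_D` (µg/h),
and — given the measured flux Js — the two-face exchange area
`DR_A/Js` and tablet diameter `2·√(area/2π)` that balance elimination
at the target plasma level.

**Synthetic data.** Seeded generators for permeation runs, release
profiles and calibration points with known ground truth, so every
estimator is covered by parameter-recovery tests.

## Worked example

```python
from buccalkinetics import (
    PermeationSpec, gen_permeation, analyze_permeation,
    ReleaseSpec, gen_release, fit_all_models,
    PKParameters, design_dosage,
)

exp = gen_permeation(PermeationSpec(seed=7))   # 6 replicates, 30-min sampling
res = analyze_permeation(exp)
print(f"Js  = {res.js_ug_cm2_h:.2f} +/- {res.js_se:.2f} ug/cm^2/h")
print(f"Kp  = {res.kp_cm_h:.5f} cm/h")
print(f"lag = {res.t_lag_min:.0f} min   (r^2 = {res.r2:.4f})")

best = fit_all_models(gen_release(ReleaseSpec(seed=7)))[0]
print(f"best model: {best.model}  k={best.params['k']:.3f} "
      f"n={best.params['n']:.3f}  r^2={best.r2:.3f}")

d = design_dosage(PKParameters(cmax_ng_ml=12.1, t_half_h=4.4, vd_l=110.1),
                  js_ug_cm2_h=res.js_ug_cm2_h)
print(f"target DR_A = {d.dr_a_target_ug_h:.0f} ug/h -> "
      f"area {d.required_area_report_cm2} cm^2, "
      f"diameter {d.required_diameter_report_cm} cm")
```

prints

```
Js  = 20.79 +/- 0.19 ug/cm^2/h
Kp  = 0.00416 cm/h
lag = 32 min   (r^2 = 0.9968)
best model: korsmeyer_peppas  k=0.254 n=0.353  r^2=0.998
target DR_A = 210 ug/h -> area 10.1 cm^2, diameter 2.54 cm
```

The synthetic run was generated with true flux 21 µg·cm⁻²·h⁻¹ and a
30-minute lag at a 5 mg/mL donor concentration: the estimated flux
(20.79), permeability (0.00416 ≈ 21/5000 cm/h) and lag (32 min) recover
the truth within replicate noise. The release profile was generated
from a power law (k = 0.257, n = 0.350), which the model ranking
correctly identifies; n < 0.5 indicates diffusion-dominated transport.
The sizing chain says a tablet delivering the estimated flux needs
about 10 cm² of two-face contact area (2.5 cm diameter) to hold the
target plasma level of a 12.1 ng/mL Cmax drug with a 4.4 h half-life.

A command-line interface mirrors the library:

```bash
buccalkinetics simulate permeation --seed 7 --out perm.csv --truth-out truth.json
buccalkinetics permeation --data perm.csv --cd 5 --out report.json
buccalkinetics pkdesign --config pk.yaml --out sizing.json
```

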