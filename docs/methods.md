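# Methods

This note documents the models implemented in `buccalkinetics`, the
numerical choices behind them, what the synthetic-data generators do
and do not emulate, and the known limitations.

## Franz-cell permeation model

A vertical Franz diffusion cell exposes an excised mucosal membrane of
area `A` to a donor solution of concentration `Cd`; drug diffusing into
the stirred acceptor chamber (volume `V_acc`) is sampled at fixed
intervals, each aliquot (`V_smp`) replaced with fresh fluid to maintain
sink conditions.

**Sampling correction.** Each withdrawal removes drug, so the cumulative
permeated amount is reconstructed as

    Q(t_n) = V_acc * C_n + V_smp * sum_{i<n} C_i,

the standard replacement-dilution correction. A `sampling_corrected`
flag bypasses it for pre-corrected data. Defaults (`V_acc` 15 mL,
`V_smp` 0.5 mL, `A` 0.636 cm²) are typical 9-mm-orifice cell values.

**Steady-state flux and lag.** In the quasi-steady-state regime Q/A is
linear in time; `Js` is its slope (µg·cm⁻²·h⁻¹) and the x-intercept,
converted to minutes, is reported as `t_lag` — read here as the time to
establish steady-state flux, not first appearance of drug. The
regression runs on the replicate-mean profile; the SE of `Js` comes
from per-replicate slopes (the pooling scheme is a package choice; the
alternative, pooled-point regression, gives the same slope for balanced
data but a model-based SE).

**Window selection.** How "the linear portion" is chosen is usually left
unstated in experimental reports, so the package makes it explicit and
testable: candidate windows are every contiguous run of points ending
at the final timepoint with length ≥ max(4, ⌈n/2⌉); windows with a
non-positive slope are discarded; the window with the highest r² wins,
with r² compared at 1e−9 resolution so numerically tied windows resolve
to the longer one. The half-length floor matters: in simulation an
unconstrained max-r² search over all end-anchored windows is biased
upward by about 1% of Js (short late windows whose noise happens to
tilt the slope up also score high on r²), while the constrained rule is
unbiased within two standard errors over 200 simulated runs. A
non-negative intercept (within a scale-aware 1e−9 tolerance) reports
`t_lag = 0` with `lag_detected = False`.

**Derived parameters.** `Kp = Js/Cd` (Cd converted mg/mL → µg/cm³, so
Kp is in cm/h), `De = Q_T/A`, `Ac = De/Cd`. These identities are exact
by construction and asserted as unit-consistency invariants. Kp should
be concentration-independent; the intrinsic permeability is the
mean ± SE of Kp over user-selected donor levels, excluding levels where
too little drug was applied to establish steady flow or where the
membrane saturated. Saturation is flagged mechanically: a donor level
whose response rose by less than a relative threshold (default 5%) over
the previous level despite the higher concentration.

## Release kinetics

Dose-fraction profiles (D in [0, 1], time in **minutes** — the printed
rate constants of matrix-tablet studies are only dimensionally
consistent with minutes) are truncated at 90% released (keeping the
first point beyond the cutoff) and fitted by least squares on D
directly, no linearising transform, to six semi-empirical models:

| model | form | free params |
|---|---|---|
| zero order | D = k·t | k |
| first order | D = 1 − e^(−k·t) | k |
| Higuchi | D = k·t^0.5 | k |
| Korsmeyer–Peppas | D = k·tⁿ | k, n |
| Hixson–Crowell | D = 1 − (1 − k·t)³ | k |
| Peppas–Sahlin | D = k₁·tᵐ + k₂·t²ᵐ | k₁, k₂ (m fixed) |

The first-order model is implemented with a negative exponent and the
rate reported positive — the only sign convention under which the curve
approaches its asymptote of 1 from below, matching release data.

Models linear in their parameters (zero order, Higuchi, Peppas–Sahlin
with fixed m) are solved exactly by the normal equations, with SEs from
s²(XᵀX)⁻¹. The nonlinear models use bounded Levenberg–Marquardt /
trust-region least squares (`scipy.optimize.curve_fit`, tolerances
1e−12) multi-started from five deterministic log-spaced rate guesses;
rate constants are bounded positive, the power-law exponent n is
unconstrained. Optimiser failure is reported as `converged = False`
with the diagnostic message — never as silent NaN. r² is defined as
1 − SS_res/SS_tot about the data mean and may be negative for a bad
model; rankings sort converged fits by descending r², break ties toward
fewer parameters, and list non-converged fits last. Because the power
law nests both Higuchi (n = 0.5) and zero order (n = 1), its
least-squares r² can never fall below theirs; this dominance is a test
invariant.

**Mechanistic decomposition.** The Peppas–Sahlin model separates a
Fickian diffusion term (k₁) from a Case II relaxation/erosion term
(k₂). The Fickian fraction and the relaxational/Fickian ratio,

    F(t) = 1 / (1 + (k2/k1) * t^m),    R/F(t) = (k2/k1) * t^m,

satisfy F·(1 + R/F) = 1 identically (a 1e−12 test invariant). Fitted
k₂ < 0 — common for inert non-erodible matrices whose relaxational
contribution shrinks — makes R/F negative and F > 1; the series is
computed literally and flagged `outside_unit_range`, since the usual
contributions-in-[0, 1] reading does not apply. The exponent m is a
user parameter (default 0.43, appropriate for the flat-cylinder aspect
ratios around 6–7 produced by the companion `aspect_ratio` helper); the
literature lookup from aspect ratio to m is deliberately not
reproduced.

**Transport classification.** n < 0.5 → diffusion-dominated
(sub-Fickian/anomalous); n = 0.5 → Fickian (Higuchi); 0.5 < n < 1 →
anomalous; n ≥ 1 → Case II or super Case II. Equality is tested at
1e−9.

## Quantification and stability

Calibration lines (absorbance vs mg/mL) are ordinary least squares via
`scipy.stats.linregress`; inversion is analytic, with readings outside
the validated linear range returned flagged rather than rejected.
`CalibrationSet` holds several curves per medium (the common
two-ranges-per-solvent practice) and selects by which linear range
contains the candidate concentration, overlaps resolving to the
lower-range curve — a package choice, since no standard switching rule
exists. Stability screening normalises a concentration series to its
first point (defined as 100%) and flags every timepoint deviating more
than a band (default ±15%) — per timepoint, not on the mean, so a
single excursion fails even if the average is stable. The report is
scale-invariant in the input concentrations.

## Formulation quality metrics

Yield% = 100·recovered/starting mass (recovery above 105% rejected as a
weighing error); DL% = 100·drug/powder mass; LE% = 100·DL%_measured /
DL%_theoretical with the theoretical value defaulting to the
composition map's drug entry; drug-per-tablet = DL%·weight. Batch
uniformity passes when SE/mean ≤ tolerance (default 10%), with an RSD
switch for pharmacopoeial-style checks. Note that drug-per-tablet
derived from DL% × mean weight can differ from directly assayed
per-tablet content when the two are measured on different sampling
units (powder aliquots vs individual tablets); the package computes the
derived quantity and leaves reconciliation to the analyst.

## PK sizing chain

`Ke = 0.693/t½` uses the conventional rounded constant so derived
rates match published PK tables digit for digit; `exact_ln2=True`
switches to ln 2. `DR_E = Cmax·Ke` (ng·mL⁻¹·h⁻¹) is the elimination
rate at the target concentration and `DR_A = DR_E·V_D` the absorption
rate needed to balance it — numerically in µg/h, because the mL→L and
ng→µg factors cancel. With flux Js, the required two-face exchange area
is `DR_A/Js` and the diameter `2·√(area/2π)`; tablet thickness is
neglected (lateral surface ≪ faces at aspect ratios ≫ 1). Saliva
volume and the drug-enriched saliva film are ignored, so sized areas
are conservative (under)estimates of delivery.

Rounding for table parity is centralised: DR_A is rounded to 3
significant figures before sizing, areas and diameters to 2 dp, and the
tested tablet's delivery rate is computed on its 2-dp-rounded area —
the convention under which published sizing tables are internally
consistent. Raw unrounded values are always carried alongside.
First-order (delta-method) SEs are propagated from Cmax, t½, V_D and Js
when supplied: relative variances add along the product chain. The
chain is a pure function: identical inputs give identical reports.

## Synthetic data generators

Each generator is a pure function of its spec (seed included) using
`numpy.random.default_rng`, so outputs are bit-identical across calls.
Noise is additive Gaussian on the measured signal — acceptor
concentration, dose fraction, absorbance — truncated at zero; the
simplest observational model, chosen because no richer error model is
identifiable from summary data.

* **Permeation**: cumulative truth Q/A(t) = Js·max(0, t − t_lag),
  optionally with a saturable Michaelis-type flux
  Js(Cd) = Jmax·Cd/(Km + Cd); acceptor concentrations are obtained by
  inverting the sampling correction, so zero-noise data round-trip
  exactly. Defaults: 6 replicates, samples every 30 min for 6 h, donor
  5 mg/mL, Js 21 µg·cm⁻²·h⁻¹, 30 min lag, noise sd 0.23 µg/mL — the
  concentration equivalent of a UV assay absorbance SE of 0.009 at a
  slope of 39.13 abs/(mg/mL).
* **Release**: D(t) from any of the six model families, clipped to
  [0, 1] before noise. Defaults: power-law truth (k = 0.25748,
  n = 0.34963), 13 timepoints up to the 40-min 90%-release time, noise
  sd 0.01 on the dose fraction.
* **Calibration**: evenly spaced concentrations on a stated line.
  Defaults: slope 39.13, intercept 0.0052 over 0.0006–0.0240 mg/mL,
  noise sd 0.009 absorbance.

The piecewise-linear permeation truth is deliberate: the analysis only
ever estimates a slope and an intercept, so solving a diffusion PDE
would add no testable surface. Consequently the generators do **not**
emulate donor depletion, back-diffusion as sink conditions degrade,
membrane-to-membrane biological variability (noise is i.i.d. across
replicates), curvature in the approach to steady state, or correlated
assay drift — so passing recovery tests demonstrates estimator
correctness under the stated observation model, not robustness to those
real-data features.

Simulation-study sizes (200 seeds for the recovery/bias checks, 13- or
12-point series, 6 replicates) match the estimators' intended use on
desk-scale experimental series and keep the full suite runtime in
seconds.

## Known limitations

* The steady-state analysis assumes sink conditions and a linear
  regime; it does not model donor depletion or estimate partition
  coefficients.
* Release fits use the replicate-mean profile; replicate-pooled fitting
  would change SEs but not point estimates for balanced designs.
* The Hixson–Crowell form is only monotone for k·t ≤ 1; the fitter does
  not forbid larger products, it simply fits worse there.
* The PK chain targets Cmax as a constant plasma level — a speculative
  steady-state construction, not a compartmental simulation; no
  absorption lag, saliva loss, or swallowed fraction is modelled.
* Uncertainty propagation is first-order only and assumes independent
  errors in Cmax, t½, V_D and Js.
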