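# Methods

## Scope and model

`inkflow` models one thing: the width *d* of a hydrogel strand deposited by
a pneumatic extrusion bioprinter, as a function of the ink's power-law
rheology (n, η), the nozzle geometry (inner diameter D, length L), the
gauge pressure ΔP and the stage speed v̇. The nozzle is treated as a
capillary rheometer die:

1. fully developed laminar flow gives the wall shear stress
   τ_w = D·ΔP/(4L);
2. the Rabinowitsch–Mooney correction converts the volumetric flow rate Q̇
   to the wall shear rate of a power-law fluid,
   γ̇_w = ((3n+1)/4n)·32Q̇/(πD³);
3. mass conservation of a strand of constant circular cross-section moving
   with the stage gives Q̇ = πd²v̇/4;
4. the constitutive closure τ_w = η·γ̇_w ties the chain together.

Eliminating the intermediate quantities yields
d² = (D⁴/(32ηLv̇))·(4n/(3n+1))·ΔP, which the package also solves for ΔP and
for v̇ (inverse process design). The closure identity τ_w = η·γ̇_w holds
algebraically at the predicted width and is asserted as a property test.

### Assumptions (the model's contract)

No slip at the wall; incompressible ink; steady laminar flow; constant
strand cross-section equal to the printed line width; entrance/exit and
barrel pressure losses negligible, so ΔP is the full gauge pressure across
the length L. Not modelled: die swell, surface-tension droplet breakup of
discontinuous strands, thermal sol–gel transition of thermo-responsive
gels, post-deposition spreading or swelling, and any continuity criterion —
continuity is a data label, never predicted.

### The viscosity parameter

η enters the prediction as a *constant* apparent viscosity (its value at
the reference shear rate γ₀ = 1 s⁻¹), not re-evaluated at the wall shear
rate. This matches how the constants are used for verification and keeps
the forward model closed-form; a self-consistent variable-viscosity mode
would change d by the factor γ̇_w^((1−n)/2) and is deliberately out of
scope. Consequence: predictions at wall shear rates far from 1 s⁻¹ inherit
the full shear-thinning error, part of why measured widths at low speed
deviate most.

## Rheology fitting

`fit_power_law` is unweighted OLS of log₁₀η on log₁₀γ̇ (the base cancels in
the slope; the intercept is back-transformed), via `scipy.stats.linregress`.
n = slope + 1, η₀ = 10^intercept. Standard errors of slope and intercept
are reported when more than two points are fitted. Choices:

* **Window.** Default is the full curve. Real flow sweeps bend away from
  the power law at the extremes, so the window is user-facing
  (`--window-max 1500` restricts to the quasi-linear region typical of a
  cone-plate sweep of a concentrated Pluronic solution).
* **Duplicate shear rates** are legitimate replicates and enter the
  regression as separate points; at least two *distinct* rates are
  required, otherwise `DegenerateFitError`.
* **R² convention.** For a Newtonian (constant-viscosity) curve the
  response has zero variance and R² is undefined; the fit reports 0 rather
  than NaN so the field stays in [0, 1].

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| nozzle registry | 21G→514, 25G→260, 27G→210 | μm | vendor IDs of the blunt needles used in the reference study; user-extensible because gauge→ID varies by vendor |
| nozzle length L | 0.005 | m | measured needle length of those tips |
| ink 24.5 wt % | n=0.0511, η=1.04 | –, Pa·s | fitted constants of 24.5 wt % Pluronic F-127 |
| ink 30 wt % | n=0.1656, η=1.46 | –, Pa·s | fitted constants of 30 wt % Pluronic F-127 |
| reference design | 3 nozzles × {1,2,3}×10⁵ Pa × {0.01,0.02,0.03} m/s | – | the 27-condition factorial of the reference study |
| small-n guard | warn below n = 10⁻⁴ | – | (3n+1)/4n → ∞ amplifies noise; allowed but flagged |

Internal units are strictly SI; μm, cP, bar/kPa and ×10⁵ Pa conversions
happen only in `inkflow.units` at the I/O boundary.

## Measured-width table and comparison

The packaged CSV carries the full factorial for the 24.5 wt % ink: 8 cells
where no strand was dispensed (`not_printed`, excluded from comparison),
11 discontinuous (droplet/defect) strands with measurable widths, and 8
continuous strands. `compare_runs` reports relative error per condition
plus RMSE in μm and mean |relative error| overall and per stage speed —
two complementary metrics, since no single error metric is canonical here.
Whether discontinuous strands belong in the comparison is genuinely
ambiguous (their widths are real measurements but violate the
continuous-strand assumption); `include_discontinuous` exposes the choice
and defaults to True so the whole measured factorial is scored. Over- vs
normal extrusion uses a strict inequality (d > D); a width exactly equal to
the bore is not over-extruded.

## Synthetic data generator

`SyntheticSpec` generates the two inputs with known ground truth:

* flow curves η_i = η₀γ̇_i^(n−1)·exp(ε_i) on a log-spaced grid (default
  10⁻²–1.5×10³ s⁻¹, 50 points — the span of a cone-plate sweep);
* print-run tables whose widths are the model prediction times lognormal
  noise over the reference factorial, all labelled continuous.

Noise is multiplicative lognormal (default σ = 0.05 on both channels):
viscosities and widths are strictly positive and the measured width sd
scales roughly with the mean, which additive Gaussian noise would violate.
One `numpy.random.default_rng(seed)` per call makes outputs bit-identical
under a fixed (spec, seed).

What the generator does *not* emulate: instrument artefacts at the ends of
a flow sweep (inertia, edge fracture), thixotropy, discontinuous-strand
morphology, or any correlation structure across conditions. Passing the
zero-noise pipeline test (generate → fit → predict → compare closes with
zero RMSE) therefore demonstrates internal consistency of the code, not
agreement with wet-lab data; the packaged measured table is what anchors
the model to reality, and there the RMSE is several hundred μm with a
~46 % mean relative error — the model captures the d ∝ D²√ΔP trend, not
per-condition accuracy.

## Numerical choices

* All formulas are closed-form; no iteration, so no tolerances beyond
  float64 roundoff. Scaling-law and round-trip identities hold to ~1e-12
  relative and are tested at that level.
* Domain validation is strict (> 0) everywhere; violations raise
  `DomainError` rather than returning NaN.
* `estimate_viscosity` exploits that d² is linear in 1/η: the least-squares
  estimate is 1/η̂ = ΣC_i d_i²/ΣC_i² with C_i the known per-run geometry
  factor — exact on noiseless model-generated runs.
* Sweep and design enumeration order deterministically by
  (nozzle, speed, pressure) so repeated runs are bit-identical.

## Problem sizes

Property tests use 1000 randomized parameter draws per identity and 200
Monte-Carlo seeds for the fit-bias check (sd of the mean fitted n ≈ 2×10⁻⁴
at σ = 0.05, against a 0.002 tolerance — a ten-fold margin). These sizes
give stable statistics while keeping the whole suite under a few seconds.

## Known limitations

* The constant-η approximation biases predictions where the wall shear
  rate is far from 1 s⁻¹ (always, for strongly shear-thinning inks).
* No correction factor maps the as-extruded diameter to the settled line
  width; spreading, die swell and gelation kinetics are unmodelled.
* The 30 wt % ink ships constants only; no measured-width table exists for
  it in the package, so it supports forward prediction, not comparison.
* Gauge→ID mappings differ across needle vendors; override the registry
  when your tips differ.
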