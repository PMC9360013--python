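# Methods

## Problem setting

The package models a paired measurement study: adolescent daughters and
their mothers each receive transmission optical spectroscopy (OS) of both
breasts, DXA-derived fibroglandular volumes, and — for mothers only —
volumetric mammography. The scientific question the statistics answer is
how well the OS-derived density indices agree with the imaging-derived
ones, within group, after adjusting for age and BMI.

## Forward model

The breast compressed in the measurement cup is treated as a homogeneous
slab of thickness `d` (45/55/65/75 mm for cups A–D). Light transport is the
steady-state diffusion approximation with extrapolated boundaries: an
isotropic point source at depth `z0 = 1/μs′` is mirrored across the
extrapolated boundary planes at `−ze` and `d + ze` with `ze = 2AD`,
`D = 1/(3(μa + μs′))`, `A = 1` (index-matched). The detected signal at
lateral offset ρ on the exit face is the image-source dipole series

    T(ρ) = (1/4π) Σ_m [ h(d − z⁺_m) − h(d − z⁻_m) ],
    h(z) = z (μeff + 1/r) e^(−μeff r) / r²,   r = √(ρ² + z²),

with `z⁺_m = 2m(d + 2ze) + z0`, `z⁻_m = 2m(d + 2ze) − 2ze − z0` and
`μeff = √(3 μa (μa + μs′))`. The series is summed vectorized over enough
mirror orders for ≈ 40 e-foldings of its exponential decay (floor 24
orders), which puts truncation error far below the 1e−9 relative tolerance
the tests demand; the unit tests compare against an independently coded
10,000-term loop.

Assumptions worth keeping in mind: homogeneous tissue (no layering or
lesions), μs′ ≫ μa (valid here: tissue-like μa is 0.002–0.02 mm⁻¹ against
μs′ ≈ 1–2 mm⁻¹), and an index-matched boundary. Because the synthetic-data
generator and the inverse fit share this forward model, parameter-recovery
results measure the inverse machinery, not the fidelity of photon transport
in real breasts.

## Chromophore basis

Tissue absorption is linear in the five chromophore concentrations
(percent of tissue volume): `μa(λ) = Σᵢ cᵢ εᵢ(λ)`, with ε in mm⁻¹ per
percent. The built-in `default_basis()` is a **synthetic,
literature-informed** construction: smooth Gaussian bands placed at the
known near-infrared features (water peak ≈ 975 nm, lipid ≈ 930 nm with a
secondary band ≈ 1040 nm, collagen's broad 910/1020 nm structure, the
deoxy-Hb 760 nm band and visible tail, the oxy/deoxy behaviour around the
800 nm isosbestic region), with magnitudes chosen so typical compositions
give μa of 0.002–0.015 mm⁻¹ across the band. It is not a published
extinction table; users with calibrated ε curves can load them from CSV
(`wavelength_nm, eps_water, eps_lipid, eps_collagen, eps_oxyhb,
eps_deoxyhb`). Basis validation enforces non-negativity and the water
(975–985 nm) and lipid (905–930 nm) local maxima — without those peaks the
usability rules below would be meaningless. `toy_basis()` is a coarse,
well-separated variant used to keep unit tests fast.

## Spectrum usability (QC)

A spectrum is fitted only if it has (i) at least 7 usable wavelengths —
matching the 7 unknowns — (ii) usable data at 985 nm and (iii) usable data
at 905 or 940 nm, the wavelengths that separate the lipid and water
absorption peaks. Each excluded spectrum gets exactly one machine-readable
reason, assigned in that order of precedence (a spectrum with 6 wavelengths
that also lacks 985 nm is logged as "too few"). The filter is pure:
permuting the input never changes the retained set or the reasons.

## Inverse fit

Seven optimizer coordinates per spectrum: water, lipid, collagen (percent),
total hemoglobin, its oxygenated fraction, scattering amplitude and power.
Fitting total Hb plus oxygenated fraction instead of (oxy, deoxy) turns the
joint hemoglobin bound (0.2–1 % on the sum) into a simple box; the only
remaining joint constraint, chromophore sum < 100 %, is handled by a hinge
penalty during optimization plus a final projection toward the lower bounds
that restores feasibility to 1e−9. Bounds: water 4–90 %, lipid 10–95 %,
collagen 1–30 %, total Hb 0.2–1 %, amplitude 0.1–4 mm⁻¹ (quoted at the
800 nm reference wavelength), power 0.05–5.

Residuals are differences of log-signals by default (signals span several
decades across source–detector offsets; a linear-scale option exists).
Optimization is trust-region-reflective least squares on normalized [0,1]
coordinates from `n_starts = 8` Latin-hypercube starting points (seeded,
hence reproducible; start points are pre-projected to satisfy the sum cap).
Termination tolerances are 1e−10 with an iteration cap of 300 function
evaluations per start; a start that hits the cap after driving the RMS
residual below 1e−8 is counted as converged — on noise-free data the
objective approaches zero, where relative decrease tests cannot fire.

Per start the result records the SSE over usable wavelengths, whether the
optimizer converged, and `n_at_bounds`, the number of normalized
coordinates within 1e−6 of 0 or 1 (the oxygenated fraction at 0/1 means one
hemoglobin species at its implicit zero bound). The selected fit is the
smallest-SSE converged candidate with `n_at_bounds ≤ 2`; ties break toward
fewer bound contacts, then lower start index. If no start qualifies the
spectrum is dropped with an explicit failure marker. Accepted fits are
averaged per participant as an unweighted arithmetic mean over all spectra
from both breasts (spectrum-weighted, not breast-weighted, matching the
protocol's "average over all usable spectra"); indices are computed from
the averaged parameters, not per spectrum.

## Density indices

- `%BDI = (collagen + water)/(collagen + water + lipid) × 100`. The
  protocol prints this formula with ambiguous bracketing; the ratio reading
  is the only dimensionally sensible one and is scale-invariant in the
  concentrations.
- Optical index `= ln((collagen + water) · power)/lipid`, natural log,
  concentrations in percent units. Evaluated at the daughters' group means
  (water 17.2, collagen 21.3, lipid 46.0, power 1.3) this gives 0.085,
  consistent in magnitude with the published group mean (0.12) — exact
  equality is not expected because a mean of per-person ratios is not the
  ratio of means. Log base and unit convention are configurable.
- `%FGV`/`%MBD` are computed per breast side (dense volume / total volume
  × 100) and then averaged over the two sides; `AFGV`/`AMBD` are the mean
  per-side dense volumes in cm³.

## Statistics

Group contrasts use the pooled-variance Student t-test (df = n₁ + n₂ − 2);
Welch is available but pooled recomputation reproduces the published
p-values from the printed summaries at their printed precision, up to the
rounding already present in those summaries. Familial resemblance is the
Pearson correlation across complete mother–daughter pairs. Device agreement
is the partial correlation given age and BMI by the residual method: both
measures are regressed on the covariates (with intercept) by least squares
and the residuals correlated; p comes from t = r√(df/(1−r²)) with
df = n − 2 − k. Measures are standardized to mean 0, SD 1 before
comparison; the influential-point sensitivity removes observations with
|z| > 2 on either measure (z from the full sample, one pass, covariates not
screened) and refits. All tests are two-sided at α = 0.05, complete-case
per comparison, with no multiple-testing adjustment. Mammographic cells for
daughters are reported NA.

## Synthetic cohort

The generator encodes the study conditions; its defaults are the published
group summaries (daughters n = 42 / mothers n = 39): %BDI 46.0 (9.8) vs
38.9 (9.1), age 15.1 ± 0.6 (range 14.0–16.3) vs 47.5 ± 7.1 (36.9–61.2),
BMI 24.2 ± 5.1 vs 30.7 ± 6.3, %FGV 45.2 (15.4) vs 31.6 (9.9), %MBD 7.3
(4.1) mothers only, AFGV 219.1 vs 245.6 cm³, hemoglobin 0.61/0.58 %,
amplitude 1.7/1.6 mm⁻¹, power 1.3/1.4, pair correlation of density 0.32.

Per participant, true density d (the %BDI estimand) is drawn normal with
linear age/BMI confounding (defaults: −0.8 %/BMI unit both groups,
−0.3 %/year for mothers, 0 for daughters — the daughters' age range is too
narrow to carry signal); the residual SD is derived from the group SD and
the truncated-normal covariate variances so the marginal SD stays at its
anchor. The composition is then constructed to make d exact: lipid takes
`(1 − d/100)` of the water+lipid+collagen total (≈ 85 %, SD 3), water and
collagen split the dense share ≈ 45:55 with jitter. Hemoglobin, its
oxygenated fraction (0.70 ± 0.08), amplitude and power are independent
truncated normals. Mother–daughter dependence is a single shared latent
factor whose correlation is calibrated so the *marginal* density
correlation equals the configured value (unbiased: 0.324 measured at
50,000 pairs for a 0.32 setting).

Spectra: up to 12 per breast (6 offsets × 2 positions), with independent
per-wavelength Bernoulli dropout (default 0.3 — in the source study the
majority of captured spectra failed the wavelength-availability rules, and
the default produces a comparable mix) and multiplicative log-normal noise
`exp(σZ)` with σ = 0.01 by default (CV ≈ 1 %; detector signals are
positive, and no within-protocol noise model is published, so σ is exposed
as a free parameter). The 16-wavelength default grid spans 650–1060 nm and
contains 905, 940 and 985 nm.

Imaging: person-level %FGV (and %MBD for mothers) are affine in d with
Gaussian noise; default slopes/intercepts/noise SDs are solved from the
anchor means and SDs above. Left/right values share the person-level value
plus jitter sized to a configurable left–right correlation (default 0.95).
Per-side fibroglandular/dense volumes are the percent measure applied to
log-normal per-side breast volumes (means 485/777 cm³ chosen so mean AFGV
matches its anchors), which guarantees dense ≤ total volume. AMBD is
emergent rather than anchored (≈ 57 cm³ vs the published 64.3 cm³) — the
generator anchors the percent scale and the volume scale, not their
product. `with_conditional_fgv_correlation(ρ)` re-derives the %FGV noise SD
(fixed-point in the side jitter) so that corr(%FGV, d | age, BMI) equals ρ
exactly; ρ = 0 switches the slope off while preserving the group mean.

What the generator does **not** emulate: heterogeneous or layered tissue,
instrument drift, menstrual-cycle and menopausal effects, non-Gaussian
imaging error, or within-participant between-spectrum composition
variability (spectra of one breast differ only by noise/dropout). Passing
recovery tests therefore demonstrate correctness of the inverse and
statistical machinery under the stated generative model, not performance on
real patient data.

## Numerical choices and problem sizes

- Optimizer tolerance 1e−10, 300-evaluation cap, 8 starts; "at bounds"
  means within 1e−6 in normalized coordinates; sum-cap feasibility 1e−9.
- QC wavelength matching uses a 0.5 nm tolerance on the grid values.
- Recovery exercises use 50 spectra (noise-free and 1 % noise), the
  fit-vs-grid oracle 20 instances of a 41 × 41 grid, estimand recovery 200
  cohorts of 42 pairs, and type-I calibration 2,000 cohorts of 39 pairs —
  sizes at which the Monte-Carlo error is a small fraction of each
  acceptance tolerance while the whole suite stays desk-scale.
- Degenerate inputs fail loudly: constant vectors cannot be standardized,
  zero pooled variance with unequal means is an error (equal means gives
  p = 1 by convention), collinear covariates raise, and a participant with
  zero accepted fits is flagged rather than silently dropped.

## Known limitations

- The forward model is an analytic diffusion approximation, not
  Monte-Carlo photon transport; absolute signal levels are representative
  only, and the extrapolated-boundary treatment is approximate at the
  shortest offsets and thinnest slabs.
- The synthetic chromophore basis reproduces spectral geometry, not
  calibrated extinction values; fitted concentrations are exact only with
  respect to the basis used.
- The published headline correlations (e.g. device agreement r_partial of
  0.46/0.60) derive from unavailable participant data and are not
  reproduction targets; the pipeline instead demonstrates that it recovers
  *known* effect sizes under its own generative model.
- The percent-to-µM hemoglobin conversion implied by the protocol's
  "0.2–1 % (4.9–23 µM)" is not constant (24.5 vs 23 µM/%); the package
  works in percent throughout and treats any µM reporting as approximate at
  23 µM per percent.
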