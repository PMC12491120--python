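# Methods

## Kinetic model and its assumptions

The central quantity is the non-displaceable binding potential BP_ND of a
PSMA-avid lesion, estimated with the simplified reference tissue model
(SRTM). SRTM assumes (i) a reference region devoid of specific binding
whose non-displaceable distribution volume equals the target's, (ii)
target kinetics well approximated by one apparent tissue compartment, and
(iii) negligible blood-volume contribution. Under these assumptions

    C_T(t) = R1 · C_R(t) + (k2 − R1·k2a) · (C_R ⊗ e^{−k2a t}),
    k2a = k2 / (1 + BP_ND),

with R1 the delivery ratio K1/K1′ (unitless), k2 the target efflux rate
(/min) and BP_ND unitless. The classic 3-parameter form is used; no
vascular term is added.

**Fitting.** Weighted least squares by Levenberg–Marquardt on the
transformed parameters (R1, log k2, log(1+BP_ND)), which makes the
positivity constraints structural rather than bound-handled. Three fixed
starting points — (R1, k2, BP_ND) = (1, 0.1, 1), (0.5, 0.3, 0.3),
(1.5, 0.05, 3) — guard against local minima; the best converged solution is
returned together with the number of starts used, Jacobian-based standard
errors (delta method back to the natural scale) and the weighted residual
sum of squares. Objective tolerance 1e−8. If no start converges the fit is
returned with NaN estimates and a `converged=False` flag rather than raising.

**Weights.** "Frame duration and counts" weighting is implemented as the
inverse variance of the frame-statistics noise model: w_i ∝ Δt_i /
(max(C_i, 0.05·maxC) · e^{λt_i}), normalized to mean 1. The 5%-of-peak
floor prevents near-empty early frames from dominating. Vendor conventions
vary; this is one concrete, documented reading, and the validation
therefore rests on parameter recovery rather than on matching any
particular software's output.

**Continuous curves from frame data.** PET frames integrate counts, so all
frame values in this package are time-averages over the frame interval,
never point samples. Conversely, when a continuous reference curve must be
reconstructed from frame values for prediction, a piecewise-linear curve
through (0, 0) and the frame mid-times is iteratively corrected until its
own frame averages reproduce the measured values (≤8 fixed-point sweeps).
Without this correction the bolus-rise frames carry ~2% reconstruction
error; with it, model self-consistency is better than 0.1% everywhere above
5% of peak. Internal grids use 0.01-min spacing; exponential convolutions
use the exact piecewise-linear closed form (cumulative trapezoid in the
k → 0 limit).

## Synthetic-data generator

The generator provides ground-truth-known stand-ins for every input the
analysis consumes.

* **Plasma input:** tri-exponential bolus form C_p(t) = (a1(t−τ) − a2 −
  a3)e^{−l1(t−τ)} + a2 e^{−l2(t−τ)} + a3 e^{−l3(t−τ)}, delay τ = 0.5 min,
  classic shape constants scaled to a ~25 kBq/ml peak. This is purely a
  simulation driver — the study design involves no arterial sampling — and
  parameter sets producing negative concentrations are rejected at
  construction.
* **Reference region:** one-tissue kinetics with defaults K1′ = 0.1
  ml/ccm/min, k2′ = 0.12 /min (resting gluteal muscle scale). These and the
  lesion defaults (R1 = 1.2, k2 = 0.3 /min, BP_ND = 2.0) are plausible
  values for PSMA tracers in pelvic tissue chosen for simulation; the study
  this emulates reports no rate constants, so they are explicitly *not*
  measured values.
* **Frame schedule:** 55 frames (15×20 s, 15×40 s, 25×60 s; 2400 s total),
  the dynamic pelvic protocol.
* **Noise:** zero-mean Gaussian per frame with variance ∝ C·e^{λt}/Δt
  (decay-corrected frame statistics), not voxel-level Poisson — adequate at
  ROI scale and keeps inverse-variance weights well defined. "5% frame
  noise" in tests means the scale is calibrated so the median frame-level
  relative SD is 5%.
* **Phantoms:** a spherical lesion (radius 8 mm, 2-mm voxels) carrying the
  lesion TAC, a disjoint reference slab carrying the reference TAC, flat
  background elsewhere; truth masks returned. No scanner physics
  (resolution, scatter, attenuation), so segmentation on the phantom is
  exact by construction — phantom tests validate bookkeeping and
  estimator correctness, not robustness to partial-volume effects.
* **DWI:** mono-exponential signal with Gaussian noise (not Rician);
  justified at the simulated lesion SNR (≥50), where magnitude bias is
  negligible. Default b-values {0, 800} s/mm² — not reported by the study,
  configurable.
* **Cohort:** days {0, 7, 21, 28}; in fold-change space ΔBP_ND% follows a
  cubic polynomial (defaults −5.63, 1.11, −0.03 per day/day²/day³ — the
  group-level longitudinal estimates such studies report), ΔADC% a linear
  slope (+1.66 %/day), ΔSUV% a linear slope (−0.83 %/day), each plus a
  per-patient Gaussian random intercept (SDs 15/8/10 points) and residual
  noise (SDs 20/10/12 points) applied to follow-up visits only; baseline
  fold changes are identically zero by construction. PSA declines
  exponentially (rate 0.077 /day, ≈88% by day 28) with multiplicative
  lognormal noise (σ_log = 0.10) so values stay positive. Absolute values
  are reconstructed from lognormal patient baselines. With heavy noise the
  reconstructed absolute BP_ND can dip below zero; the statistical layer
  operates in fold-change space, where this is harmless.

What the generator does **not** emulate: inter-visit misregistration,
organ motion, partial-volume effects, bladder spill-in, Rician DWI noise,
and lesion-level response heterogeneity beyond random intercepts. Passing
tests therefore demonstrate estimator correctness under the stated models,
not robustness to those real-world effects.

## Image quantification conventions

* Decay correction to injection time uses the exact frame-integrated
  factor e^{λt₀}·(λΔt)/(1 − e^{−λΔt}), λ = ln2 / 67.71 min for Ga-68,
  implemented with expm1 for short-frame stability; images carry a flag and
  double correction is an error.
* Lesion segmentation: threshold = 40% of the maximum voxel inside a
  search sphere around a seed point; the mask is the 6-connected component
  of supra-threshold voxels containing that maximum, restricted to the
  sphere. 6-connectivity is deliberately conservative (avoids diagonal
  leakage toward bladder-like structures). No background-adaptive
  correction is applied; the mask records method, threshold and search
  region as provenance.
* TAC extraction is the unweighted voxel mean per frame; fitting weights
  are attached per the kinetics weighting rule.
* SUV = concentration / (injected dose / body weight), 1 g/ml density.
  SUVpeak searches spheres of exactly 1 ml (radius 6.2035 mm) centred at
  each VOI voxel, membership by voxel-centre inclusion; centring on VOI
  voxels keeps the peak a sub-volume of the lesion (configurable).
* Axis order (x, y, z, frame), 0-based indices, voxel centres at
  (index + ½)·voxel size; frames must be contiguous — gaps are rejected,
  never interpolated.

## ADC estimation

Per-voxel weighted log-linear least squares of ln S on b with weights ∝ S²,
which matches the full nonlinear fit at high SNR while remaining
deterministic (no starting values) — a documented difference from unknown
scanner-console internals. Voxels with any non-positive signal are excluded
and counted. For two b-values the estimator reduces exactly to the
closed-form two-point ADC. Reported in mm²/s.

## Statistical layer

* **Fold change** is 100·(follow-up − baseline)/baseline. The convention is
  chosen so that declines are negative, consistent with how PSA and SUV
  responses are reported; exclusion of PET-negative patients from group
  summaries is explicit configuration, never inferred from the data.
* **Quartiles** use midpoint plotting positions (k − ½)/n with linear
  interpolation (Hazen). This convention reproduces the study's printed
  day-28 upper quartile exactly; its printed lower quartile (−89.6) is not
  reproducible from the tabulated PSA values under any standard convention
  (closest: −89.7, obtained here), almost certainly a rounding artefact in
  the source table — flagged, not forced.
* **Mixed models** are fitted by REML (statsmodels MixedLM) with a random
  intercept per patient (or lesion). Confidence intervals and p-values use
  t statistics on residual degrees of freedom (n_obs − n_fixed) — the
  classical default of the era's tooling, stated as a convention (no
  Satterthwaite). Exact-fit data (zero residual variance) make the REML
  likelihood singular; such fits short-circuit to the OLS closed form with
  zero variance components, which is the analytic limit. Singular fixed
  designs raise an error naming the collinear terms (e.g. a noise-free
  cohort makes ΔADC% exactly proportional to day, so the extended model is
  legitimately unidentifiable there).
* **Model identifiability on the study grid:** with follow-up days
  {7, 21, 28} alone, a cubic in time is saturated; cubic trajectory models
  on the 4-day study grid therefore include the day-0 rows (fold change
  identically 0), matching how an intercept ≈ 0 arises in such analyses.
  Simulation experiments that need a correctly specified follow-up-only fit
  use a five-visit grid (0, 7, 14, 21, 28).
* **Calibration:** across 1000 simulated cohorts (n = 50 patients) the
  nominal 95% CIs of the trajectory coefficients cover the truth ≈96% of
  the time; the REML standard errors are ~3–5% conservative relative to
  the empirical estimator SD in this design. Coverage checks use 1000
  replicates so the Monte-Carlo SE (~0.6%) is small against the 93–97%
  acceptance band.
* **Agreement:** differences d = ΔSUV% − ΔBP_ND% are modelled as d ~ 1 +
  (1|lesion); bias is the intercept and the limits of agreement are bias ±
  1.96·√(σ²_lesion + σ²_residual), so repeated visits of a lesion are not
  treated as independent pairs. If the grouping is degenerate (no
  between-lesion variation) the classical Bland–Altman on pooled
  differences is used.
* **Concordance:** the repeated-measures concordance correlation is
  computed from the balanced two-way variance decomposition of
  value ~ method + subject: ccc = σ²_subject / (σ²_subject + d²/2 +
  σ²_residual) with d the method mean difference; σ²_subject is left
  untruncated so systematic anticorrelation yields a negative coefficient.
  For unreplicated pairs this closed form coincides with Lin's sample CCC,
  which also serves as the reported fallback for degenerate decompositions.
* **PSA trajectory model:** the original analysis's exact specification is
  not fully recoverable; the default reconstruction is ΔPSA% ~ 1 + day +
  (1|patient) on all 8 patients with day-0 rows included and missing visits
  dropped. It estimates −2.17 %/day against a published −1.96 %/day; the
  estimate falls inside the published 95% CI (−2.58, −1.34), and the
  discrepancy is reported rather than tuned away. Alternative
  reconstructions (excluding day-0 rows, excluding the PET-negative
  patient, random slopes) give −1.57 to −2.23 %/day.

## Numerical and design choices

* All simulators are bit-reproducible given a seed; the pipeline stamps
  every output with the global seed and a hash of the configuration
  (excluding the output path).
* Problem sizes in tests and the acceptance script — 200 noisy SRTM
  replicates, 200 ADC replicate sets, 1000 coverage cohorts, 20
  grid-oracle instances — were chosen to keep Monte-Carlo error well below
  the tolerances being asserted.
* The SRTM test oracle exploits the model's conditional linearity: with
  k2a fixed, (R1, k2) solve in closed form, so a dense 1-D profile grid
  over log k2a is a genuinely global optimizer to compare the
  Levenberg–Marquardt fit against. It exists only in the test suite; the
  public API deliberately exposes a single estimator.

## Known limitations

* SRTM assumptions themselves (shared non-displaceable volume, one-tissue
  target) are taken as given; model mis-specification bias is not studied.
* No registration, motion correction or partial-volume correction — VOIs
  are assumed aligned upstream; the DWI VOI is assumed resampled by
  nearest-neighbour.
* The agreement and extended-model analyses on an 8-patient cohort are
  illustrative of the method, not powered inference; per-lesion imaging
  values of the original study are shown only in its figures, so its
  imaging-level tables cannot be reproduced numerically and are covered by
  property-based surrogates instead.
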