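# Methods

## Scope and data model

The package quantifies ellipsoid-zone (EZ) integrity from layer-segmented
OCT macular cubes and relates it to visual acuity at cohort level. Inputs
are per-eye segmentation surfaces — internal limiting membrane (ILM), EZ,
retinal pigment epithelium (RPE) and Bruch's membrane (BM) — sampled on an
en-face lattice of `n_bscans × n_ascans` columns over a
`width_mm × height_mm` footprint (defaults 128 × 512 over 6 × 6 mm, axial
sampling 1.955 µm/px over 1024 px), an optional 8-bit intensity volume,
and a visit table (patient/eye IDs, visit year, acuity, GA and phakic
status). Segmentation itself is out of scope; surfaces are inputs.

Conventions: depths in µm increase downward from the top of the B-scan;
column `(b, a)` owns the half-open footprint cell
`[a·dx,(a+1)·dx) × [b·dy,(b+1)·dy)` mm; an absent EZ is NaN in memory and
the `NA` sentinel on disk. Anatomical ordering ILM ≤ EZ ≤ RPE ≤ BM is
enforced on construction; violations up to 2 µm are treated as
segmentation jitter and clamped (the deeper surface is pulled up to the
shallower one), larger violations are rejected as corrupt. An intensity
volume is stored 0–255 with 255 = maximum brightness; conceptually the
top of the scale is pure white.

## Metric definitions

* **EZ-RPE thickness** per column: `max(0, z_RPE − z_EZ)` µm; absent EZ
  → 0 µm. Treating absence as zero thickness keeps the two loss
  conventions consistent: total attenuation is defined by zero thickness,
  and absent-EZ columns carry intensity 0.
* **Regions**: central subfield (1 mm diameter circle), central macula
  (2 mm), panmacular (all columns), centered on the fovea (default: the
  geometric cube center; overridable for decentered scans). A column
  belongs to a circular region iff its footprint center lies inside the
  circle — no partial-area weighting. The discretization error of this
  rule is bounded and tested (central-subfield area within 3 % of
  π·0.25 mm² on the 512 × 128 lattice).
* **Partial / total EZ attenuation**: percentage of regional columns with
  thickness ≤ 20 µm / ≤ 0 µm. Total ≤ partial by construction.
* **Mean regional thickness** (CST / CMT) is the unweighted column mean
  (columns have equal area, so this equals the area-weighted mean); the
  foveal-point value is the single column containing the fovea center.
* **Panmacular volume**: Σ thickness(µm)·10⁻³ · dx·dy mm³, algebraically
  identical to panmacular mean thickness (mm) × footprint area.
* **EZ intensity**: per column, the maximum voxel value within ±2 axial
  pixels of the EZ surface (max-pooling absorbs ±1 px segmentation
  jitter; window configurable). RPE intensity is sampled identically.
  Absent EZ → intensity 0.
* **EZ intensity index**: per column `I_EZ · (I_EZ / I_RPE)`, defined 0
  where `I_RPE = 0` (a shadowed column carries no normalizable signal),
  then averaged over the region. Forming the index per column and then
  averaging is the default; the variant built from regional mean
  intensities is also available (`mode="region_mean"`). Under a uniform
  per-eye gain g both intensities scale by g, so the ratio `I_EZ/I_RPE`
  is invariant and the index scales by exactly g — this is the algebraic
  property that motivates RPE normalization, and it is tested.

## Visual acuity

Snellen fractions convert by `logMAR = log10(D/N)` and
`letters = round(85 − 50·logMAR)` (half away from zero); the identity
reproduces 20/20 → 85, 20/25 → 80, 20/32 → 75, 20/40 → 70. One ETDRS line
is 5 letters everywhere. Cross-sectional groups: excellent ≥ 80 letters,
worse ≤ 70, the band between is excluded from subgroup comparisons.
Longitudinal change groups between two visits: loss ≥ 10 letters
(≥ 2 lines) vs loss < 5 letters (improvement included); 5–9 letters is an
unassigned band. A restricted longitudinal contrast conditions on
excellent baseline acuity and compares eyes that fall to the worse band
against eyes that stay excellent.

## Cohort statistics

Two eyes of one patient share unmeasured patient-level factors, so group
contrasts use the two-level random-intercept model
`y = β₀ + β₁·group + u_patient + ε`, `u ~ N(0, σ²_u)`, `ε ~ N(0, σ²_ε)`,
fitted by restricted maximum likelihood. The implementation profiles the
single variance ratio λ = σ²_u/σ²_ε: for fixed λ the block covariance
`I + λJ` inverts in closed form (Woodbury), every GLS cross-product
reduces to per-patient sufficient statistics, and the profiled REML
criterion is minimized over log λ by bounded scalar search with an
explicit λ → 0 boundary check. The fixed-effect p-value is a Wald z test
on β₁ (swappable design; no multiple-testing correction is applied, and
per-metric p-values are reported as-is). The implementation reproduces R
`lme4::lmer` estimates, standard errors and variance components to the
precision lmer prints; in the independent-eyes limit it reduces exactly
to the closed-form two-sample analysis.

Structure–function associations are Pearson correlations (two-sided p
from the t transform, n−2 df) over all eyes of a stratum; the GA × acuity
table uses the Pearson chi-square without continuity correction (Fisher's
exact available by flag). Report builders emit one row per
(metric, region) for three strata — all eyes, foveal GA, no GA — and
flag, rather than fail on, empty groups. Eyes with extrafoveal GA form no
stratum of their own; they contribute to "all eyes" only.

## Synthetic cohort generator

The generator exists so every pipeline stage is testable without patient
data; its defaults emulate the structure of a dry-AMD cohort of ~116 eyes
(80 patients, second-eye probability 0.45) followed at years 0 and 5.

Per eye: a smooth base EZ-RPE thickness field (six-component random
cosine mixture rescaled to mean 33 µm, sd 4 µm), 0–8 drusen (parabolic
local compressions, radius 0.05–0.2 mm, peak reduction 10–25 µm, floored
at 1 µm so drusen thin but never abolish the band), and with probability
0.33 a GA disc that zeroes thickness and removes the EZ surface. GA
involves the fovea with probability 0.84 (center within 0.35 mm of the
fovea, radius 0.3–1.5 mm) and is otherwise peripheral (radius 0.3–0.6 mm
at 1.2–1.8 mm offset); discs grow 0.25 mm/year in radius and are clamped
inside the footprint so that the analytic ground truth below stays exact.
The intensity volume renders EZ and RPE bands (levels 140 and 180) over
background 30, multiplied by a per-eye gain drawn from 0.8–1.2 (media
clarity), with Gaussian noise (sd 8) and uint8 quantization; both bands
are absent inside GA.

Acuity is drawn from a disclosed linear model,
`letters = 87 − 0.35·(central-subfield total attenuation %) −
0.6·max(0, 25 − CST µm) + N(0, 3)`, clipped to [0, 100] and rounded.
This is the minimal generative structure that produces the
attenuation–acuity association pattern the pipeline is meant to recover;
it is a modeling choice, fully exposed in `SimConfig`.

Ground truth per eye-visit records lesion geometry, gain, the noiseless
letters, and total-attenuation fractions computed *analytically* from
circle–circle intersection of the GA disc with each region circle
(panmacular: πr²/footprint). Partial attenuation has no closed form under
the smooth field + drusen, so its truth is read from the generated
thickness grid itself. Randomness uses one global seed with per-eye
substreams (`default_rng([seed, eye_index])`), making cohorts
reproducible regardless of generation order.

Default generation runs on a down-scaled 64 × 64-column lattice (256
axial px); the full 512 × 128 lattice is available by flag. Measured
regional attenuation matches analytic truth within 8 percentage points at
64 × 64 (discretization of the column-center rule; ~3 points at
512 × 128) — both bounds are tested.

What the generator does **not** emulate: speckle statistics and
device-specific noise, irregular (non-circular) GA lesion shapes and
multifocal lesions, pseudodrusen, outer-retinal tubulation, fixation
error beyond a fixed fovea-center offset, and wet-AMD features (fluid).
Passing tests therefore demonstrate correctness of the measurement and
statistical machinery under known geometry, not performance on clinical
segmentations.

## Numerical choices

* Letter rounding: nearest integer, half away from zero — deterministic
  and consistent with the standard chart pairings.
* Cohort percentage reporting rounds half away from zero at one decimal
  (computed in decimal arithmetic to avoid binary-float artifacts).
* REML search: log λ bounded in [ln 1e−8, ln 1e8], xatol 1e−10, with an
  explicit boundary comparison at λ ≈ 0; reported p-values are floored at
  the smallest positive double rather than returned as 0.
* Chi-square requires all four marginals positive; degenerate tables in
  pipeline reports are flagged, not fatal.
* Surface TSV serialization uses `repr` floats, so read ∘ write is
  bit-exact and rerenders byte-identically.

## Limitations

* The fovea defaults to the geometric cube center; badly decentered scans
  need an explicit center.
* The foveal-point thickness is a single-column value and correspondingly
  noisy on real data.
* The mixed model supports a single binary fixed effect with a patient
  random intercept — the design used by the cohort contrasts — not
  general fixed-effect designs or random slopes; multivariate adjustment
  is deliberately out of scope.
* Column-center region membership yields a few percentage points of
  discretization error on coarse lattices; use the full lattice when that
  matters.
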