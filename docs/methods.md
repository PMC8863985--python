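# Methods

This note documents the models implemented in `babytract`, the choices
made where the procedures are underdetermined, what the synthetic cohort
does and does not emulate, and the numerical conventions.

## Coordinate conventions

All spatial objects live in continuous RAS millimetres. When inputs are
ACPC aligned, the origin is the anterior commissure; x > 0 is right,
y > 0 anterior, z > 0 superior. Voxel indices are 0-based; a continuous
point belongs to voxel (i, j, k) under the half-open center-of-voxel boxes
[i − 0.5, i + 0.5) in voxel space, which removes boundary ambiguity. TRK
files are normalised to RAS mm on read via their header transform; writing
emits TCK, so there is a single internal space. Hemisphere is encoded in
bundle names (`_L` / `_R`); analyses across hemispheres use |x| so both
hemispheres share one medial→lateral axis.

## Inversion-recovery relaxometry

The magnitude IR signal is modelled as |S(t)| = |a (1 − b e^(−t/T1))|,
with a the initial-magnetisation scale, b the effective inversion
coefficient (2 for perfect inversion) and t the inversion time. The
default schedule is 20 TIs starting at 50 ms with 150 ms spacing. Because
the absolute value creates a null point at t = T1 ln b and local minima on
the wrong side of it, each voxel is fitted with trust-region least squares
from five T1 starts (300, 800, 1500, 2500, 4000 ms), b = 2,
a = max(signal), keeping the best residual. Bounds: T1 ∈ [50, 10000] ms
(generous physiological range at 3 T), b ∈ [1, 2.2], a > 0. A fit is
flagged non-converged when the input is constant/zero (non-identifiable),
the schedule has fewer than three TIs, or more than 5% of the signal
energy is left unexplained; downstream profiling skips invalid voxels, so
the treatment of poorly fitted voxels is explicit rather than silent.
R1 = 1000 / T1[ms] is reported in s⁻¹.

## Bundle segmentation

* **Candidacy.** A streamline is densified to steps of at most half the
  smallest voxel size, and "passes through" a waypoint means a densified
  vertex falls inside a mask voxel. The arc-length positions of first
  contact with the ordered include-waypoints must be monotone in one
  traversal direction; either direction is accepted (storage direction is
  arbitrary) and the matched direction becomes the member's orientation
  flag. Contact with any exclude ROI disqualifies. Exclusion ROIs are
  supported but empty by default.
* **Resolution.** A streamline qualifying for several bundles goes to the
  one with the highest mean probability along its vertices (trilinear
  samples of the bundle's probability map). The mean, rather than the
  maximum, is robust to single-voxel peaks. Exact ties go to the
  lexicographically first bundle name, deterministically, with a logged
  warning. Resolution runs before cleaning.
* **Cleaning.** Members are resampled to 100 nodes; per node the mean and
  sample covariance over members define a gaussian; a member's distance is
  the mean over nodes of its Mahalanobis distance, and members beyond 4 SD
  are dropped. Covariances are regularised by adding (0.1 mm)² to the
  diagonal so near-parallel bundles never produce a singular matrix.
  Because removals shift the core, cleaning iterates (up to 5 rounds, or
  until nothing is removed); bundles with fewer than 5 members are
  returned unchanged with a warning.
* **Validation.** Bundles are voxelised (a voxel is set iff ≥1 densified
  vertex falls in it) and compared with the dice coefficient
  DC = 2|A∩B|/(|A|+|B|), defined as 0 (with a warning) when both masks are
  empty.
* **Template ROIs.** Atlas ROIs defined on a template grid are resampled
  to the subject grid through a user-supplied template→subject affine:
  nearest-neighbour for binary masks, trilinear for probability maps. The
  shipped default atlas is the phantom's own; real infant-template ROIs
  are consumed as user-supplied NIfTI inputs, not redistributed.

## Tract profiles

Members are reoriented using their candidacy flags so node 1 lies at the
order-1-waypoint end, resampled to 100 equidistant nodes (piecewise-linear
arc-length interpolation; node k sits at arc fraction (k−1)/99), and the
per-node mean position defines the bundle core. Scalar maps are sampled
trilinearly with validity awareness: in strict mode (default) a sample is
missing whenever any neighbouring voxel with nonzero interpolation weight
is invalid — this is what makes the ventricle mask effective against CSF
partial-volume leakage — while lenient mode renormalises over valid
neighbours. Per node, the profile value is the weighted mean over member
samples; the default gaussian weighting uses exp(−d²/2) with d the
member's Mahalanobis distance to the node distribution, down-weighting
stray trajectories, and a uniform option is the plain mean (both agree
exactly when members coincide, and profiles of constant fields are exactly
constant under either). The weighted SE uses the effective sample size
(Σw)²/Σw². Node indices are 1-based in all outputs.

## Development models

All inference is built on a linear mixed model with a single random
intercept; estimation is REML for reported fits and ML for likelihood-ratio
tests. Because development rates are ~10⁻³ with residual SDs ~10⁻⁵, the
response is standardised internally before optimisation (estimates,
variances and log-likelihoods are transformed back exactly); the
implementation is cross-checked against lme4 in the test suite. R² is
marginal — the squared correlation between the fixed-effects-only
prediction and the response — with the usual
1 − (1 − R²)(n − 1)/(n − p − 1) adjustment; a conditional R² is not
reported.

Stage 1 fits bundle-mean value ~ 1 + age + (1|subject) per bundle (a
model-comparison helper tests random slopes per subject with an LRT
against chi-square, df = 2 for the extra variance and covariance). Stage 2
fits the same model per (bundle, node), giving the development map:
newborn mean, rate, and the average newborn (|x|, y, z) node coordinates.
Stage 3 keeps every 10th node — nodes {10, 20, …, 100}, fixed at the
upper anchor for determinism and exposed as a flag — for spatial
independence, z-scores the coordinates with the sample SD (n − 1), forms
interactions from the z-scored mains, and fits

1. speed-up: slope ~ 1 + newborn + (1|bundle)
2. spatial: slope ~ 1 + |x| + y + z + |x|·y + |x|·z + y·z + (1|bundle)
3. combined: the union,

with an ML likelihood-ratio test of 3 vs 2 (df = 1). Missing node values
are dropped listwise per model; nodes with too few subjects are flagged,
not fatal. Each hemisphere's bundle is its own random-intercept group (24
groups). A robustness refit drops the first and last 10 nodes before
subsampling, checking that effects are not driven by nodes near cortical
gray matter.

## The synthetic cohort

The phantom generates everything the pipeline consumes with exact ground
truth. Its purpose is validation of the machinery, not anatomical realism.

* **Geometry.** 24 bundles as quadratic Bézier arcs (S-shaped bundles get
  a third waypoint) in distinct sectors of a 80³ × 2 mm grid whose centre
  voxel is the commissure-analog origin; the 11 hemispheric families are
  mirror images (x → −x) so the |x| convention is genuinely exercised. A
  built-in validator rejects layouts whose centerlines approach closer
  than 13 mm (tubes would overlap). Streamlines are the centerline plus a
  constant gaussian offset (SD 1 mm) and a small smooth wiggle; half are
  stored reversed to exercise orientation handling. 500 random curved
  distractor segments test specificity. Waypoints are 6 mm half-width
  boxes at arc fractions 0.25/0.75 (plus 0.5 for curvy bundles);
  probability maps are gaussian kernels (4 mm) of centerline distance.
* **Newborn fields.** Per-bundle newborn R1 means are painted on 6 mm
  tubes with a small smooth zero-mean texture (SD 0.003 s⁻¹). The 24
  values average exactly 0.46 s⁻¹ and span 0.42–0.55 s⁻¹, with projection
  bundles (CS, ATR) highest and FcMi/IFOF lowest. MD mirrors R1
  (anticorrelated means around 1.2 × 10⁻³ mm²/s).
* **Development.** The voxel-wise rate field is the combined model itself:
  rate = γ₀ + γ·(z-scored |x|, y, z and interactions) + λ·(newborn − mean),
  with γ₀ = 0.16/180 s⁻¹ per day, γ = (4.19e-5, −1.10e-4, 1.68e-4) for the
  mains, (−4.74e-5, 0, 1.05e-4) for |x|·y, |x|·z, y·z, and λ = −0.003 per
  day. The |x|·z coefficient is generated as 0 (no reliable reference
  value). z-scoring uses the bundle node coordinates with equal per-bundle
  weight, and the interaction regressors are mean-centred over those
  nodes; this pins the bundle-averaged rate at exactly γ₀, which is what
  makes the grand-mean calibration below exact rather than approximate
  (coordinate correlations would otherwise shift the grand mean by up to
  ~0.01 s⁻¹ over 180 days).
* **Cohort and calibration.** 13 subjects, 29 sessions (9 newborn, 10 +
  10 at three and six months; six subjects attend all three timepoints).
  Ages are drawn from 8–12, 88–102 and 185–195 days so the newborn→6-month
  mean gap is 180 days, and the newborn field is anchored at the mean
  newborn age. This makes the three calibrated quantities mutually
  consistent: newborn grand mean 0.46 s⁻¹, 6-month grand mean 0.62 s⁻¹,
  and mean rate × 180 d = 0.16 s⁻¹ (with wider age windows no single rate
  can satisfy all three simultaneously). Subject-level random intercepts
  have SD 0.01 s⁻¹; volumes carry Rician noise (SD 0.005 s⁻¹), the
  appropriate noise family for magnitude MR data. A central 8 mm sphere is
  the ventricle analog for exclusion-mask handling. IR series are
  forward-generated from T1 = 1000/R1 with a = 1000, b = 2 plus Rician
  noise.
* **What the phantom does not emulate** — and hence what passing tests do
  not show about real data: realistic bundle shapes, lengths and crossing
  regions (real candidacy and atlas-resolution errors are driven by
  crossings); registration error in template→subject transforms (the
  phantom atlas is already in subject space); partial-volume structure
  beyond the single ventricle blob; B1/slice-profile artefacts in the IR
  model; non-linear growth (generation and models are both linear in age,
  so model misspecification is untested); and between-subject variability
  beyond a global intercept. Dice ≥ 0.95 recovery on the phantom reflects
  the generator's clean separation, not expected performance on real
  infant tractograms.

## Problem sizes in the shipped checks

The test suite exercises reduced cohorts chosen to keep the full run at a
few minutes on one CPU: most fixtures use 8 streamlines per bundle and 40
distractors; the grand-mean round trip uses 15 per bundle with 100
distractors; the 20-seed end-to-end sign-recovery check uses 8 per bundle
with a 12-session cohort; null-calibration simulations use 40–60
replicates. `scripts/acceptance.py` runs the full default cohort (50
streamlines per bundle, 500 distractors, 29 sessions). Statistical
assertions use tolerances derived from their own Monte-Carlo or standard
errors; the grand-mean round trip asserts agreement within 0.01 s⁻¹, and
the systematic allowance of 2 × 10⁻⁵ s⁻¹/day in the per-bundle rate check
accounts for members sampling the rate field ~2 mm off the centerline
where the spatial gradient shifts the true value.

## Known limitations

* The per-node LMM loop is a plain Python loop over statsmodels fits
  (~2400 fits for a full map); adequate here, but a vectorised solver
  would be needed for voxel-wise use.
* `fit_ir_volume` loops voxels serially; fitting a full-resolution brain
  would want chunked parallelism.
* The probabilistic tie-break is applied before cleaning; with heavily
  overlapping real bundles the order could matter.
* The random-slope LRT uses a chi-square(2) reference, which is
  conservative at the variance boundary (the usual chi-bar-square mixture
  would be sharper).
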