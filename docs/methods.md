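# Methods

`tumorad` reimplements, on synthetic data with known ground truth, the
analytical core of a preclinical pharmaco-imaging workflow: longitudinal
tumor-MRI volumetry with exponential growth kinetics, a fixed 39-feature
radiomic panel over a segmented volume of interest (VOI), per-subject
post/baseline feature ratios, and permutation-based group statistics with
false-discovery-rate control. This note records the model, the parameters
that matter, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## Growth kinetics

Tumor growth is modeled as exponential: the rate of volume increase is
proportional to the current volume. Between two imaging timepoints t₁ and
t₂ with volumes V₁ and V₂,

    SGR = 100 · ln(V₂/V₁) / (t₂ − t₁)        [%/day]
    DT  = ln 2 / (SGR/100)                   [days]

SGR is the specific growth rate and DT the volume doubling time. Volumes
come from either of two estimators:

* **caliper / ellipsoid**: three orthogonal diameters — anteroposterior
  (AP), transverse (TS), craniocaudal (CC) — with V = π/6 · AP · TS · CC;
* **VOI**: in-mask voxel count × physical voxel volume from a binary
  segmentation.

DT is reported in the same units regardless of estimator; the %/day
convention for SGR is converted internally so DT = ln 2/SGR holds in
consistent (fractional per-day) units. A non-growing tumor (SGR ≤ 0) has
no doubling time; DT is emitted as NaN, excluded from group statistics
with a logged warning. Day values are accepted as reals although study
designs use integer days.

## The 39-feature radiomic panel

Features are computed in 3D over the VOI in four blocks (the canonical
order is `tumorad.texture.FEATURE_NAMES`):

* **Primary (11)** — Deviation, Mean, Max, Min, Sum, Volume, Max.
  Diameter, Entropy, Size Variance, Intensity Variance, Kurtosis.
  Deviation, Intensity Variance and Kurtosis are population moments of the
  raw in-mask intensities (Kurtosis is the Pearson, non-excess, m₄/m₂²
  form; NaN for a zero-variance VOI). Entropy is Shannon entropy in bits
  of the discretized-level histogram. Size Variance is the population
  variance of GLSZM zone sizes. Volume and Max. Diameter use physical
  spacing; Max. Diameter is the exact maximum pairwise distance between
  in-mask voxel centers, computed over surface voxels (identical result,
  cheaper) with a convex-hull reduction for large surfaces.
* **GLCM block (6)** — Homogeneity (inverse difference), Correlation,
  Contrast from the gray-level co-occurrence matrix, plus Coarseness,
  Busyness and Complexity. The latter three have no co-occurrence-matrix
  definition; they are computed from the neighbourhood gray-tone
  difference matrix (NGTDM), their canonical home, with 26-voxel
  neighbourhoods and an ε = 10⁻⁶ guard on the Coarseness denominator (a
  constant VOI therefore saturates at Coarseness = 10⁶, with Busyness and
  Complexity 0). Correlation of a zero-variance marginal is NaN.
* **GLRLM (11)** and **GLSZM (11)** — the standard run-length and
  size-zone emphasis statistics (short/long × low/high gray level, the
  two non-uniformities, and Run/Zone Percentage). Zones are maximal
  26-connected components of equal gray level.

**Discretization.** In-mask intensities are binned into Ng equal-width
levels (default Ng = 32, configurable and recorded in every output)
between the in-mask minimum and maximum; a constant region maps to level
1. Because the bin range adapts to the data, all texture features are
invariant to adding a constant to the image — only Mean/Max/Min/Sum
shift. This range-adaptive binning also normalizes pure amplitude
changes: notably, Busyness *decreases* monotonically as additive noise
grows (the noise stretches the range, so per-bin differences shrink),
while Entropy is non-decreasing in the noise level. Both monotonicities
are asserted by tests.

**Directions and anisotropy.** GLCM and GLRLM aggregate the 13 unique 3D
directions at voxel distance 1 by summing counts before feature
computation (merged-matrix convention; per-direction averaging is a
config alternative). Runs, co-occurrences and zones are defined on the
voxel grid irrespective of physical anisotropy; only Volume and Max.
Diameter use spacing. With the merged convention, Run Percentage is
defined as total runs / (13 × voxel count) so it stays in (0, 1]; for a
single direction this reduces to runs/voxels. Run/zone mass conservation
(Σ length×count = voxel count) holds per direction.

Non-finite feature values are carried as NaN, never dropped; downstream
statistics delete them pairwise with a logged count.

## Synthetic phantoms and cohorts

The generator emulates the imaging phenotype of an aggressive orthotopic
mammary carcinoma (4T1-like): a lobulated ellipsoidal mass with a
centrally located necrotic core, a peritumoral edema rim that outlines
the tumor, and additive Gaussian noise. Per contrast the compartments
differ: on T2-like images the core (160) and edema (130) are hyperintense
relative to viable rim tissue (100, background 20); on T1-like images the
core is hypointense (60). These levels are free parameters — no
quantitative signal calibration to any real scanner is implied.

Geometry: tumor diameters are the AP/TS/CC extents; the boundary radius
is perturbed by a low-order (degree 2–3) real spherical-harmonic field
scaled to a maximum relative amplitude (default 0.08; 0 gives an exact
ellipsoid). The mask covers rim + core; edema lies outside the mask, as a
rater segmenting the tumor margin would exclude it. The necrotic core
occupies a fraction of the (lobulated) radius (default 0.3). Default
voxel spacing is anisotropic, 0.109 × 0.25 × 1 mm, echoing a small-animal
T1 GRE geometry; tests that do not need that anisotropy use coarser
isotropic-ish grids for speed.

Cohorts: the default study design has four groups sized 29/23/23/6 imaged
at days 8 and 26 post-implantation in two contrasts. Group mean doubling
times are 4.6/4.8/3.5/4.5 days — three arms in the 4–5 day range and one
accelerated arm in the 3–4 day range; per-subject SGR is drawn with a
between-subject SD of 1.5 %/day, and baseline diameters from N(6, 0.5²)
mm per axis (chosen as a realistic day-8 orthotopic tumor size). Caliper
tables are emitted for two measurement modalities (`us`, `mri`) with
independent 3% multiplicative measurement noise per diameter. A
ground-truth manifest (per-subject SGR, diameters, group effects) is
written next to the data so tests never re-derive truth from the pipeline
under test.

Determinism: every render is a pure function of its parameter object. The
lobulation field's seed is held fixed across timepoints of a subject, so
growth is shape-preserving and the realized VOI volume ratio tracks
exp(SGR·Δt/100) (within 5% at the default resolution; asserted over 20
random draws). The noise field is drawn once per seed as a unit field and
scaled by an in-mask SD and a background SD separately; group texture
effects multiply only the in-mask SD, the core fraction and the core-rim
intensity contrast of endpoint renders, so effect and no-effect renders
with the same seed are voxel-identical outside the mask.

**What the generator does not emulate:** MR physics (relaxation, bias
fields, k-space artifacts), Rician noise statistics (additive Gaussian is
used; Rician would matter at low SNR), infiltrative margins, motion, or
inter-rater segmentation variability. Passing tests therefore demonstrate
the correctness and calibration of the *analysis*, not claims about real
animal data.

## Statistics

The analysis unit per feature is the per-subject endpoint/baseline ratio
(repeated-measures design). Baseline values below 10⁻¹² in magnitude
yield flagged-missing ratios, never ±∞.

* **Permutation t-test** per feature: observed pooled-variance two-sample
  t (Welch selectable), null from n_perm random label shuffles (default
  10,000), two-sided p = (1 + #{|t*| ≥ |t|})/(n_perm + 1). The +1
  smoothing makes p = 0 unattainable, keeping BH input contracts valid;
  consequently p ≥ 1/(n_perm+1). An exhaustive-enumeration mode covers
  all C(n, n₁) splits for small samples and is used to validate the
  shuffled null. Zero variance in both groups with equal means yields
  p = 1 by convention.
* **FDR**: Benjamini–Hochberg step-up across the 39 features of one
  (contrast, control-vs-treatment) comparison; flagged set = adjusted
  p < α (default 0.05).
* **Correlation**: Pearson r with the same permutation scheme on shuffled
  y, two-sided on |r|; zero-variance input returns (NaN, 1).
* **Doubling-time comparisons**: Kruskal–Wallis (tie-corrected) across
  groups; pairwise Wilcoxon rank-sum tests, exact when both groups have
  n ≤ 10 and no ties, otherwise the normal approximation with continuity
  correction; multiplicity correction FDR by default, Bonferroni
  selectable. A Shapiro–Wilk screen (3 ≤ n ≤ 5000; constant input
  reported as certainly non-normal) gates the nonparametric path in
  reports.
* A paired sign-flipping permutation variant on within-subject
  differences is exposed for baseline-vs-endpoint questions, without any
  claim of equivalence to unpaired designs.

Features with fewer than two finite values in a group are reported as
untested rather than silently dropped.

## Validation experiments and problem sizes

The acceptance suite and `scripts/acceptance.py` recompute, from scratch:

* the 39-name panel on a fresh phantom;
* oracle equivalence of every matrix and feature against an independent
  brute-force implementation on 50 random fixtures (≤ 8×8×4, Ng ≤ 8), to
  10⁻¹⁰ relative tolerance;
* closed-form volumetry (π/6 unit sphere; DT = 18 days for exact doubling
  over an 18-day interval) and VOI-vs-caliper DT agreement within 5% on
  lobulation-free ellipsoids;
* type-I error of the three tests under seeded nulls (500 replicates,
  2000 permutations), expected in [0.03, 0.07] at α = 0.05, and
  convergence of the shuffled p to exhaustive enumeration within 2 Monte
  Carlo standard errors;
* BH on the hand-worked example {0.01, 0.02, 0.03, 0.04} → all 0.04, and
  a complete-null 39-feature screen over 50 replicate cohorts (mean
  flagged count ≤ 1);
* recovery experiments on compact cohorts (8 + 8 subjects, 4 mm baseline
  tumors, one contrast, 20 replicates): the pre-registered strong
  endpoint effect (core fraction ×2, in-mask noise ×1.5, core-rim
  contrast ×1.3) must drive Entropy and Zone Percentage below the FDR
  threshold in ≥ 80% of replicates; and a four-group cohort with one
  accelerated arm (true DT 3.5 vs 4.5 days) must rank that arm fastest by
  median DT under all four volumetry methods (caliper ×2 modalities, VOI
  ×2 contrasts).

These sizes keep the full suite and the acceptance script in the
minutes range on a single CPU while leaving the statistical margins wide
(the DT gap is ≈ 3 between-subject SDs; the texture effect is far above
the detection threshold at n = 8 per arm).

## Known limitations

* The discretization scheme, the Size/Intensity-Variance readings and the
  Kurtosis convention follow this package's documented choices; vendor
  radiomics packages vary on all three, so absolute feature values are
  comparable only within a fixed configuration (which is why ratios and
  within-configuration contrasts are the analysis unit).
* Coarseness/Busyness/Complexity are genuinely NGTDM quantities even
  though the panel groups them with the GLCM block.
* Only two-timepoint exponential kinetics are supported; no
  Gompertz/logistic fitting.
* The permutation machinery assumes exchangeability under the null;
  group-specific variance structure is not modeled.
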