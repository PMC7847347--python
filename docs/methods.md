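# Methods

`vasarad` re-implements, as a tested library, a radiogenomics workflow for
predicting IDH1 genotype in lower-grade glioma (LGG) from two complementary
MRI descriptions: 23 qualitative VASARI traits scored by radiologists, and
56 quantitative radiomics features extracted from the apparent diffusion
coefficient (ADC) map inside a tumor mask.  Because no patient data ship
with the package, a seeded synthetic cohort generator provides the study
conditions for all tests; this note records the model, the parameters that
matter, and the choices made where the design was genuinely open.

## The prediction workflow

Subjects are split, stratified by genotype, into a training and a
validation cohort (default fraction 67/102, mirroring a 102-subject study
design with a 50:52 mutant:wildtype balance).  On the training cohort only:

1. **Feature normalization.** Every feature column is min–max rescaled to
   [0, 1]; the training bounds are stored and reused verbatim on validation
   data, with out-of-range values clipped.  Constant columns map to 0 and
   are flagged degenerate.
2. **Two-step selection.** A greedy mRMR ranking (difference form,
   `I(f;y) − mean_s I(f;s)`, plug-in mutual information in bits, continuous
   features discretized into 3 levels at μ ± σ) forms a candidate pool
   (default: all 23 VASARI traits; the top 30 of 56 radiomics features).
   Each pooled feature is then scored by the 0.632+ bootstrap AUC of a
   single-feature random forest, and the top-k (5 VASARI, 10 radiomics)
   form the selected set.
3. **Model-order sweep.** For k = 1..5 (VASARI) and 1..10 (radiomics), a
   random forest on the top-k features is scored with the 0.632+ bootstrap
   AUC on the training cohort; the optimal order maximizes that AUC, ties
   going to the smaller model.
4. **Validation and fusion.** The optimal models are refit R times with
   distinct seeds and scored on the validation cohort; metrics are reported
   mean ± sd over the repeats.  The fusion model averages the two models'
   predicted wildtype probabilities with weight w = 0.5.  Age and gender can
   be appended as two additional normalized columns to test whether clinical
   covariates add information.

The 0.632+ estimator draws B bootstrap resamples, trains on each, and
scores the out-of-bag subjects; with `apparent` the resubstitution AUC and
`oob` the mean out-of-bag AUC,

    R = clip((apparent − oob) / (apparent − 0.5), 0, 1)
    w = 0.632 / (1 − 0.368·R)
    AUC_632+ = (1 − w)·apparent + w·oob,

where 0.5 (chance-level AUC) plays the role of the no-information rate, and
R is 0 whenever `apparent ≤ 0.5`.  Replicates whose out-of-bag set lacks a
class are skipped and counted.  AUC itself is the Mann–Whitney pair
statistic with ties counted ½; ROC curves come from a threshold sweep over
the observed scores.  Sensitivity/specificity/accuracy use a
probability ≥ 0.5 decision rule with wildtype as the positive class (a
Youden-point operating rule was considered and rejected as an undocumented
extra degree of freedom; the threshold is configurable).

## The 56-feature radiomics panel

Families: 3 shape, 13 first-order histogram, 9 GLCM, 13 GLRLM, 13 GLSZM,
5 NGTDM (names in `vasarad.radiomics.FEATURE_REGISTRY`).

* **Discretization**: fixed bin *count* Ng = 32, uniform between the
  in-mask minimum and maximum (min → level 1, max → level Ng).  A fixed
  count keeps matrix dimensions and feature scales comparable across
  subjects, which between-subject modeling requires; the bin-width
  convention was the main alternative and is deliberately not used.
  Constant volumes are flagged degenerate (all voxels level 1).
* **Directions**: the 13 unique 3-D offsets at Chebyshev distance 1.  GLCM
  and GLRLM matrices are summed over directions before features are
  computed, giving one rotation-robust value per feature.  The GLCM is
  symmetrized (each pair counted in both orders) and normalized.
* **Mask restriction**: voxels outside the mask break runs and zones and
  are excluded from co-occurrence pairs; NGTDM neighborhood means average
  over whichever of the 26 neighbors are in the mask, and voxels with no
  in-mask neighbor are excluded from the level counts.
* **Run/zone percentage**: zone percentage is `Nz / Nvoxels`; run
  percentage of the merged matrix is `Nr / (13 · Nvoxels)`, i.e. the mean
  per-direction run percentage, keeping it in [0, 1].
* **Shape**: eccentricity is `sqrt(1 − λ_min/λ_max)` of the covariance of
  in-mask voxel coordinates in physical (mm) units, 0 for a single voxel;
  volume is voxel count × voxel volume; surface area counts exposed voxel
  faces weighted by physical face area.  Only eccentricity is a named
  selection target in the emulated design; volume and surface-to-volume
  ratio are the most common companions in the shape family.
* **Histogram entropy/uniformity** use a fixed-width 64-bin in-mask
  histogram (configurable); all entropies are base 2.  Kurtosis is excess
  kurtosis.
* **Numerical guards**: ε = 1e-12 on NGTDM denominators (coarseness capped
  at 1/ε for flat volumes); GLCM correlation defined as 0 when the marginal
  variance vanishes.

Every texture feature is verified against an independent brute-force
enumeration oracle (pair enumeration, run scanning, 26-connected flood
fill, per-voxel neighborhood means) at tolerance 1e-9, and the mass
invariants — per-direction run mass and zone mass equal the in-mask voxel
count, GLCM sums to 1 — hold on every random instance.

## VASARI encoding

The 23-trait domain table ships as an editable JSON resource
(`vasarad/data/vasari_lexicon.json`).  The five traits central to the
emulated design (enhancement quality, deep white matter invasion, tumor
location, proportion of necrosis, T1/FLAIR ratio) follow the domains the
design names; the other 18 follow the public VASARI guide and are flagged
as such in the resource file.  Ordinal traits are coded by rank (1-based)
so code order matches clinical order; nominal traits use documented integer
codes in listing order — single-column codes rather than one-hot, because
tree ensembles split adequately on small integer categories and the design
treats each trait as one feature with one AUC.  Encoding is bijective per
trait; records round-trip exactly.

## The synthetic cohort generator

The generator emulates a two-class LGG population with planted,
independently controllable class signal.  Tumors are rotated ellipsoids
(principal radii drawn from `tumor_radius_range`, default 6–12 mm,
log-uniform anisotropy normalized to constant product so eccentricity never
leaks into volume) placed in a 48³ volume at 1 mm isotropic spacing.  The
in-mask intensity field is Gaussian-filtered white noise whose *ranks* are
mapped onto a per-subject skew-normal quantile grid, then scaled to the ADC
range: background N(1.2, 0.15²)·10⁻³ mm²/s, clipped at 0 — a plausible LGG
diffusion range; the emulated study reports no distributional parameters,
so these are plausibility-based, not fitted.

The rank-remap construction is the key design decision: it decouples the
marginal intensity distribution (histogram features) from the spatial
correlation structure (texture features), so each planted effect acts on
its target family.  Pure rank-Gaussianization proved *too* sterile — it
makes affine-invariant histogram statistics deterministic, so any
perturbation separates the classes through side channels at AUC 1.0 —
hence three class-independent per-subject jitters: background mean
(sd 0.05), log background sd (sd 0.10), and the skew-normal shape
parameter (sd 2.0), giving histograms the natural between-subject
variation in location, scale, skewness and kurtosis that real ADC
distributions show.

Planted class effects (`ClassEffects`), all zero-able:

| effect | default | acts on |
|---|---|---|
| `necrosis_focus_rate` | 0.8 foci/tumor (wildtype, Poisson) | low-ADC foci ~N(0.6, 0.1²): histogram minimum/variance, low gray-level emphasis |
| `histogram_min_shift` | −0.05 ·10⁻³ mm²/s | a smooth dip deepening the wildtype minimum by a per-subject random amount (sd 40% of the shift) |
| `texture_length_delta` | +0.12 voxels smoothing sd (mutant) | run/zone lengths, GLCM correlation and contrast, NGTDM |
| `eccentricity_shift` | +0.30 anisotropy (wildtype) | eccentricity only (volume is product-normalized) |
| `vasari_effect` | 1.0 | interpolates the class-conditional trait multinomials toward their mixture; 0 = identical classes |
| `clinical_age_shift` | +4.1 years (wildtype) | age covariate (43.2 vs 47.3 year means, sd 16.3) |

Default effect sizes were calibrated once, by a per-feature AUC scan on
100-subject cohorts, so that single-feature AUCs land in the 0.65–0.95
band — the regime the emulated study reports for its selected features —
with the five signal-carrying VASARI conditionals (wildtype: more
enhancement, deep white matter invasion, necrosis, infiltrative T1/FLAIR;
mutant: frontal predominance) producing a comparable qualitative signal.
Signal strength grows with tumor size and volume resolution (larger VOIs
average away extraction noise), so full-scale default cohorts separate more
cleanly than the emulated patients; absolute AUCs on synthetic cohorts are
therefore not comparable to clinical values, and no test asserts them.

Randomness is one hierarchical stream: subject i draws from
`SeedSequence(seed, spawn_key=(1, i))`, so a subject's data are independent
of cohort size; identical config + seed reproduces cohorts bit for bit.

**What the generator does not emulate**: multi-sequence MR contrast
(T1W/T2W/FLAIR appearance), DWI physics and noise floors, registration and
partial-volume artifacts, anisotropic slice spacing, scanner and site
effects, or any correlation between VASARI traits and the voxel data beyond
their shared genotype dependence.  Passing tests therefore demonstrate that
the machinery recovers planted signal of realistic magnitude under
controlled conditions — not that it would reach any particular accuracy on
clinical data.

### Second-rater simulation

`perturb_mask` flips voxels with probability `min(1, s/(1+d²))`, d the
distance to the mask boundary, modulated by a smooth spatial noise field so
flips form contiguous contour deviations; beyond a reach of `2 + 3√s`
voxels nothing flips, so the deep interior is untouched at moderate
severity, while severity → ∞ flips everything and the Dice similarity
coefficient (DSC = 2|A∩B|/(|A|+|B|)) goes to 0.  `calibrate_severity`
bisects on the mean DSC over a set of masks, which decreases monotonically
in severity, to reproduce a desired interobserver regime (the emulated
study's segmentation agreement, DSC ≈ 0.88).

## Statistics

Cohort balance between training and validation uses the 2×k chi-square
test *without* continuity correction (this choice reproduces the printed
p-values of the emulated study's characteristics table from its own
counts), falling back to Fisher's exact test on 2×2 tables when any
expected count is below 5, and the classical equal-variance two-sample
t-test for continuous variables.

## Tie-breaking and determinism

* mRMR: higher score, then **lower redundancy**, then lexicographic name.
  The redundancy tie-break matters: when a feature duplicates one already
  selected, its score ties with independent noise at exactly 0, and
  preferring the less redundant candidate is what "minimum redundancy"
  means at the margin.
* AUC ranking and order sweeps: higher AUC, then smaller order /
  lexicographic name.
* All forests, resamples and cohorts are seeded; rerunning a pipeline with
  the same config and seed writes byte-identical stage outputs (hash-checked
  in the run manifest).

## Problem sizes used by the test suite and acceptance script

Monte-Carlo tests run on reduced cohorts chosen as the package's own
desk-scale defaults: 6³ volumes for oracle equivalence (100 instances),
28–32³ volumes with 4–7.5 mm tumors and 8–15 bootstrap replicates with
8–10-tree forests for the planted-recovery (25 seeds × 100 subjects) and
no-signal calibration (50 seeds × 32 subjects) experiments.  The
fusion-complementarity experiment (25 seeds × 120 subjects, 50/50 split)
moderates the radiomics effect sizes so that neither single model
saturates: decision averaging at a fixed weight can only help when both
models are good but imperfect — the regime the workflow is designed for —
whereas against a ceiling-level model any admixture is dilution; the
60-subject validation cohorts also keep the upward bias of
max(two noisy AUCs) below the margin being tested.  `scripts/acceptance.py` runs the
full workflow at study scale (102 subjects, 48³ volumes, stratified 67/35
split, B = 40, 200-tree final forests, 10 repeated trainings) plus the
30-mask interobserver simulation.

## Known limitations

* The feature formulas follow the field's canonical definitions; the
  emulated study's exact supplementary formula sheet was not available, so
  individual feature values need not match its MATLAB implementation
  (choices such as Ng = 32, 64-bin histogram entropy, merged directions are
  documented above and configurable).
* Single-feature 0.632+ AUC ranking (one AUC per feature) is implemented;
  ranking by incremental model AUC is a plausible alternative reading of
  the two-step selection and is not provided.
* The mutual-information estimator is the plug-in estimate; it is biased
  upward on small samples, which is immaterial for ranking but makes the
  absolute bit values approximate.
* Fusion weight is fixed (default 0.5); no weight optimization is offered,
  by design.
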