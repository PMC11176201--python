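# Methods

`wallrad` implements a radiomic analysis of the urinary bladder wall on
T2-weighted pelvic MR: from a 3D scalar volume and a hollow wall mask to
a standardized intensity scale, a multi-family feature table, a hybrid
("optimal biomarker"-style) feature subset search, and a repeated
stratified cross-validated estimate of how well the selected subset
separates men with mild lower-urinary-tract symptoms (IPSS < 8) from
those with moderate-to-severe symptoms (IPSS ≥ 8). Because no patient
data ship with the package, a synthetic phantom generator produces
cohorts with the statistical structure the analysis assumes, and every
stage is validated against those phantoms.

## Data model and conventions

A case is a `VolumeImage` (3D array plus voxel spacing in mm), a
`WallMask` (binary array on the same lattice) and a `CaseRecord` (age in
years, BMI in kg/m², prostate size in mL, IPSS in 0–35). Voxel indices
are 0-based with axis order (x, y, z) as returned by the NIfTI reader;
geometry is computed in voxel space and converted to mm through the
spacing only where units demand it. The class label is a pure threshold:
positive iff IPSS ≥ 8. Cases with any missing clinical variable are
excluded at manifest load (exclusion, not imputation; each exclusion is
logged with its reason).

The wall mask must be a hollow shell: foreground enclosing at least one
background component not connected to the grid border (6-connectivity).
This is enforced when masks are read from disk and by the morphometry
stage; derived masks (e.g. tight crops) may legally lose the cavity, so
the type itself only checks binary/non-empty.

## Intensity standardization

Two-phase histogram-landmark standardization. Training maps each image's
decile landmarks linearly onto [0, 4095] anchored at its 1st/99th
percentiles and averages the mapped landmarks over images; application
sends each image's own (p1, deciles, p99) piecewise-linearly onto the
learned scale, clipping to the standard range. The map is monotone; on
any image it is idempotent to well under 1% of the standard range, and
invariant to affine re-scalings of the input — the properties that make
intensity features comparable across scanners. The landmark set and
standard range are configuration.

Landmarks are estimated over the mask's bounding region when masks are
given (the pipeline's normal path). Without a mask the default is all
voxels: trimming a low-intensity fraction first (an option kept for
volumes with a true air peak, `foreground_percentile`) composes badly
with the transform's own tail clipping — the collapsed low tail shifts
the trimmed voxel set on a second pass and drags the landmarks with it,
breaking idempotence — so trimming is off by default.

Inhomogeneity (bias-field) correction is deliberately not built in: the
phantoms have no bias field, and the standardization stage accepts
already-corrected volumes from any external tool.

## Feature extraction

Four families, concatenated in the order morphological → intensity →
texture → clinical.

**Morphological (14 columns).** Wall volume (voxel count × voxel
volume); outer and cavity volumes via hole filling; outer surface area
from a marching-cubes mesh; sphericity π^{1/3}(6V)^{2/3}/A of the outer
surface; equivalent-sphere diameters; bounding-box extents; local wall
thickness as twice the Euclidean distance transform sampled on its ridge
(the medial surface), summarized by mean/median/max/SD. On a hollow
sphere phantom (outer 20 mm, inner 16 mm, 1 mm voxels) the voxelized wall
volume is within 5% of the analytic value and mean thickness within
4 ± 1 mm.

**Intensity (12 columns).** In-mask mean, median, SD, min, max,
p5/p25/p75/p95, skewness, kurtosis (Fisher; defined as 0 for a
zero-variance wall), and histogram entropy over 64 fixed bins spanning
the standard range so entropies are comparable across cases.

**Texture (the sweep).** Gray-level co-occurrence matrices with Haralick
summaries, computed in sliding in-plane windows and averaged over the
wall. Quantization is equal-width over the in-mask robust range
([p1, p99], clipped). A window of w×w voxels is centred on every wall
voxel whose window holds at least half wall voxels (configurable); per
window, co-occurrence counts at offset (angle a, distance d) are
accumulated, symmetrized, normalized, and summarized by the requested
Haralick statistics; the per-window values are averaged over all
qualifying windows of the volume. One column per (a, d, b, w, f)
combination, named `{f}_a{a}_d{d}_b{b}_w{w}`.

Texture is 2D in-plane by default because the source acquisitions are
thick-slice sagittal series whose through-plane step (~4 mm) is an order
of magnitude coarser than the in-plane resolution; 3D offsets would mix
incommensurate physical scales. A whole-ROI 3D co-occurrence mode (13
lattice directions, no windows) is available via `TextureConfig.mode`.

Windowed counting convention: in symmetric mode a voxel pair contributes
once per endpoint lying inside the window. This makes reversing the
offset a no-op and renders the angle-averaged features exactly invariant
under 90° in-plane rotation of image and mask — anchoring pairs at a
single endpoint loses that exactness at window boundaries.

Haralick conventions: 0·log2(0) := 0 for entropy; correlation := 0 when
either marginal SD vanishes; cluster shade/prominence are computed from
raw moments of i+j (central-moment expansion), and all statistics linear
in the matrix are evaluated as one matrix product against precomputed
weight vectors — this is what makes the windowed sweep tractable
(hundreds of thousands of small GLCMs per case).

A combination with no qualifying window yields a NaN sentinel; at table
assembly sentinels are imputed with the column median across cases
(preserving the rank statistics the filter uses) and a column with more
than half sentinels is dropped with a warning. The assembled table is
finite by construction.

The default sweep (a ∈ {0°,45°,90°,135°}, d ∈ {1,2,4}, b ∈ {8,16,32},
w ∈ {5,9,15}, 10 Haralick statistics → 1080 texture columns) is
configuration, not contract; the test and acceptance runs use a reduced
sweep (b ∈ {4,8}, w ∈ {5,9} → 480 texture columns, 509 columns in all)
to keep a full cohort extraction under a minute on one CPU.

**Clinical (3 columns).** Age, prostate size, BMI passed through.

## Univariate analysis

Per feature, a Welch unequal-variance t-test of the group mean
difference; features rank ascending by p, ties broken by descending
absolute standardized mean difference, then name. A feature constant in
both groups carries a NaN sentinel and ranks last. These p-values are a
ranking device for the filter stage, not formal inference, so the
ranking uses raw p-values; Benjamini–Hochberg q-values are reported
alongside for information. Pearson feature–feature correlation (with
zero-variance columns flagged and zeroed off-diagonal) feeds redundancy
pruning and the heat-map export. A Mann–Whitney-style alternative is
available through the Kruskal–Wallis baseline selector.

## Feature selection

Three legs combined:

1. *Filter*: keep the `filter_pool_size` lowest-p features (default 200).
2. *Redundancy*: scan the pool in rank order, dropping any feature with
   |r| > 0.9 against an already-kept one (deterministic greedy).
3. *Wrapper/embedded*: greedy forward selection with swap refinement.
   From the empty set, each sweep scores every single-move neighbour —
   add any pool feature (below `max_subset_size`), or swap any member
   for any pool feature — by repeated stratified CV of the downstream
   classifier (5-fold × 10 repeats by default, all splits derived from
   the configured seed), accepts the best move if it improves the
   objective by > 1e-6, and the search stops after two sweeps without an
   accepted move. The classifier participates in selection (the
   "embedded" leg); there is no separate penalized-model step. The
   search strategy sits behind the `obm_search` interface so beam or
   exhaustive-small alternatives can be plugged in.

Inner-CV repeats during the search (10) are deliberately fewer than the
final evaluation's (100): the search only needs a stable ordering of
candidate subsets.

Literature baselines for comparison: ANOVA F (identical to squared-t for
two classes), Kruskal–Wallis, chi-square after shifting each feature to
be nonnegative (subtract the column minimum), and a greedy MRMR
(F-statistic relevance minus mean |Pearson| redundancy), each returning
a top-k list (k = 10 by default).

## Evaluation

Stratified K-fold CV: per-class round-robin after a seeded shuffle, so
fold class counts differ by at most one within each class (with 50/37
labels and k = 5: 10 negatives per fold, 7–8 positives). Default
classifier: per-fold z-scaling (statistics from training rows only)
followed by a soft-margin linear SVM with unit cost — a conventional,
fast choice for wrapper selection; logistic regression and a random
forest are available through configuration. Metrics per repeat come from
the validation predictions pooled across the repeat's folds (stabler for
AUC with few positives than per-fold averaging): accuracy, sensitivity
(recall of the IPSS ≥ 8 class), specificity, balanced accuracy
(≡ (sens+spec)/2, an exact identity per repeat), and trapezoidal ROC
AUC with midrank tie handling (equal to tie-aware pair counting to
1e-10). Repeats reshuffle folds with seeds derived from (seed, repeat
index), so a longer run's first repeats coincide with a shorter run's,
and every report is a pure function of (inputs, seed).

The majority-class baseline scores accuracy equal to the majority
fraction (50/87 → 0.57 at study scale) and balanced accuracy 0.5; its
AUC is undefined for a constant score and reported as 0.5 with an
explicit degenerate flag. Subset comparisons (age-only, BMI-only,
all-clinical, optimal) reuse identical fold seeds so the comparison is
paired.

## Synthetic cohorts

Each phantom is a hollow ellipsoidal shell: outer semi-axes sampled from
10–15 mm, wall thickness from 3.5–6 mm (resampled if under 2 voxels;
error after 100 tries), centre jittered, in a 40³ grid at 1 mm isotropic
spacing — a scaled-down bladder that keeps full-cohort runs desk-sized
while preserving wall-to-window geometry. Wall voxels carry a base
intensity plus a stationary correlated Gaussian field (white noise
smoothed with a Gaussian kernel whose width is the correlation length,
then renormalized to unit variance so the marginal intensity
distribution is identical in both classes); cavity and background carry
distinct base intensities plus white noise (urine bright on T2). A
per-case random gain and offset emulate inter-scan intensity drift for
the standardization stage to remove.

The classes differ only where a dial says so: `texture_effect` scales
the positive class's texture correlation length (length × (1 + effect));
`intensity_effect` shifts its wall mean; `morphology_effect` its
thickness. Both default effect structure and clinical model mirror the
target population: texture differs (effect 1.0), intensity and
morphology do not, age and BMI are identically distributed, and prostate
size alone is larger in the positive class (40 vs 55 mL means). IPSS is
sampled uniformly within the class range ([0,7] / [8,35]) — a declared
stand-in, since the within-class score distribution of a real cohort is
not modelled. Cohorts are pure functions of (config, seed), with
independent per-case streams so any case regenerates alone.

What the phantoms do *not* emulate: anatomically realistic bladder
shapes, bias fields, scanner noise spectra, partial-volume effects, or
correlations between clinical variables and image content. Passing tests
therefore demonstrate that the pipeline recovers the *category* of a
planted class contrast and stays calibrated when there is none — not
clinical performance on real scans.

## Statistical validation choices

*Null calibration.* With all effects zero the classes are exchangeable.
Marginal calibration is checked with genuinely independent replicates:
one p-value per tracked feature per cohort, pooled over 30 independent
small null cohorts, must be KS-uniform. Within a single cohort the
~509 features are heavily dependent (the correlation matrix's effective
rank is about 3 — windowed texture features of one stationary field are
near-duplicates), so the single-cohort uniformity check compares the KS
distance of the p-value ECDF against its label-permutation distribution,
which preserves that dependence, at α = 0.01; a naive KS test against
Uniform(0,1) would reject for any seed purely because of the dependence.
Similarly, the subset search overfits its CV objective under the null
(selection picks the luckiest of many noise features), and that bias is
identical under label permutation — so the search's null-cohort
objective is required to sit within 3 SD of its own permutation
distribution, with the majority fraction reported alongside.

*Signal recovery.* On cohorts whose classes differ only in texture
correlation length (effect 1.5, n = 40, clinical matched), the search
must select only texture-category features in ≥ 9 of 10 seeds and the
selected subset's repeated-CV AUC must exceed 0.9; the hybrid search's
objective must match or beat each literature selector's top-10 subset in
≥ 8 of 10 seeds. These are tendencies over seeds, not fixed margins.

## Numerical details

- Percentile-tie nudge: on heavily discretized data the landmark
  percentiles can tie; the source landmark vector is made strictly
  increasing by an epsilon before interpolation.
- StandardScaler's zero-variance guard leaves constant features unscaled
  (effective SD floor), giving them zero discriminative weight.
- GLCM with no valid pair returns the zero matrix; Haralick on it yields
  the NaN sentinel resolved at assembly.
- Stratified folds with k equal to the number of cases degenerate to
  singleton (leave-one-out) folds.
- Seeds: a single global seed fans out to per-stage seeds by CRC-32
  hashing of the stage name, all below 2³¹; per-repeat CV seeds derive
  from (seed, repeat) via `numpy.random.SeedSequence`.

## Known limitations

- The texture model has a single latent dimension per class contrast;
  real wall remodeling is heterogeneous within and across patients.
- The wrapper search is greedy with swaps: deterministic and fast, but
  not guaranteed to find the globally best subset of a given size.
- No bootstrap confidence intervals, calibration analysis, or external
  validation; single-sequence (T2) volumes only; no DICOM ingestion or
  registration.
- The feature inventory is configurable but makes no claim of IBSI
  certification (naming follows IBSI where natural).
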