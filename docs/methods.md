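# Methods

## Scope and data model

The pipeline operates on one 3-D CT volume per contrast phase (unenhanced,
arterial, venous, optionally delayed), each in Hounsfield units with a voxel
spacing in mm, paired with a voxel-aligned binary lesion mask (VOI).  Axes
are ordered (x, y, z) with the third index running over slices; voxel
indices are 0-based and in-VOI samples are ordered lexicographically by
(i, j, k).  Every downstream statistic is invariant to that ordering.
Masks must share the volume's grid and spacing (tolerance 1e-3 mm); no
registration or contour propagation is performed — each (phase, mask) pair
is treated independently, and HU values are carried as floating point.

## Washout densitometry

With phase means U (unenhanced), E (enhanced) and D (delayed):

* absolute washout = 100·(E − D)/(E − U), undefined when E = U;
* relative washout = 100·(E − D)/E, undefined when E = 0.

The conventional rule classifies a lesion as `benign_pattern` iff U < 10 HU
or (absolute > 60 % and relative > 40 %); comparisons are strict, exactly as
the thresholds are conventionally quoted.  Which acquisitions serve as
"enhanced" and "delayed" is the caller's designation; the operators are pure
functions of the three means.  Lesion size ≥ 40 mm is surfaced as an
advisory flag only and never changes the class.  Adding a constant to all
three means leaves absolute washout unchanged (shift invariance).

## The 32-feature texture signature

Grey levels: the VOI's own [min, max] range is binned uniformly into
Ng levels (default 32, configurable); the maximum maps to level Ng and a
constant VOI to level 1.  Because binning is min–max relative, all
quantized (second-order) features are invariant to a constant HU offset.

First-order (5): mean and sample SD (ddof = 1) of the raw HU values;
skewness as the standardized third central moment; kurtosis as the raw
m₄/m₂² (no excess-3 subtraction); entropy −Σ q·log₂ q over the Ng-bin
histogram.  A constant VOI gets SD = skewness = kurtosis = entropy = 0.

GLCM (16): for each direction offset, ordered in-VOI voxel pairs at the
given distance (default 1) are counted, the count matrix is symmetrized by
adding its transpose, counts are pooled over directions and normalized.
Features are the Haralick set: autocorrelation, cluster prominence, cluster
shade, contrast, correlation, difference entropy, difference variance,
dissimilarity, energy, entropy, inverse difference moment (homogeneity),
maximum probability, sum average, sum entropy, sum variance, variance.
Correlation falls back to 0 when a marginal variance vanishes; a
single-voxel VOI (no pairs) is a degenerate-matrix error.

RLM (11): maximal equal-level runs of in-VOI voxels along each direction
(a gap in the VOI breaks the chain), pooled over directions.  Features are
the Galloway set normalized by the number of runs N_r: SRE, LRE, GLN, RLN,
RP (= N_r/N_p with N_p the voxels traversed, per direction before
pooling), LGRE, HGRE, SRLGE, SRHGE, LRLGE, LRHGE.

Directions: default `3d` uses the 13 unique nearest-neighbour offsets; a
slice-wise `2d` mode with the 4 unique in-plane offsets is available
because CT slice thickness (~5 mm) is much larger than in-plane spacing
(~0.74 mm).  Offsets are in voxel units — spacing anisotropy is ignored in
offset geometry, matching common texture-tool behaviour.  Logarithms are
base 2 with 0·log 0 := 0.  The provenance fields (phase, Ng, mode,
distance) travel with every feature vector.

The 5 + 16 + 27 split is the canonical reconstruction of a 32-feature
first-/second-order budget: the named GLCM/RLM members fix most of the
second-order set and the remainder are the standard Haralick/Galloway
completions.  No numerical identity with any commercial texture tool is
claimed.

## Cohort statistics

Group comparisons use the pooled-variance two-sample Student's *t* test by
default (this choice reproduces the reference cohort's printed P values
from its printed mean(s.d.)/n summaries; Welch is available behind a
flag), and the Pearson χ² without continuity correction for 2×2 tables.
`t_from_summary` is algebraically identical to the raw-sample test and
exists so printed summary tables can be checked directly.

Feature selection keeps features with P < α (default 0.05) in the
carcinoma-vs-pooled-benign comparison, per phase, with no multiplicity
adjustment by default (matching the reference analysis; Benjamini–Hochberg
is available).  Under the null its per-feature false-selection rate is ≈ α.

ROC analysis is empirical over all distinct score thresholds; AUC is the
trapezoidal area, identical to the Mann–Whitney probability with half
credit for ties.  Orientation is chosen so AUC ≥ 0.5 and is recorded.  The
Youden cut-off is reported as the midpoint between the adjacent distinct
scores bracketing the optimum (hence half-integer cut-offs on integer
scores); ties on J break toward the lowest cut-off.

## Unsupervised arm

Pipeline per phase: z-score columns (ddof = 1; constant features dropped
with a warning) → outlier screen → re-standardize the retained subjects →
K-means, k = 2, Lloyd iterations, best of 50 seeded restarts (seed and
restart count recorded) → PCA of the standardized matrix for 2-D
visualization (deterministic sign convention: the largest-magnitude
loading of each component is positive) → cluster→class mapping by majority
agreement and per-class detection rates (correct/total, with the counts
reported).  K-means runs on the full standardized feature space by
default — PCA is presentation only — but a config switch allows clustering
on the first m component scores instead.

Outlier screening replaces a by-inspection removal with an algorithmic
rule.  The default flags subjects whose Euclidean distance to their 3rd
nearest neighbour exceeds max(median + k·1.4826·MAD, 2·median) of those
distances, k = 3 by default, in a single pass.  The nearest-neighbour
distance was chosen over distance-from-the-grand-median because the latter
inevitably flags the whole minority class once the benign/malignant
separation is large: in a 32-dimensional standardized space the
within-cluster distances concentrate tightly around their median, so any
cluster displaced far enough to be clusterable also sits beyond
median + 3·MAD.  The kNN statistic is small inside any sufficiently
populated cluster and large only for isolated points, which is the
behaviour the screening needs; the 2·median floor absorbs the upper tail
of the skewed kNN-distance distribution in small cohorts.  The simpler
grand-median rule remains available as `method="median"`, and the
multiplier, neighbour order and method are all configurable and reported.
The rule is calibrated for high-dimensional feature tables; in very low
dimension (a handful of features) its false-flag rate rises and a larger
`k_mad` is advisable.

## Synthetic data

`generate_phantom` builds an ellipsoidal lesion (semi-axes 0.42× the grid,
default 48×48×16 voxels ≈ 11 500 in-VOI voxels) filled with a spatially
correlated Gaussian field: white noise smoothed with a Gaussian kernel
whose sigma is the texture correlation length (voxels).  Class presets tie
the intensity scale to the reference cohort's group statistics — unenhanced
VOI mean(SD) 33.4(4.7) HU for carcinoma, 20.2(9.2) for adenoma, 2.8(9.4)
for incidentaloma.  The carcinoma preset is rougher (correlation length
1.2 voxels vs 3.0) and carries necrosis blobs (15 % of the VOI at ~18 HU,
thresholded from a coarser random field) and calcification specks (2 % at
~50 HU).  Blob means were deliberately kept within a few within-lesion SDs
of the tissue mean: with min–max quantization, far-out blob intensities
compress the viable-tissue histogram into a few grey levels and would
invert the intended heterogeneity ordering — mirroring the real-world
behaviour in which massively calcified tumours become texture outliers
rather than typical members of their class.  After heterogeneity
implantation the whole masked sample is affinely moment-matched, so the
unenhanced VOI mean and SD equal the configured targets exactly (the
mean-densitometry semantics of a clinical report are whole-VOI statistics).
Contrast phases add a class-specific constant enhancement plus 1 HU of
white per-phase noise; the offsets are derived so the class-mean HU
trajectory reproduces the reference washout percentages (carcinoma
30.0/16.5 abs/rel, adenoma 32.2/23.7, incidentaloma 63.3/46.5 — i.e. the
incidentaloma clears the >60 %/>40 % rule and the other two classes do
not).  One integer seed fully determines all four phases and the mask.

`generate_image_cohort` draws subject-level unenhanced means from the
class mean(SD) — the between-patient spread — while each phantom keeps its
class's within-VOI texture SD; the reference table's single SD column is
thereby used in both roles, which is a modelling convenience, not a claim
about the data-generating process.

`generate_cohort_table` bypasses images entirely: per-subject 32-feature
vectors per phase from group-specific diagonal Gaussians over fixed,
varied per-feature scales.  `separation` is the Euclidean norm of the
carcinoma-vs-benign mean shift in pooled within-group SD units, spread
equally across features (default 4.0, giving strong but imperfect
clusterability comparable to the reference detection rates).  Optional
injected outlier carcinomas are displaced by 12 SDs per feature with
random signs (far from every centroid and from each other), emulating
heavily calcified outlier tumours; outliers carry a ground-truth flag.
Optional clinical fields (age, sex, side, diameter) are drawn from the
reference group summaries.  Default group sizes are 10/9/11.

What the generators do **not** emulate: organ anatomy, partial-volume and
beam-hardening physics, scanner noise spectra, inter-feature correlation
structure within a class, or any texture-level ground truth for real
adrenal lesions (none is published).  Tests passing on these phantoms
demonstrate the correctness and calibration of the computations, not
clinical performance on patient images.

## Numerical conventions and degenerate inputs

* Seeds: every stochastic component takes an explicit integer seed;
  cohort-level generators derive per-subject seeds from one root generator.
* Quantization tolerance: GLCM probability sums are exact up to 1e-9;
  feature-vs-oracle agreement is asserted at 1e-9.
* Degenerate inputs raise typed errors rather than returning NaN: empty
  VOIs, single-voxel VOIs (no co-occurring pairs), zero pooled variance,
  single-class ROC labels, all-constant feature matrices.
* Pipeline outputs are plain CSV/JSON with no timestamps and an embedded
  SHA-256 config hash, so identical config + seed reruns are byte-identical.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on synthetic data at
deliberately modest sizes: phantoms of 48×48×16 (calibration, ~11 500 VOI
voxels) or smaller for smoke tests; 30-subject cohorts mirroring the
reference group sizes; 500 simulated cohorts for the null-calibration
check, 200 for power, 100 seeds for the unsupervised-recovery and
outlier-recovery checks; 50 random micro-VOIs (≤ 6³ voxels, Ng ≤ 8) for
brute-force oracle equivalence.

## Known limitations

* Feature definitions are the canonical Haralick/Galloway forms; no
  equivalence with any specific commercial implementation is claimed.
* Offset geometry ignores voxel anisotropy; use the `2d` mode when slice
  thickness dominates.
* The outlier rule is a reconstruction of a judgement call and is
  calibrated for high-dimensional feature tables.
* AUC confidence intervals (DeLong), multivariable models and survival
  analysis are out of scope.
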