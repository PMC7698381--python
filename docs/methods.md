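# Methods

`iish` quantifies combined intra-site and inter-site radiomic heterogeneity of
multi-lesion CT patients and couples the resulting statistic (cluDiss) with
clinical and genomic variables into linear risk scores and a platinum-
resistance classification protocol. This note records the models, the
conventions the implementation fixes where the underlying method leaves
choices open, and what the synthetic phantoms do and do not establish.

## Per-voxel texture maps

CT intensities are min-max rescaled to 0–255 and discretized into 32 gray
levels. The reference range is, by default, the union of the patient's
lesion voxels (`rescale_scope="lesions"`): a tumor-focused window that makes
every downstream feature invariant to constant intensity shifts and
insensitive to background anatomy. `rescale_scope="image"` is available for
comparison. A degenerate range (constant input) maps everything to level 1
with a warning rather than failing.

For every voxel inside a lesion, a gray-level co-occurrence matrix (GLCM) is
accumulated over an 11×11×1 in-plane patch centered on the voxel, pooling the
four in-plane direction offsets at distance 1 into one symmetric GLCM
(pooling and direction-averaging give identical normalized matrices; pooling
is simpler). Both voxels of a pair must lie inside the lesion mask, so
surrounding tissue and air never contaminate the statistics; this mask
restriction is a deliberate convention and is recorded in the map provenance.
Four Haralick statistics are taken from the normalized GLCM:

    energy      = Σ p²
    entropy     = −Σ p log₂ p        (0·log 0 := 0)
    homogeneity = Σ p / (1 + |i−j|)
    contrast    = Σ p (i−j)²

A patch yielding zero valid pairs uses the degenerate single-cell convention
(energy 1, entropy 0, homogeneity 1, contrast 0). The sliding-window kernel
is compiled with numba and is tested for bit-level agreement (< 1e-10)
against a naive pure-Python per-voxel re-computation.

## Subregions: kernel K-means with AIC model selection

Each lesion is partitioned independently. The per-voxel descriptor is
7-dimensional: the four Haralick map values plus the voxel coordinates, all
z-scored per lesion, with the spatial channels down-weighted by
`spatial_weight = 0.1` so that spatial contiguity breaks ties without
dominating texture. Clustering is hard kernel K-means with an RBF kernel
whose bandwidth is the median pairwise descriptor distance on a ≤2000-voxel
subsample; k-means++-style seeding in the kernel-induced metric, 10 restarts,
at most 50 iterations. Lesions larger than `sample_cap = 1000` voxels are
clustered on a random subsample and the remaining voxels assigned by kernel
distance to the cluster means — an accuracy/cost trade-off that keeps the
kernel matrix exact at a size where a full decomposition is cheap.

The cluster count k ∈ {1, …, 5} minimizes an Akaike information criterion.
The AIC is computed from the diagonal-covariance Gaussian mixture implied by
the partition: weights, means and per-channel variances are the M-step
estimates from the hard labels, the likelihood is the *soft* mixture
likelihood, and the parameter count is (k−1) + 2kd. Two simpler candidates
were rejected because they provably inflate k on homogeneous lesions: a
WCSS-based "classification likelihood" criterion overstates the gain of any
split (splitting a single Gaussian always reduces within-cluster variance by
a factor bounded away from 1), and spherical components reward splits merely
because the z-scored descriptor is anisotropic. With the mixture AIC, the
test suite verifies that k = 1 is selected on i.i.d.-descriptor lesions and
k = 2 on two-class lesions with 5-SD separation in at least 90% of 50 seeded
replicates each, with ≥ 95% voxel-label agreement. Per-cluster variances are
floored at 1e-3 of the channel variance to avoid mixture singularities on
singleton clusters.

Each subregion is described by the mean of its four Haralick map values; the
clustering is per lesion (its own AIC-selected k), and subregions from all
lesions are pooled per patient. Clustering per lesion rather than jointly per
patient keeps lesions commensurable and matches the notion of subregions
extracted "from within" each volume of interest.

## The group dissimilarity matrix and cluDiss

Pairwise Euclidean distances between pooled subregion descriptors form the
dissimilarity matrix. The GDM is a K×M (10×10) 2D histogram built by
dependence counting: the upper-triangle dissimilarities are min-max
normalized per patient and assigned to K equal-width levels (the maximum is
clamped into level K; an all-equal set maps to level 1); for each subregion s
and level ℓ the group size c(s, ℓ) counts the other subregions whose
distance to s falls in level ℓ; every non-empty (s, ℓ) entry increments
G(ℓ, min(c, M)).

Two conventions here deserve emphasis because the construction is the
package's own resolution of a genuinely ambiguous recipe:

* **Dissimilarities are normalized per patient; group sizes are not.**
  Texture-descriptor scale is arbitrary, so dissimilarity levels must be
  relative. Group sizes, however, are absolute partner counts clamped at M —
  the same logic as a neighborhood gray-level dependence matrix. Min-max
  normalizing the sizes per patient was tried and discarded: it erases
  exactly the dependence on the number of disease sites that the statistic
  exists to capture: under per-patient size normalization the rank
  correlation of cluDiss with the number of distinct lesions collapses to
  near zero, whereas with absolute counts the test suite verifies it at
  ≥ 0.8 on a 40-patient phantom cohort.
* **The moment uses raw bin indices.** With P = G/ΣG and count-weighted mean
  levels μ_D = Σ i·P and μ_A = Σ j·P,

      cluDiss = 1/(K·M) · Σᵢ Σⱼ (i + j − μ_D − μ_A)⁴ · G(i, j),

  G entering as raw counts. The statistic therefore grows with the number of
  lesions and subregions as well as with the spread of their textural
  dissimilarities, and its magnitude on realistic phantoms lands in the
  tens-to-hundreds range where the shipped decision thresholds live. The
  default cutoffs — 68.62 for cluDiss and 642.00 for the iRCG score (68.82
  also circulates for the former; the default uses 68.62) — are documented
  configuration values from the clinical development of these measures, not
  quantities this implementation re-derives; `find_cutpoint` refits them on
  new cohorts by Youden-optimal ROC analysis.

Fewer than two subregions (or fewer than two in-scope lesions) yield
cluDiss = 0 flagged not-evaluable; the protocol requires at least two tumor
sites. Pelvis-only and abdomen-only variants run the identical chain on the
region-filtered lesion subset.

Conventional measures are total tumor volume (voxel count × voxel volume, in
cc) and the number of distinct anatomic site labels.

## The 75 average-heterogeneity features

Computed over the pooled voxel set of all lesions (config-switchable to a
volume-weighted per-lesion average); pooling makes the non-uniformity
features (GLN, SZN, DCN) burden-sensitive, which matches their documented
correlation with total tumor volume. Families and counts are frozen by
`feature_manifest()`: first-order (4), GLCM (5), GLRLM (13), GLSZM (13,
including GLN and SZN), NGTDM (5, including coarseness), NGLDM (15,
including DCN), Sobel statistics (4) and Gabor statistics (16 = 4
orientations × 4 statistics). Matrix families use 3D 26-neighborhood offsets
merged before statistics and the same 32-level discretization as the texture
maps. NGLDM uses dependence threshold α = 0 with the center voxel included
in the dependence count; its 15-feature list is the 14 standard dependence
features plus dependence-count energy. Sobel and Gabor are applied slice-wise
(2D) to the rescaled volume; Gabor uses wavelength 2 px (frequency 0.5),
bandwidth √2, orientations {0°, 45°, 90°, 135°}; responses are summarized by
{mean, std, skewness, kurtosis} (Pearson kurtosis) of the magnitude over
lesion voxels. A filter term named without a statistic resolves to its mean.
Shape features are excluded by design — they describe single tumors, not
cross-site heterogeneity. Every accumulator is tested against independent
brute-force enumeration on small random images, exactly for the integer
matrices.

## Risk scores and classification protocol

The three score presets use the published coefficients with variables in raw
units (age in years, CNB as a genome fraction, cluDiss as computed);
resection is coded complete=0, optimal=1, suboptimal=2 and stage III=0,
IV=1. Raw units are the only encoding consistent with the magnitude of the
shipped iRCG cutoff (≈ 4.44·70 + 3.72·60 + 2.11·0.5 ≈ 600). Score = cutoff
classifies as high risk. Elastic-net refitting delegates to scikit-learn's
`ElasticNet` (mixing α, penalty λ; grid search by CV when a tuning grid is
given); note scikit-learn's penalty parameterization differs from glmnet's
by a factor involving n, so λ values are not numerically interchangeable
with glmnet's. ROC cut points maximize Youden's J with ties broken toward
the lower cutoff; anti-concordant scores flip the direction flag.

Platinum-resistance classification is a linear-kernel SVM under stratified
3-fold cross-validation repeated 100 times. Features are standardized on
each training fold; SMOTE (minority kNN interpolation, k ≤ 5, implemented
in-package) balances the training fold only — its random stream is derived
from the seed and the training-fold content alone, so held-out patients
cannot influence the synthetic samples. Out-of-fold decision scores are
pooled per repetition into AUROC, sensitivity and specificity; 95% CIs are
percentiles over the 100 repetition estimates; variable importances are mean
absolute standardized weights rescaled to max = 100. The averaged-radiomics
variant wraps the SVM in recursive feature elimination with the feature
count chosen from {5, 10, 15, 20, 25} by nested 3-fold CV. Model comparison
is a two-sided paired Wilcoxon signed-rank test on the per-repetition AUROC
differences — the natural paired test for repeated-CV estimates.

Scanner robustness uses a two-sided Wilcoxon rank-sum per feature (GE vs
non-GE); a feature is robust iff p > 0.05 (no detectable scanner shift);
constant features get p = 1 and a flag. The radiogenomic screen reports
Spearman ρ with two-sided p per (feature, enrichment score) pair, flags at
p < 0.05, and Benjamini–Hochberg q-values as a clearly-labeled companion;
cells with fewer than 5 complete pairs are not evaluable. Enrichment scores
themselves (ssGSEA, ESTIMATE, consensus TME) are consumed as precomputed
tables, never computed here. Survival associations delegate to lifelines
(Cox proportional hazards with Wald CIs and concordance; Kaplan–Meier by
risk group with log-rank p); group PCA loading tables delegate to
scikit-learn.

## Phantoms

`make_patient` renders ellipsoidal lesions filled with Gaussian-random-field
texture: white noise smoothed at a class-specific correlation length, scaled
to a class mean and SD. The palette of eight texture classes varies local
contrast (SD 3–25 HU-equivalent) and smoothness (correlation length 0–2
voxels), which is what the Haralick descriptor actually measures; class
means differ so lesions are visible, but separation does not rely on them.
Multi-class lesions split the ellipsoid into equal slabs, and ground-truth
voxel labels are returned for recovery tests. The default grid is 96×96×32
at 1×1×3 mm, keeping the full per-patient chain around a second.

`CohortSpec` defaults emulate the target clinical population: 75 patients,
2–8 lesions each, 1–4 distinct texture classes, ~19% missing platinum
labels, logistic resistance link with intercept −1.2 (≈ 23% prevalence at
the center of the heterogeneity range) and slope 1.0 per texture class,
exponential PFS with median 15 months and log-linear hazard slope 0.35 per
class, 30% censoring, and a GE/non-GE scanner mix. All randomness flows from
one cohort seed through `SeedSequence([cohort_seed, patient_index])`, so any
subset regenerates identically.

What the phantoms do **not** emulate: CT physics (noise spectra,
reconstruction kernels, contrast phases), anatomy, irregular lesion shapes,
partial-volume effects, or genuine scanner effects (scanner labels are
assigned metadata). Passing tests therefore establish that the
implementation has the intended mathematical behavior — monotone response to
the number of texturally distinct lesions, separation of homogeneous from
heterogeneous disease, correct protocol hygiene — not that the statistic
prognosticates outcomes in real patients.

## Problem sizes and numerical conventions

The test suite and the acceptance script run: the Haralick oracle on twenty
20×20 images; cluster-count recovery on 50 descriptor-level replicates per
condition; monotonicity on a 40-patient cohort (lesion counts cycling 2–8);
homogeneity arms of 30 patients each; and the classifier ordering on a
60-patient outcome-linked cohort — sizes chosen to estimate each property
stably at interactive cost. Other conventions: geometry comparisons use
1e-4 mm (spacing) and 1e-3 mm (origin) tolerances; discretization bins are
equal-width with the maximum clamped into the top level; entropy uses log
base 2 with 0·log 0 = 0; degenerate inputs (constant volumes, all-equal
dissimilarities, constant features) take documented conventions rather than
raising, except where a computation is meaningless (empty masks, single-class
outcomes, zero events).

## Known limitations

* The GDM construction resolves a genuinely ambiguous recipe; an implementer
  cross-checking against other radiomics software may need to switch
  conventions behind the same interface. The shipped cut-offs are defaults,
  not reproduced values.
* Kernel K-means on subsampled lesions is deterministic given the seed but
  not invariant to voxel order; lesion-level seeds are derived from the
  lesion's position in the patient's lesion list.
* DICOM support covers plain axial series only.
* Elastic-net coefficients are reported in raw variable units; standardized
  fits, if wanted, require standardizing the inputs first.
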