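# Methods

This note documents the models, parameter choices and numerical
conventions behind `lungphen`, and what the synthetic phantoms do and do
not establish about real LDCT data.

## Segmentation

The lung field is found by 1-D K-means (k = 2) on voxel HU. Centers are
initialized deterministically at the 10th and 90th HU percentiles and
Lloyd-iterated to a 1e-3 HU tolerance, so segmentation has no random
seed. The lowest-center cluster (air + parenchyma) forms the candidate
set; 26-connected components touching the volume border are discarded as
exterior air, components smaller than 1% of the candidate set are
dropped, the mask is closed with a 2 mm ellipsoidal structuring element
(converted to voxels per axis), and voxels above the vessel threshold
(−300 HU) are excluded. The vessel threshold, component fraction and
closing radius are conventional lung-CT values, not derived quantities;
all are exposed in `SegmentationParams`. Lowering the vessel threshold
can only shrink the mask (it is the final exclusion), and no mask voxel
ever lies on an outer face.

Intensity-driven segmentation of a blurred air/soft-tissue edge loses
roughly half a voxel of boundary shell; on the default phantoms this
bounds Dice against ground truth at ≈ 0.95–0.98 depending on seed and
kernel, which matches what intensity-based methods achieve on real lung
CT.

## Lattice features

Windows are cubic in millimetres: the edge in voxels per axis is
`round(W / spacing_axis)`, minimum 1, so anisotropic spacing gives
anisotropic voxel counts but constant physical extent. Windows tile the
mask bounding box from its origin with stride equal to the window edge
(non-overlapping); a window is evaluated only if ≥ 50% of its voxels are
in-mask (`min_occupancy`), and all features use in-mask voxels only.
Lattice points at window corners vs centers is a display convention; the
tiling origin adopted here is the bounding-box corner.

Quantization is fixed-range: HU clamped to [−1024, 200] and binned into
32 equal-width levels, the upper bound mapping to level 32. A fixed
range (rather than per-window min–max) keeps levels comparable across
windows, scans and kernels; per-window normalization is available as an
option but changes the meaning of every quantized feature.

The 26 features are: histogram {mean, variance (population), Fisher
skewness, excess kurtosis, Shannon entropy (natural log, over quantized
levels), uniformity}; GLCM {contrast, correlation, energy (ASM),
homogeneity (IDM), entropy, dissimilarity, cluster shade, cluster
prominence, maximum probability}; GLRLM {SRE, LRE, GLN, RLN, RP, LGRE,
HGRE, SRLGE, SRHGE, LRLGE, LRHGE}. Co-occurrence and run-length counts
are accumulated over all 13 unique 3-D directions into a single matrix
before features are computed (direction-aggregated rather than
per-direction averaged) — more stable in small windows, and switchable
via the `directions` argument. The GLCM is symmetrized (each pair
counted in both orders) and normalized to unit mass; pairs and runs
never cross the mask or window boundary. RP divides total runs by the
in-window voxel count per direction summed over directions.

Degenerate conventions: zero-variance windows return skewness 0,
kurtosis 0 and GLCM correlation 0; windows with no valid voxel pair are
skipped. Per-scan descriptors are unweighted means over evaluated
windows, with the window count recorded.

Both matrix builders are verified against brute-force pair/run
enumeration oracles to 1e-10 in the test suite.

## Harmonization

Outlier screening: each feature is the response in three univariable OLS
regressions (age, BMI, pack-years as single predictors, pooled over the
dataset); a scan is flagged if any residual leaves the median ± 2.5·IQR
band of its residual vector. Flags are dataset-relative by construction.
A constant covariate degenerates to intercept-only regression (residuals
are centered values). The pipeline default drops flagged scans before
ComBat; harmonization with outliers retained is available by config.

ComBat follows the standard parametric empirical-Bayes algorithm: per
feature, batch indicators and protected covariates are fit jointly by
least squares; data are standardized by the grand mean (batch-size
weighted) plus covariate effects and the pooled residual SD; per-batch
location/scale estimates are shrunk by iterated conditional posterior
means (normal prior on location, inverse-gamma on scale, moment-matched
hyperpriors, tolerance 1e-4) and inverted out. Categorical protected
variables are reference-coded indicators; the design is checked for rank
and aliased columns are reported by index. The implementation matches
Bioconductor's `sva::ComBat` to ~1e-13 on seeded data (tested through
Rscript). A single-batch fit is the identity by construction (γ* = 0,
δ* = 1).

One property worth knowing: EB shrinkage pulls each feature's batch
location toward the cross-feature prior mean, leaving an in-sample
residual of about half the batch-mean sampling noise (≈ 1.3/√n per batch
in standardized units). Harmonization therefore removes *almost* all of
an injected shift (tests assert > 95%), not exactly all of it — the
price of the variance reduction that motivates EB in the first place.

Residual batch differences are quantified by two-sample KS tests per
feature (asymptotic p by default; the exact small-sample method is
available below ~25 scans per batch), reporting the count significant at
α = 0.05 before and after harmonization.

## Clustering, consensus and entanglement

Features are z-scored per column (parameters stored for reuse);
distances are Euclidean; linkage is Ward. Neither linkage nor metric is
canonical for this problem — Ward's compactness-seeking behaviour is
chosen for consistency with nearest-centroid mapping, and both are
configurable. Zero-variance features are excluded from the distance with
a warning. Cut labels are renumbered 1..K by descending cluster size,
ties broken by ascending centroid norm (the label convention is ours;
nothing in the method fixes which cluster is "1").

Consensus clustering (Monti resampling): 250 resamples of 80% of scans
without replacement, Ward-clustered and cut at each K in 2–6; the
consensus matrix entry is co-clustering count over co-sampling count.
The area under the empirical CDF of consensus entries is computed
exactly as 1 − mean(entries); K = 2 is scored by its raw area and K > 2
by the relative area increase, and the argmax is selected. Pairs never
co-sampled (possible at low subsampling) get consensus 0 with a warning.
All resampling is driven by a single seeded generator.

Entanglement between two dendrograms on the same scans: with x_i, y_i
the displayed leaf ranks of scan i, the coefficient is Σ|x_i − y_i|^L
normalized by its maximum over permutation pairings — attained by the
order reversal, which the test suite confirms by brute force at small n.
L defaults to 1.5. The optional "step2side" untangling greedily flips
merge-node children on both trees to minimize the coefficient before
measuring; the greedy pass order is made symmetric by evaluating both
argument orders and keeping the better alignment. Identical displayed
orders give exactly 0.

Cluster mapping standardizes the new cohort with the *training* model's
mean/SD (required for centroid comparability — standardizing the new
cohort by its own statistics would silently re-center the batch), then
assigns each scan to the Euclidean-nearest centroid, ties to the lower
label. In the pipeline the independent cohort is first harmonized with
the training-fit ComBat model, since the centroids live in harmonized
space.

The "statistical significance" of a clustering is reported by an
interpretive permutation-style check (between/within sum-of-squares
ratio against Gaussian data matched to the pooled moments); no canonical
test exists for this quantity and it is labelled as an interpretation.

## Association reporting

Continuous covariates: per-cluster mean (SD) and the tie-corrected
Kruskal–Wallis test with chi-square asymptotic p. Categorical: per-
cluster counts and Pearson chi-square; 2×2 tables use the Yates
continuity correction — the default of R's `chisq.test`, and the
convention under which published screening-cohort contingency p-values
reproduce to two decimals. A flat α = 0.05 per test, no multiple-testing
correction, complete-case handling of missing values. Note that the
chi-square asymptotic for Kruskal–Wallis is only loosely calibrated at
n ≤ 8 (exhaustive-permutation comparisons in the tests show gaps up to
~0.2 without ties); at cohort scale this is immaterial.

## Synthetic data

`make_phantom_volume` builds a 64×64×64 voxel, 1 mm isotropic phantom:
exterior air at −1000 HU, a soft-tissue body ellipsoid at +40 HU
(semi-axes 0.44 of the grid extent), and two lung lobes (semi-axes
(0.17, 0.24, 0.34) of extent, offset ±0.20 laterally). The lobe size is
near the largest that keeps a shell thick enough to stop exterior air
leaking into the lung under 26-connectivity. Parenchymal texture is a
Poisson process of Gaussian hyperattenuating blobs plus voxel noise:

| parameter | phenotype 1 | phenotype 2 |
|---|---|---|
| blob density (cm⁻³) | 2.0 | 2.0 |
| blob radius (mm) | 1.5 | 2.5 |
| blob amplitude (HU) | +100 | +120 |
| parenchyma mean (HU) | −850 | −880 |
| noise SD (HU) | 40 | 50 |

Phenotype 2 is the coarser, more heterogeneous parenchyma — larger
texture elements on a lower-attenuation, noisier background, loosely
emphysema-like. Contrast is carried by blob *size* rather than by
density × amplitude because summed blob attenuation must stay below the
vessel-exclusion threshold: overlapping bright blobs that cross the
K-means midpoint punch holes in the segmentation candidate set and make
the phantom unsegmentable, which no realistic parenchymal texture does.

Kernels: "medium" is Gaussian smoothing (σ = 1 mm); "sharp" is an
unsharp mask (amount 1.0, radius 1 mm) on the *same* pre-filter volume,
so paired renderings share anatomy and truth mask exactly — the
smooth/sharp reconstruction contrast reduced to its minimal pair.

Covariates are drawn with screening-cohort parameters: age
~ N(64.8, 5.84²) years, BMI ~ N(27.08, 6.04²) kg/m² plus a
`bmi_effect` (+4 kg/m² default) for phenotype-2 subjects, pack-years
~ N(52.47, 24.85²), balanced sex and smoking status, Lung-RADS group B
with probability 46/308 and cancer with 15/308. Values are clipped only
to plausibility bounds (age ≥ 40 y, BMI ≥ 15, pack-years ≥ 0); tighter
range clipping would truncate the distributions and bias the means away
from their generating values. The BMI effect is a stand-in linking
phenotype to an observable covariate, not a biological claim.

`generate_feature_table` bypasses imaging entirely: 26-feature vectors
from two multivariate-normal populations with a configurable mean shift,
plus per-batch `x·scale + loc` distortions — exactly the location/spread
model ComBat assumes. It drives the harmonization and clustering tests
at sizes where rendering volumes would be wasteful.

What the phantoms do not emulate: airways, vasculature with realistic
topology, nodules, dose/slice-thickness effects, scanner noise texture
(NPS), or spatial covariate structure. Passing tests establish that the
pipeline recovers known structure under its own generative assumptions;
they do not certify performance on real LDCT.

## Problem sizes and determinism

Unit and acceptance tests run phantoms at the 64³ default and
feature-level cohorts of 100–500 scans; the end-to-end pipeline tests
use 6–12 phantom acquisitions (×2 kernels ×3 window sizes), a scale
chosen so the whole suite exercises every stage in a few minutes while
preserving all statistical contrasts. Every stochastic component — the
generators, consensus resampling, permutation checks — takes an explicit
seed, run manifests contain no timestamps, and identical (config, seed)
pairs reproduce every artifact bit-for-bit.

## Known limitations

- The 26-feature list follows the canonical histogram/GLCM/GLRLM
  definitions; variant formulations of e.g. homogeneity or run
  emphases exist in the radiomics literature, and the feature set is
  configuration-driven for that reason.
- The KS batch assessment is two-batch only; multi-batch designs
  harmonize fine but need pairwise reporting outside the package.
- The entanglement untangler is a greedy heuristic; it can stop short of
  the global optimum, so reported coefficients are upper bounds on the
  best achievable alignment (exact at the extremes tested).
- Mapping assumes the independent cohort's features are commensurate
  after ComBat; a cohort with a feature scale unseen in training will
  map, but meaninglessly.
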