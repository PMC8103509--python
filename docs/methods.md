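# Methods

## The synthetic phantom

The generator emulates a stacked-cartridge CT texture phantom: ten slabs,
each filled with one texture, surrounded by air (−1000 HU). The scene is
a fixed, continuous "ground truth" rendered once on a fine master grid
and reused for every virtual acquisition, so all scans image the same
object, as with a physical phantom.

**Layers.** The ten default layers span −900 to +700 HU in base value and
mix spatial-frequency content deliberately: band-limited correlated noise
at two correlation lengths (fine/coarse "cork"), white uniform noise,
lightly smoothed speckle, thresholded smooth blobs, an in-plane linear
gradient, and three periodic structures (checkerboard, triangle-wave
ridges, honeycomb cell walls, lattice grid). Amplitudes (60–120 HU) keep
every rendered intensity inside [−1000, +800] HU. Diversity of scale is
the point: resolution effects on texture features are only visible when
the scene contains structure near the voxel size.

**Master grid.** 0.1 mm in-plane — at least 3.9× finer than the finest
acquisition (0.39 mm), keeping the truth-discretization error negligible —
and 0.3125 mm through-plane. The coarser z grid is deliberate: the z axis
is never resampled, layer thickness is an exact multiple of the 1.25 mm
slice thickness, and the acquisition z grid aligns with layer boundaries,
so slices tile layers exactly and no cross-layer partial-volume mixing
occurs.

**Acquisition model.** (1) in-plane Gaussian blur with the scanner
profile's PSF FWHM; (2) exact box-average of the blurred scene over each
output voxel's physical footprint (prefix-integral implementation, exact
for a piecewise-constant master grid); (3) additive zero-mean Gaussian
noise with sd = `noise_sd_hu + noise_sd_slope / spacing`, so smaller
pixels are noisier, as in real CT where a smaller pixel integrates fewer
photons. ROI masks are produced by majority vote of master-grid labels
within each output voxel. Box-averaging conserves the in-ROI mean, which
the tests assert to within 1 HU across the spacing range.

**Scanner profiles.** Two virtual models ("Discovery-STE": 0.6 mm PSF,
5 + 10/d HU noise; "LightSpeed-Pro-32": 0.8 mm PSF, 8 + 12/d HU noise).
The real scanners' physical differences are not published; these profiles
are stand-ins chosen so that the two models produce visibly different
concordance patterns, not estimates of the actual hardware.

**Extents.** Default layers are 32 × 32 × 3.75 mm (three slices per
layer) with a 2 mm in-plane ROI margin; the `small_spec` preset used by
the end-to-end tests and the acceptance script is 20 × 20 × 2.5 mm
(two slices per layer, 1.5 mm margin), whose ROIs (≈600–3900 voxels
depending on spacing) keep a full study run under a minute.

**What the generator does not emulate.** CT physics — beam hardening,
helical reconstruction, convolution kernels, dose — and anatomical
variability. Passing tests therefore demonstrate that the *pipeline*
behaves correctly and that the qualitative resolution effects emerge
under a controlled imaging model; absolute concordance counts on real
phantom or patient data will differ.

## Feature extraction

91 non-shape features; shape features are excluded because they are
computed on the original geometry and cannot respond to in-plane
resampling. Composition: 18 first-order, 22 GLCM, 16 GLRLM, 16 GLSZM,
14 GLDM, 5 NGTDM. Standard deviation (redundant with variance) and the
deprecated GLCM duplicates Dissimilarity, SumVariance and SumAverage
(linear functions of DifferenceAverage, ClusterTendency and JointAverage
on a symmetric matrix) are excluded; that is what fixes the count at 91.

Conventions: fixed 25 HU bin width anchored at the ROI minimum's bin
(`level = floor(x/W) − floor(min/W) + 1`); population (1/n) variance
throughout; kurtosis without excess correction; GLCM/GLRLM at Chebyshev
distance 1 over the 13 unique 3-D directions, features computed per
direction then averaged; GLSZM zones and GLDM/NGTDM neighborhoods
26-connected; GLDM dependence threshold α = 0. No resegmentation,
clipping, or image filtering.

Degenerate inputs must still produce 91 finite numbers (the CCC is
computed feature-wise, so a single NaN would poison a whole scenario):
zero-variance ROIs take Skewness = Kurtosis = 0, a single-level GLCM has
Correlation = 1 and Imc1 = Imc2 = 0, NGTDM coarseness is capped at 1e6
when its denominator vanishes, and every division guard returns the
formula's documented limit.

Correctness is established two ways: hand-derived examples frozen into
unit tests, and exact count-matrix equality against independent
nested-loop references on random small ROIs (the acceptance suite runs
50 of them per family).

## Resampling

Only the in-plane axes are resampled; slice thickness is a controlled
constant of the study design. The output grid has
`n_out = round(n_in · d_in / NUIR)` voxels per in-plane axis (minimum 1)
and preserves the origin under the voxel-center convention.

Kernels are evaluated separably in source-pixel units. The windowed-sinc
family uses radius m = 5, which probing shows is the radius the reference
toolkit's interpolators actually use (kernel values match
`w(x)·sinc(x)` with m = 5 exactly, support ending at |x| = 5). Per-output
sample the tap weights are normalized to sum to one — this guarantees
exact DC preservation, including near edges where the window is
truncated; the oracle-equivalence test disables normalization to match
the reference convention, which does not normalize. Out-of-support taps
clamp to the edge, avoiding injection of out-of-range HU at boundaries;
ROIs sit interior to the layers, so features are insensitive to the
choice. The Gaussian interpolator uses σ = 0.8 × output spacing with 3σ
support. B-spline (order 3, prefiltered, interpolating) delegates to
`scipy.ndimage.map_coordinates`.

Masks are resampled with nearest neighbor by default — the default must
never blend labels — and LabelGaussian (per-label Gaussian-smoothed
indicators, argmax) is available as the tested alternative; either way
the output label set is a subset of the input's. When a pipeline sweep
requests "LabelGaussian" as the interpolation method, the image takes
the Gaussian kernel and the mask the label-aware one, since a label
interpolator is undefined on continuous intensities.

## ComBat

Canonical parametric empirical-Bayes harmonization: per-feature OLS fit
of batch intercepts (and optional covariates), batch-size-weighted grand
mean α̂, pooled 1/N residual variance; standardized residuals give
per-batch γ̂ᵢ (mean) and δ̂ᵢ² (variance); prior hyperparameters by method
of moments across features; γ*, δ* by iterating the coupled posterior
equations to 1e-4 relative convergence (max 500 iterations). The
transformation divides by √δ* — δ* is carried as a variance — and adds
back α̂ + β̂X. A printed form of the transformation that multiplies by δ*
instead of dividing circulates in the applied literature; the canonical
division is implemented, as only it inverts the model. One batch is a
degenerate case handled as the exact identity. Features with zero pooled
variance cannot be standardized and pass through unharmonized.

Phantom batches are individual scans (10 ROI rows each) and carry no
biologic covariates, so X is empty; the covariate path is retained for
generality and degenerate (constant) covariate columns are dropped.
Before fitting, features with near-zero variance — the same value, after
rounding to 12 significant digits, in ≥ 95% of rows — are removed; such
features make the standardization step ill-conditioned.

The implementation matches Bioconductor `sva::ComBat` to ~1e-14 on a
shared fixture, which the suite asserts through `Rscript`.

A known behavior worth stating: with a uniform injected multiplicative
effect, EB shrinkage of δ̂ toward the batch prior retains the per-feature
sampling noise of the batch variances in the harmonized table, so
post-harmonization variance ratios scatter around 1 with roughly the
χ²(n−1) spread attenuated by the shrinkage weight — at 50 rows/batch
about 80–90% of features land in [0.8, 1.25], not ~100%. This is a
property of the estimator (sva behaves identically), not an
implementation artifact.

## Concordance analysis

Lin's CCC with population moments; identical constant vectors score 1 by
convention. The reproducibility cutoff is strict (ρ_c > 0.9), as is the
Spearman threshold (|ρ| > 0.90). De-duplication is a greedy pass in
canonical catalog order — keep a feature iff it is not highly correlated
with any already-kept feature — because a deterministic survivor rule is
needed for reproducible runs; which member of a correlated group survives
is otherwise arbitrary, so de-duplicated counts are order-dependent by
nature. Constant features (undefined ρ) are kept. In pairwise-ComBat
scenarios the NZV filter and the two-batch fit are applied per scan pair,
and the concordant set is scored over the retained features while the
percentage denominator stays 91; the de-duplication step uses the
unharmonized rows, since per-pair harmonized tables cannot be pooled.

## Problem sizes

The end-to-end tests and the acceptance script use the `small_spec`
phantom with the full 14-scan protocol: a complete approach run (render,
acquire, 140 ROI extractions, 21 CCC pairs) takes a few seconds, and the
whole acceptance study about half a minute on one CPU. The default-sized
phantom scales every stage by roughly 4× and is the intended setting for
interactive use and the CLI.

## Known limitations

* The synthetic scanner profiles are stand-ins; absolute concordance
  counts are not comparable to physical-phantom values, only the
  qualitative structure (decay with spacing gap, benefit of windowed-sinc
  resampling, behavior of ComBat) is.
* The feature catalog is a reconstruction of a 91-feature non-shape set;
  other extractors' catalogs may differ by a few members, so real-data
  comparisons of intersection counts should tolerate small set
  differences.
* Nonparametric ComBat priors and reference-batch mode are out of scope.
* Interpolation is evaluated in-plane only; 3-D isotropic voxel
  resampling is a different design question.
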