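# Methods

## The radial-position model

The unit of analysis is a segmented interphase nucleus, represented as a
voxel set with physical spacing (z, y, x) in µm.  Radial position of a
point is expressed through a per-voxel coordinate that increases from
the nuclear center to the border; the nucleus is then split into K
shells of equal volume by cutting that coordinate at its empirical
k/K-quantiles over mask voxels (K = 5 throughout the shipped analyses;
shell 1 is innermost).  A FISH signal's shell is the shell of the voxel
containing its centroid.  Condition effects on a chromosome's radial
placement are tested by a 2×K Pearson chi-square test of homogeneity on
the pooled shell counts of the two conditions.

Two radial coordinates are provided:

- **edt** (default): 1 − d/d_max, where d is the Euclidean distance
  transform to background in µm.  Its level sets are inward offsets of
  the nuclear surface, it is defined for arbitrary mask shapes, and the
  quantile construction guarantees equal shell volumes to within one
  voxel.
- **ellipsoid**: the Mahalanobis-type scale s at which the voxel lies on
  the s-scaled fitted ellipsoid; level sets are scaled copies of the
  fitted surface.

The two coordinates agree exactly on a sphere but diverge with
flattening, because an offset surface of an ellipsoid is not a scaled
ellipsoid: measured voxel-level shell agreement is ≈96% for a sphere,
≈93% at flattening 1.2, ≈87% at 1.5 and ≈73% at 2.7 (the default
myoblast shape), with disagreements confined to bands around shell
boundaries (≥99.5% of disagreeing voxels move by a single shell).  The
choice of coordinate is therefore a real analytic decision; it is
recorded in all output metadata, and synthetic ground-truth shell
indices are always generated with the same mode the pipeline uses, so
parameter-recovery results measure pipeline error rather than the
mode discrepancy.

Quantile cuts break ties deterministically in raster order.  This makes
runs bit-reproducible, at the price that a voxel whose coordinate equals
a boundary value exactly may land in either adjacent shell after a grid
rotation — shell volumes are unaffected.

## Morphometry

The nucleus ellipsoid is estimated from the second moments of the voxel
coordinates: semi-axes √(5λᵢ) of the eigenvalues of the coordinate
covariance (the inertia-equivalent ellipsoid, exact for a uniformly
filled ellipsoid), orientation from the eigenvectors.  Volume is voxel
count × voxel volume, not the fitted ellipsoid volume.  Flattening is
defined as a/c, the ratio of longest to shortest semi-axis —
dimensionless, ≥1, monotone in the intuitive notion of a nucleus being
"flatter"; comparisons of flattening values are only meaningful within
this definition.  Masks whose voxel volume differs from their fitted
ellipsoid volume by more than ±25% are flagged as non-ellipsoidal
(touching nuclei, debris) and excluded from morphometry; no watershed
splitting is attempted.

Volume and flattening samples of this kind are typically non-normal, so
group comparison uses the two-sided Mann-Whitney U test (exact
enumeration for n1+n2 ≤ 12 without ties, otherwise the tie-corrected
normal approximation), with Shapiro-Wilk p-values reported alongside to
document the normality gate.

## Imaging

Segmentation: Gaussian pre-smoothing (σ = 0.3 µm), global Otsu
threshold, 3-D connected components with 26-connectivity, per-z-slice
hole filling, minimum volume 50 µm³, labels ordered by descending
volume.  The scheme replaces the original study's closed-source
reconstruction software with a standard, parameter-exposed equivalent.
Otsu on a 256-bin histogram makes segmentation invariant to positive
intensity scaling.

Spot detection: negated Laplacian-of-Gaussian filtering with per-axis σ
set in voxels from a single physical spot radius (default 0.4 µm), 3-D
local maxima (3³ footprint), threshold at mean + k·sd (k = 5) of the
filtered response inside the nucleus masks, sub-voxel centroid by
intensity-weighted mean over a 3³ neighbourhood of the raw channel.
Spots whose centroid lies outside every mask are discarded and counted;
a centroid that rounds to a voxel just outside its mask after sub-voxel
refinement is snapped to the nearest mask voxel within one voxel.

All physical quantities use the voxel spacing; coordinates follow the
convention voxel center = index × spacing, ordered (z, y, x).

## Synthetic data: what it emulates, what it does not

Nuclei are ellipsoids with log-normal per-axis size variation
(CV = 0.08) and uniformly random orientation, voxelized at
(0.5, 0.2, 0.2) µm spacing.  Defaults: myoblast-like semi-axes
(8, 6, 3) µm; myocyte-like nuclei scaled anisotropically
(×7/8, ×1, ×2/3) so they are smaller and flatter, matching the observed
direction of the differentiation effect.  Absolute nucleus dimensions
are not reported in the source data; these values are typical for
cultured mammalian cells, and only the ordering between conditions is
load-bearing for the analyses.

Spots: 2 per nucleus by default (a diploid autosome pair); a shell index
is drawn from the configured probability vector and a voxel uniformly
from that shell, with a sub-voxel jitter confined to the voxel, so true
shell labels are exact.  Rendering convolves both channels with an
anisotropic Gaussian PSF (σ = (0.6, 0.25, 0.25) µm), then applies
Poisson photon noise and additive Gaussian background (counterstain
plateau 100 photons, 500 photons per spot, background 10, read noise
σ = 2) — a plausible confocal photon budget; the source study reports
no acquisition statistics.

Not emulated: myotube syncytium geometry (each nucleus is rendered in
its own field of view), chromatin texture, optical aberrations beyond a
Gaussian PSF, spot clustering or overlapping homolog signals, and
segmentation-relevant artefacts such as touching nuclei.  Passing
recovery tests therefore demonstrates correctness of the measurement
chain under these idealised conditions, not robustness to crowded or
aberrated real images.

Expression matrices are log2-scale Gaussian (per-gene baseline uniform
in [4, 12], noise sd 0.25), triplicate per group, with a 5% spike
fraction shifted ±3 log2-units in group 2 by default.

## Statistics

- **Chi-square homogeneity** (2×K, no continuity correction): expected
  counts from margins, df = K′−1 after dropping zero-total columns (with
  a warning).  Expected cells < 5 raise a warning flag, not an error —
  sparse outer shells make them unavoidable at these sample sizes.  The
  seven chromosomes are tested separately without multiplicity
  adjustment, matching per-chromosome reporting conventions.
- **Count reconstruction**: the smallest n ≤ 1000 such that
  c_k = round(n·p_k/100) sums to n and reproduces every percentage at
  two decimals.  Rounding is half-away-from-zero, the convention of
  printed tables (numpy's default half-even fails on exact .005 cases).
  All 14 packaged rows reconstruct exactly, with totals 68–128 —
  consistent with ~50±8 scored nuclei carrying ~2 signals each.
- **Differential expression**: per-gene two-sample t-test on log2
  values, pooled variance by default.  With triplicates, Welch's
  Satterthwaite df is estimated from two 2-df variances and collapses
  toward 2; in simulation at the default settings this cuts the power of
  the 2-fold + BH(q<0.01) filter from ≈0.9 (pooled) to ≈0.3.  Pooled is
  therefore the default and `welch=True` an option for genuinely
  heteroscedastic designs.  The significance threshold applies to
  BH-adjusted q-values over all tested genes; a raw-p mode exists behind
  a flag.

## Problem sizes and numerical choices

The shipped validation runs use 50 nuclei per condition (≈100 spots per
condition) for pipeline parameter recovery, 1,000 replicates × 200
spots for the uniformity-null calibration, 10,000 replicates for
chi-square type-I calibration, and 2,000 genes for expression power —
sizes at which the Monte-Carlo bands quoted in the tests are stable.
All randomness derives from a single seed through substreams keyed by
stage name, so adding a stage never perturbs another stage's draws and
every run is bit-reproducible.

Known limitations: no watershed separation of touching nuclei, no
deconvolution or chromatic/drift correction, no probe-level microarray
processing (the expression stage starts from a gene-level matrix), and
chi-square power at ~100 signals per condition is modest — true
distribution differences of the magnitude seen in the packaged table
are detected in most but not all simulated replicates.
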