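# Methods

## Preprocessing chain

A centroid spectrum is a list of (m/z, intensity) peak apexes. The fixed
chain applied before any modeling is: RMS normalization → binning → ROI
averaging.

* **RMS normalization** divides the intensity vector by its root mean
  square, computed over the detected centroids only (not over a resampled
  profile). The output has RMS exactly 1 and is invariant to global
  intensity scaling, which removes pixel-to-pixel ionization-efficiency
  differences.
* **Binning** accumulates centroids onto half-open bins
  `[lo + i·w, lo + (i+1)·w)` anchored at the lower mass limit; defaults are
  m/z 600–950 with w = 0.2 Da, i.e. 1750 bins. Centroids outside the range
  are dropped; within a bin intensities are *summed*, conserving ion count.
  A centroid at exactly 600.0 lands in bin 0; 950.0 is out of range.
* **ROI mean**: each pixel is normalized, then binned, then the vectors are
  averaged element-wise. The order matters — averaging before normalizing
  weights bright pixels more — and is fixed as normalize → bin → mean. The
  ROI mean is *not* re-normalized afterward; downstream components consume
  it as is, so the convention must be respected when comparing against
  other implementations.

## Recognition model

PCA retains the smallest component count whose cumulative explained
variance reaches `variance_kept` (default 0.95), capped at rows − 1. In PCA
space, multiclass Fisher LDA solves the generalized eigenproblem
S_B w = λ S_W w with pooled within-class scatter S_W; eigenvectors are
scaled so the pooled within-class variance per direction is 1 and signs are
fixed by a largest-coefficient convention, making the fit deterministic. If
S_W is exactly singular (e.g. duplicated rows), a ridge of
1e−8 × trace(S_W)/k is added with a warning.

**Outlier rule.** Each class's dispersion is the root-mean-square Euclidean
distance of its training points from its class centroid in discriminant
space — equivalently the square root of the summed per-direction variances.
A spectrum whose distance to the *winning* centroid exceeds
`multiplier × dispersion` (default multiplier 3) is declared `OUTLIER` in
outlier mode. The scalar-per-class form was chosen over a per-direction SD
because the rule compares against a full d-dimensional Euclidean distance:
with C classes the discriminant space has up to C−1 directions, and for a
roughly isotropic class cloud the typical distance is √d per-direction-SDs,
so a per-direction threshold of 3 SD would reject most of the training data
itself once d exceeds ~9. The RMS-distance form keeps the familiar "3
standard deviations" reading while scaling correctly with dimension.
Dispersions are floored at 1e−6·(1 + ‖centroid‖) so that noiseless,
perfectly duplicated training classes remain classifiable. Ties in the
nearest-centroid step break toward the lexicographically smallest class
label. Whether the reference implementations this mirrors compute their
dispersion per class or pooled, in PCA or LDA space, is not documented
anywhere we know of; the choice here is explicit and serialized with the
model.

**Evaluation.** Stratified k-fold cross-validation (default k = 5; folds via
scikit-learn's `StratifiedKFold`, shuffled under the given seed) refits the
full PCA/LDA model on each training split and classifies the held-out fold
in outlier mode. Two rates are reported: excluding outliers
(correct / non-outlier predictions) and including outliers (correct / all,
outlier-flagged rows counted as errors); the first is always ≥ the second.
The holdout variant splits each class at `round(2/3 · n)` training rows
(minimum 2, maximum n − 1). The outlier rule is applied at prediction time
only; training rows are never trimmed.

## Tissue mapping and streaming

`classify_image` applies the preprocessing chain and the classifier to every
measured pixel; pixels absent from the image or with all-zero spectra are
`UNMEASURED` and excluded from the area-percentage denominator, so reported
percentages always total 100% of the measured region. Streaming mode
(`stream_classify`) is stateless per spot: each spectrum is preprocessed and
classified independently and its event emitted before the next spectrum is
consumed, which makes label-for-label equivalence with the batch map exact
by construction. Per-spot latency is recorded; classification cost per
spectrum is one projection (O(bins × PCA components)) plus C centroid
distances, well under a millisecond at the default grid.

## Cross-instrument comparison

Per-cell lipid intensities from different instruments are divided by the
cell's intensity of a reference lipid (PC 34:1 in the default workflow),
which cancels instrument-global sensitivity factors. Each non-reference
lipid's ratios are then tested with a one-way ANOVA across instruments:
F = MS_between / MS_within with df (instruments − 1, cells − instruments),
compared against the upper-α F quantile (α = 0.05 default). With 6
instruments and 3 replicate cells the critical value is F(5, 12) ≈ 3.106.
Each lipid is tested against the single critical value with no multiplicity
correction, mirroring the per-lipid verdict this analysis reproduces; a
Bonferroni option exists but is off by default. Zero within-group variance
with nonzero between-group variance reports F = +∞. The report carries one
df pair, which assumes every lipid is observed in every replicate profile —
the natural shape of the long-form input CSV.

## Synthetic data generator

The generator produces data with the statistical structure the analysis
assumes, with known ground truth.

* **Panel**: 79 lipids in m/z 600–950. PC 34:1 (760.585 Da) and PC 36:1
  (788.610 Da) carry literature [M+H]+ masses; the other 77 are synthetic
  species at fixed masses ≥ 0.3 Da apart (so distinct lipids rarely share a
  0.2 Da bin), drawn once from a hard-coded stream.
* **Class profiles**: one Dirichlet(5)-drawn base composition shared by all
  classes, modulated multiplicatively by sparse log-normal perturbations
  (≈25% of channels, log-scale SD 0.6) at two levels — one shared within
  each receptor subtype and one specific to each line — both scaled by the
  `separation` parameter and renormalized to sum 1. Every class therefore
  contains the same lipids in different ratios, lines within a subtype
  resemble each other more than lines across subtypes, and `separation = 0`
  collapses all classes onto the base. The subtype-level component exists
  because receptor subtypes are biologically coherent lipid phenotypes: a
  grouping of otherwise arbitrary line profiles carries no subtype signal a
  2-direction LDA could recover, which would misrepresent the system being
  emulated.
* **Spectra**: one centroid per panel lipid, intensity = scale × abundance ×
  unit-mean lognormal noise with coefficient of variation `noise_cv`
  (default 0.05 — a modeling choice; no quantitative within-culture
  variance is published for this assay). Multiplicative lognormal noise
  keeps intensities positive and CV-stable, matching the ratio-based
  analysis downstream. Sparse low-intensity background peaks (Poisson mean
  8, 0.05–0.5% of scale) are placed > 0.06 Da away from any panel mass.
* **Single-cell images**: 5 µm pixels; cells are disks with diameters
  uniform in 20–150 µm, placed without overlap (largest first, rejection
  sampling; failure reports how many were placed). A pixel belongs to a
  cell iff its center lies inside the disk; at 5 µm pixels every ≥ 20 µm
  cell covers ≥ 4 pixels. Background pixels carry background-only spectra.
* **Tissue images**: 30 µm pixels; an elliptical tumor region of one class
  with a contiguous necrotic subregion grown breadth-first to
  `round(fraction × tumor pixels)` pixels. Necrotic spectra use the tumor
  profile mixed 50/50 with a uniform profile at 10% intensity — distorted
  and dim enough to violate the 3-dispersion rule, as necrosis should. The
  background border is unmeasured by default (the measured region is the
  section), so area percentages refer to tissue; `include_background=True`
  restores measured background pixels.

What the generator does **not** emulate: isotope envelopes, ion mobility,
matrix clusters, mass-calibration drift, chimeric boundary pixels between
touching cells, within-class covariance structure beyond independent
per-channel noise, and staining-registration error. Passing tests therefore
demonstrate the pipeline's correctness and its behavior under the stated
noise model, not performance on real tissue.

## Problem sizes and defaults

The reference operating regime used throughout the tests and the
reproduction script is 14 classes × 16 cells (224 library spectra) at
separation 1.0 and noise CV 0.05 on the default 1750-bin grid — a scale at
which the full fivefold cross-validation runs in well under a minute. Under
these conditions both evaluation levels classify essentially perfectly
(rates at or near 100%), tissue maps recover the necrotic share as
`OUTLIER` within a few pixels, and spectra of a class absent from the
library are rejected as `OUTLIER` in ≥ 90% of draws at separation 2.

## File formats

Images: processed-mode imzML (via pyimzml; a `<name>.meta.json` sidecar
carries pixel size and grid shape, which imzML written by pyimzml cannot)
or a CSV dialect `row,col,mz,intensity` with a metadata comment line.
Coordinates are 0-based (row, col); imzML's 1-based x/y map as x = col + 1,
y = row + 1. ROI tables are CSV `cell_id,row,col,label`; label maps CSV
`row,col,label`; libraries CSV with a grid comment line; models a versioned
JSON text document whose repr-precision floats restore bitwise. All writers
stage to a temporary file and rename atomically. Zero-pixel images are
written as a minimal processed-mode imzML stub, since pyimzml cannot
round-trip an empty spectrum list.
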