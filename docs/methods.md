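# Methods

## Model and assumptions

The composite index is the first principal component of four min–max
normalized indicators.  The construction assumes that (i) the indicators are
each monotone proxies of ecosystem quality — greenness (NDVI) and moisture
(tasseled-cap WET) rising with quality, dryness (NDSI) and either heat (LST,
for RSEI) or particulate load (DI, for DRSEI) falling with it; (ii) min–max
normalization makes their scales commensurate, so PCA on the **covariance**
matrix (not the correlation matrix) is meaningful — normalizing and then
standardizing again would defeat the purpose of letting spatially variable
indicators carry more weight; and (iii) the dominant shared axis of variation
is ecological quality, so PC1 is interpretable as the index.

Consequences worth keeping in mind:

- **The index is relative per scene.**  Normalization minima/maxima are
  computed per scene (per date).  Comparing absolute index values across
  dates assumes comparable scene extremes; level classification and change
  grading inherit that assumption.  Cross-date harmonization is deliberately
  left to the caller.
- **Loadings follow spatial variability.**  An indicator with little spatial
  variation relative to its normalized range contributes little variance and
  receives a small |loading|, regardless of its ecological importance.  This
  is a property of the weighting mechanism, not a bug; the synthetic suite
  tests it directly (see below).

## Pipeline and numerical choices

1. **Preprocessing** (`raster_io`): Collection-2 reflectance scaling
   (2.75e-05, −0.2) applied at read time under `SensorProfile` control; cloud
   contamination decoded from QA bits {1 dilated cloud, 3 cloud, 4 shadow} by
   default; repeat acquisitions combined by the per-pixel median over valid,
   cloud-free contributors (an even count takes the mean of the two middle
   values); residual gaps filled from a secondary acquisition, never touching
   valid primary pixels.
2. **Indicators** (`indicators`): formulas as given in the README.  Pixels
   with an exactly zero denominator are invalidated, not clamped.  Open water
   (MNDWI > 0) is removed from **all four** indicators' masks, not just WET,
   so the PCA sample is identical across components.  DI is computed from
   surface reflectance to keep units and resolution aligned with the rest.
3. **Fusion** (`composite`): population (1/N) covariance of the jointly valid
   pixel vectors; `numpy.linalg.eigh`; components sorted by descending
   eigenvalue; eigenvector signs first fixed deterministically
   (largest-|entry| positive), then PC1 oriented by the ecological rule
   NDVI loading ≥ 0 (tie → WET sign).  PC1 scores are mean-centered
   projections; the final index is their min–max normalization, so index
   minima and maxima are exactly 0 and 1 on valid pixels.  An optional
   `max_samples` (seeded) subsamples the covariance estimate for very large
   rasters; scores are always computed for every pixel.
4. **Assessment** (`assessment`): levels at 0.2 intervals with half-open bins
   and a closed top bin ([0.8, 1.0]), so boundary values join the upper level
   and exactly five codes cover [0, 1]; binning uses `floor(5·x)` to keep
   exact boundaries stable in floating point.  Change codes are level
   differences in [−4, 4]; category areas are pixel counts × pixel area from
   the affine transform.  Mean centers are unweighted pixel-center means in
   the projected CRS.  Zonal membership is pixel-center-in-polygon with no
   partial-pixel weighting; the EI comparison scale defaults to 100.
5. **Validation** (`validation`): population (1/N) moments throughout (no
   Bessel correction).  The centered RMS difference is the square *root* of
   the mean squared anomaly difference — the only form satisfying the Taylor
   law of cosines E′² = σf² + σp² − 2σfσpR, which the statistics are checked
   against at 1e-10 on every sample.

## File formats

GeoTIFF I/O is implemented with tifffile.  Georeferencing is carried in the
standard GeoTIFF ModelPixelScale/ModelTiepoint tags plus a JSON
ImageDescription holding the full 6-parameter affine, CRS identifier, band
names, sensor and nodata, which is what makes write→read round-trips
bit-exact (the validity mask of a multiband stack is stored as an extra
plane).  Region polygons are GeoJSON; EI tables are CSV (region_id, ei).

## The synthetic-scene generator

`synthetic.generate_scene` emulates the statistical structure the method
assumes, not radiometry.  A latent quality field q ∈ [0, 1] rises radially
from an urban core to the rural edge (plus Gaussian-smoothed spatial noise,
kernel 3 px).  Bands are linear in q and in a diffuse pollution term
`di_variability · (1 − q)` entering red (+0.10) and NIR (−0.10)
antisymmetrically, with slopes chosen so NDVI and WET rise with q while NDSI,
DI and the Kelvin ST band fall.  A small fraction (0.5 %) of pixels are
persistent particulate point sources (red +0.15, NIR −0.12) whose contrast
does **not** scale with `di_variability`: they anchor the DI band's extremes,
so shrinking the diffuse contrast shrinks DI's normalized bulk variance and
hence its PCA loading — the spatial-variability→loading mechanism as a
testable property (with `di_variability = 1/√10` the diffuse DI variance is
exactly ten times smaller, verified on the noise-free, point-source-free
counterpart).  Water pixels get fixed band values with green ≫ swir1 so
MNDWI > 0 by a margin far exceeding the band noise; cloud pixels are bright,
cold and flagged with QA bit 3.  Per-band noise is smoothed white noise of
standard deviation `noise_sd` (default 0.015 reflectance; 40× that in Kelvin
for ST).  All randomness flows from one seeded generator; no global state.

Default conditions: 96×96 pixels at 30 m, 25 % urban, 5 % water, 5 % cloud.
District tilings are exact rectangular partitions on pixel boundaries; the
standard validation setup uses a 6×6 grid (36 districts), where the
county-mean index–EI correlation is stable seed to seed (the regional EI
spread is ≈12 index points, so reference noise of sd 5 attenuates the
correlation only mildly).  Reference EI is 100 × regional mean latent quality
plus Gaussian noise, clipped to [0, 100].

What passing tests on these scenes does **not** show: robustness to
atmospheric or BRDF effects, sensor cross-calibration, mixed pixels at water
edges, seasonal phenology, or real EI's multi-component construction — the
generator's quality→band mapping is linear and its noise Gaussian, so the
synthetic results demonstrate correctness of the machinery and the internal
mechanisms, not real-world retrieval accuracy.

## Problem sizes

Tests and the acceptance script use 96×96 scenes, 10 seeds for parameter
recovery, a 10,000×4 sample for the PCA-vs-oracle check and 100 random pairs
for the Taylor identity; the whole suite runs in a few seconds.

## Known limitations

- No reprojection: stacks must already share a grid and CRS (mismatches are
  errors, not resampling triggers).
- The ST band is taken as product Kelvin; no emissivity retrieval, and
  `SensorProfile` applies no separate thermal scale/offset.
- Constant indicators (zero range) are degenerate-input errors rather than
  being silently dropped from the PCA.
- `average_correlation` implements the mean-of-absolute-pairwise-correlations
  summary only; assembling the pairwise matrix is left to the caller.
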