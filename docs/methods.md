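# Methods

This note documents the models behind `crownid`, the parameters that matter,
and the choices made where the underlying procedures are under-specified in
the literature. Nothing here states an empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Synthetic forest and sensor simulation

### What the generator emulates

The simulator produces the minimal structure that makes crown-level species
classification a well-posed problem:

- **Stem maps** with a minimum spacing constraint; species counts follow the
  requested mixture by largest-remainder apportionment (exact to one stem),
  then shuffle over positions.
- **Crown envelopes**: cones for conifers, ellipsoid caps (or paraboloids)
  for broadleaves, with height, crown ratio and radius drawn per species.
  Twelve species profiles mirror the hardwood/softwood composition of a
  Great Lakes–St. Lawrence mixed forest. Heights span pole-size to mature
  stems; crown radius ≈ 0.13–0.26 × height (broadleaves wider).
- **Returns**: one emitted pulse is a nadir ray — scan geometry is abstracted
  to a pulse density plus vertical jitter because nothing downstream consumes
  per-pulse trajectories. A canopy pulse returns from an exponential depth
  below the envelope with scale 1.2 m ÷ the species' foliage density, so
  dense conifer crowns return from nearer the surface. A fraction of canopy
  pulses (the sensor's *second-return propensity*) yields a second return,
  which reaches the ground with a per-wavelength *canopy penetration*
  probability and otherwise stops deeper in the crown.
- **Intensities**: log-normal per species and wavelength with a stated
  coefficient of variation. Green (532 nm) foliage backscatter is low,
  near-infrared (1064 nm) high — brighter for broadleaves than conifers —
  and shortwave-infrared (1550 nm) intermediate, so multispectral
  normalized-difference indices are discriminative by construction.

### Sensor regimes (defaults)

| | linear monospectral | linear multispectral | single-photon |
|---|---|---|---|
| wavelengths (nm) | 1550 | 532 / 1064 / 1550 | 532 |
| density (pts/m²) | 5.8 | 4.8 / 12.4 / 11.9 | 28.6 |
| P(2nd return) | 0.45 | 0.50 | 0.08 |
| P(2nd reaches ground) | 0.45 | 0.12 / 0.45 / 0.42 | 0.10 |
| solar noise (pts/m²) | 0 | 0 | 0.25 |
| intensity | continuous log-normal | continuous log-normal | quantized pulse-width analogue |
| ranging noise σ (m) | 0.05 | 0.05 | 0.12 |

The densities and the qualitative contrasts (green-channel penetration
deficit, single-photon second-return deficit and solar noise) are the stated
acquisition characteristics being emulated; the remaining values are one-time
field-realistic choices. Pulse counts are calibrated so the *realized*
aggregate density matches the nominal one: second returns inflate the count
by P(2nd) × canopy fraction, which is estimated on a deterministic probe
grid before sampling.

Single-photon intensity is deliberately degraded: the log-normal draw is
blurred (extra ×log-normal(σ=0.6)) and quantized to at most eight discrete
levels. This mimics an intensity that is only a pulse-width analogue — the
derivation real vendors use is not public, so this is a stated assumption,
not a reconstruction — and it makes single-photon intensity features the
weakest of the three sensors, as the tests verify.

### What the generator does NOT emulate

Full waveforms, scan-angle and range effects, flight-line overlap, vendor
return-detection and ground-classification algorithms, off-nadir crown
displacement, understory vegetation, and species mixtures within one crown.
A green test therefore establishes that the *pipeline machinery* recovers
known structure under the stated model — not that real-forest accuracies
would match.

### Noise filtering

The solar-noise filter is a voxel-occupancy density filter standing in for
vendor differential cell-count filters whose parameters are unpublished:
points whose 3×3×3 voxel neighbourhood (1 m voxels) holds fewer than 4
points are removed. On the simulator's own output this retains ≥ 99 % of
canopy points and removes ≥ 90 % of injected uniform noise.

## Terrain models

- DTM: Delaunay TIN over ground-classified returns, evaluated at cell
  centres; exact for planar ground (a property test); nodata outside the
  convex hull. Ground labels are taken from the input cloud (the simulator
  provides them; vendor classifications play this role for real data).
- DSM: highest return per cell; empty cells filled from a TIN of first
  returns so the surface has no interior holes. The point rule is a design
  choice — only the TIN algorithm itself is standard.
- CHM = DSM − DTM clipped at 0; 0.25 m cells by default.
- Registration: cell (i, j) is centred at origin + (j+½, i+½)·cell, row 0 at
  the southern edge; fixed so rasters round-trip bit-exactly through GeoTIFF.

## Crown delineation

The delineator follows the classic raster recipe. All constants below are
package defaults, calibrated once on synthetic cone/ellipsoid scenes and
fully exposed in `SegmentationParams` — operational segmenters state the
*laws* (σ and exclusion radius proportional to local height) but not the
constants.

- smoothing σ(h) = max(0.5, 0.06·h / cell) pixels, implemented as a bank of
  quantized σ levels with normalized convolution around nodata;
- treetop exclusion radius r(h) = max(1.0, 0.15·h) m; a treetop must exceed
  every pixel within its radius; equal-height ties break toward the lowest
  (row, col) for determinism. The implementation is verified against an
  exhaustive per-pixel oracle on small grids;
- region growing: marker watershed on the inverted smoothed CHM, then a stop
  rule removes pixels below 0.3 × apex height (the growth-stop fraction;
  "much smaller than the maximum" is not quantified anywhere) and keeps the
  component containing the apex; minimum crown area 3 m²;
- attributes are computed on the *unfiltered* CHM (height = max unfiltered
  value in the crown); the delineation score is a weighted mean of
  piecewise-linear plausibility sub-scores for crown ratio (ideal 0.3–0.9),
  circularity (≥ 0.4), height-to-area ratio (0.05–2 m⁻¹), crown area
  (5–250 m²) and compactness (1 − eccentricity, ≥ 0.3), uniform weights;
- resegmentation: crowns flagged by low score (< 0.45), an outlying
  height-to-area ratio (outside 0.02–6), or eccentricity > 0.7 are eroded
  until they fall into ≥ 2 substantial components, each holding its own
  height maximum; the original region is then re-flooded from those maxima,
  so labelled area never grows. Crowns that never split are left untouched.

The eccentricity flag is the calibrated operationalization of "improbable
proportions": on synthetic scenes, merged double crowns show eccentricity
≈ 0.75 while clean crowns stay below ≈ 0.55.

## Features

Feature definitions and the manifest are documented in
`crownid/features.py`. Decisions worth recording:

- **Single-value height normalization**: all returns of a crown are reduced
  by one DTM value at the crown centroid. Per-point normalization is
  deliberately avoided because it warps crown shape on slopes (a test checks
  within-crown height differences are preserved exactly on a slope).
- **2 m cutoff**: returns at or below 2 m above ground are discarded before
  any feature is computed.
- **34 geometric features**: the return-type-ratio family (RM) is
  under-determined by published feature tables; this package fixes
  {mean, p25, p50, p75} height-statistic ratios over the pairs 1st/all,
  2nd/all, 2nd/1st plus the three return-count ratios (15 features), which
  closes the set at 34. RM entries involving second returns are *missing*
  (not zero) for crowns without second returns — such crowns cannot train a
  forest and are flagged, then dropped at training time. This is the
  mechanism by which single-photon and green-channel data lose crowns.
- **Percentiles** use linear interpolation (numpy's default) everywhere; the
  intensity-at-height-percentile feature takes the first return whose height
  is nearest the percentile, ties toward the lower height. Both are verified
  against literal brute-force oracles on small point sets.
- **Normalized differences** use the (longer − shorter)/(longer + shorter)
  sign convention on matched per-channel statistics (mean, p50, p75); simple
  ratios are shorter/longer. No intensity range-normalization is applied
  (range information is not modelled).
- Multispectral three-channel data: 3D features are computed on the pooled
  cloud; intensity features per channel (16 × 3) plus 18 cross-channel
  indices = 66 intensity features. Published counts give 65 for this
  configuration without an enumeration; the one-feature discrepancy is
  accepted and recorded rather than hidden.

## Classification

- **Balanced random forest**: per tree, a bootstrap of minority-class size is
  drawn *within each class* (with replacement); trees are sklearn CARTs with
  √p feature subsampling; 500 trees by default. OOB predictions aggregate
  votes from trees whose bootstrap missed the sample. The per-tree
  downsampling variant was chosen over per-forest downsampling (the
  alternative discards data permanently).
- **MDA** is the raw OOB permutation importance in accuracy percentage
  points, averaged over all trees (trees that never split on a feature
  contribute zero — the classic convention). The retention threshold 0.1
  therefore reads "permuting this feature costs ≥ 0.1 points of OOB
  accuracy". It is a weak pre-filter by design: pure-noise features average
  ≈ 0 but single-forest estimates fluctuate by ±1–2 points, so some noise
  survives to the later stages, which is harmless.
- **Correlation filter**: Pearson |r| > 0.9 on raw feature values; features
  are admitted in descending-MDA order so the higher-MDA member of every
  over-correlated pair survives; the removal log records each drop.
- **VSURF-style selection**: (1) rank by mean MDA over 50 forests and drop
  features below a null threshold (mean + 1 sd of the magnitudes of negative
  MDAs — negative MDAs can only arise from noise); (2) ascend through the
  ranking, keeping a feature iff it lowers mean OOB error (over 3 forests)
  by more than one between-forest sd. Per-step errors are logged. Selection
  runs once; the 20 evaluation runs then vary only the forest seed — the
  ordering of steps in the standard protocol implies selection precedes the
  repeated runs.
- **Evaluation**: mean OOB accuracy over 20 seeded runs; the confusion
  matrix, per-class accuracies and Gini ranking come from the first
  (designated) run. "Top 25/15" subsets are taken by Gini importance of the
  full model, the ranking statistic not being specified elsewhere.
  Shapiro–Wilk normality checking is not implemented as a gate anywhere;
  the forest makes no normality assumption.
- **Percent reporting**: percentages pass through one decimal place before
  integer rounding (both half-up). This two-stage convention is what makes
  published per-class tables internally consistent (e.g. 81/146 → 55.5 → 56).
- **NOCAI** = accuracy × k, reported to one decimal (half-up), where 1/k is
  the expected accuracy of random assignment over k classes.

## Test-suite scaling

The default protocol (500 trees, 50 VSURF permutations) is kept for library
defaults, but the test and acceptance suites scale it down to fit a
single-CPU time budget: 150-tree forests, 6–10 VSURF permutations, and a
~2.9 ha 12-species stand with 42 stems per species (≥ 35 per class, the
stated worst case). The 20-run OOB averaging protocol itself is retained.
Orderings asserted by the tests (2-class > 4-class > 12-class accuracy;
multispectral intensity > monospectral intensity; pooling never hurts beyond
run noise) are qualitative structure, stable under this scaling.

## Known limitations

- The simulator's species separation is stated, not fitted to any real
  forest; absolute accuracies on synthetic stands do not predict real-data
  accuracies.
- Crown polygons from the raster delineation are cell-boundary contours;
  sub-pixel crown edges are not modelled.
- The single-photon intensity analogue is an assumption (see above).
- No radiometric cross-sensor calibration is attempted; intensity features
  are only comparable within one simulated acquisition.
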