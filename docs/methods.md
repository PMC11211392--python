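# Methods

## Unit of analysis

A single-channel grayscale tile (8- or 16-bit). All parameters are computed
on the whole tile; no background exclusion is applied before the histogram
statistics, matching common practice for SHG field-of-view tiles where the
collagen-free background carries information about deposit density.

## Histogram statistics

Mean, SD, skewness and kurtosis use population (biased) central moments over
all pixels: g₁ = m₃/m₂^1.5 and excess kurtosis g₂ = m₄/m₂² − 3 (Gaussian → 0).
With ~10⁵–10⁶ pixels per tile the sample-correction distinction is
negligible, but fixing the convention makes results bit-reproducible. A
constant tile has undefined shape statistics; these are reported as NaN
sentinels and later dropped per-parameter by the comparison stage.

## Triangle thresholding and TC-ratio

The Triangle (Zack) construction: find the histogram peak, draw a chord to
the farthest nonzero tail bin, and return the bin maximizing perpendicular
distance from the histogram to the chord. Conventions:

- 256 histogram bins for both bit depths; 16-bit data are min–max rescaled
  onto the bin grid and the selected bin is mapped back to native intensity.
- Foreground is *strictly above* the level.
- When both tails are equidistant from the peak, the bright side is used,
  since collagen occupies the bright tail of an SHG histogram.

TC-ratio = foreground count / total pixels. It is exactly invariant under
90° rotation and flips and non-increasing in the level.

## GLCM texture

Co-occurrence at pixel distance 1 in the four standard directions, counted
symmetrically ((i,j) and (j,i)) and normalized to sum 1; features are
averaged over the four directions, which makes them exactly invariant to 90°
rotations and flips. Conventions (not derivable from the feature names
alone, so stated explicitly):

- 256 gray levels; 16-bit tiles are min–max rescaled to 256 levels to bound
  the matrix.
- "energy" is the angular second moment Σp², so a constant tile scores
  exactly 1; "homogeneity" is the inverse difference moment.
- entropy uses log base 2 (a two-entry equiprobable matrix scores exactly 1).
- correlation is undefined (NaN) when a marginal variance vanishes.

## FFT orientation index

The mean-subtracted tile is Fourier-transformed; the zero-centered power
spectrum is binarized automatically and an ellipse is fitted to the
foreground pixel coordinates by second central moments (semi-axes =
2·√eigenvalues of the coordinate covariance — the convention of standard
particle analyzers). N = 1 − S/L ∈ [0, 1]: 0 isotropic, 1 fully aligned. The
fitted major axis is perpendicular to the dominant fiber direction (Fourier
duality).

Numerical choices:

- The threshold (Otsu by default, Triangle optional) is computed on the
  **raw** power values with the DC pixel excluded. Spectral power is
  heavy-tailed, so this isolates the dominant low-frequency lobe (~0.1% of
  pixels) whose shape carries the anisotropy. A log transform before
  thresholding was evaluated and rejected: it flattens the spectrum so the
  automatic foreground swells to 10–40% of the plane and the measured N no
  longer increases with planted alignment.
- If the automatic threshold keeps fewer than 0.1% of pixels (extremely
  aligned fields concentrate nearly all power in a handful of pixels), the
  brightest 0.1% are used instead so the degenerate N → 1 limit remains
  measurable. Fewer than 5 foreground pixels is an error.
- No windowing before the FFT; tiles are large and leakage mainly affects
  the excluded DC cross.
- N is exactly scale-invariant up to threshold-boundary ties (spectra of
  real images contain bitwise-equal centro-symmetric pairs; a rotation or
  rescale can move one tied pixel across the threshold, changing N by ≲0.01).

## Fractal dimension

Box counting on the Triangle-thresholded mask: origin-anchored s×s grids,
partial edge boxes counted, sizes the powers of 2 from 2 to min(height,
width)/4, and D the least-squares slope of log N(s) against log(1/s). The
power-of-2 ladder tiles power-of-2 tiles exactly and makes fits
reproducible; multi-offset grid averaging is deliberately not applied.
Reference values: filled square D = 2, straight line D = 1, depth-5
Sierpinski carpet D ≈ log 8/log 3 = 1.893, all recovered within 0.05.

## Group comparison

Per parameter: two-sided unpaired Student's t (pooled variance,
df = n₁+n₂−2); Welch's correction behind a flag. "Significance" is p < 0.05
by default with no multiple-testing correction across the twelve parameters
(Bonferroni/Holm available behind a flag but off, matching the convention of
reporting each parameter at nominal level). D'Agostino–Pearson omnibus
normality (K² = z(g₁)² + z(g₂)², χ²₂) is reported per group as a flag; a
non-normal flag does not change the test. 95% CIs of group means use the
t-distribution. NaN sentinel rows are dropped per parameter; a parameter
with fewer than 3 defined values in a group is excluded from the
significance denominator. Tiers: * p<0.05, ** p<0.01, *** p<0.001,
**** p<0.0001, strict inequalities.

## Synthetic fiber fields

Each fiber draws a base heading from von Mises(μ, κ) (κ = 0 → uniform), a
length from a log-normal with the stated arithmetic mean/SD, and walks unit
steps with Gaussian per-step heading jitter (default 5°/step). The polyline
is stamped, dilated to the fiber width (default 3 px), blurred by a Gaussian
PSF (default σ = 1.5 px), and background (default 20, kept above the noise
floor so additive Gaussian noise of SD 8 does not clip at zero and spike the
histogram) plus noise are added, then clipped to bit depth. Everything is
drawn from one seeded generator, so outputs are byte-identical per
(config, seed).

Class presets (generator conventions emulating the two stromal
architectures):

| preset | n_fibers | length_mean (px) | κ |
|---|---|---|---|
| invasion | 120 | 200 | 6 |
| pseudoinvasion | 45 | 60 | 0.5 |

Cohorts jitter the per-image parameters multiplicatively (15% on fiber count
and length, 20% on κ, 8% on intensity) and draw the alignment axis uniformly
per image, since tiles have no preferred laboratory orientation.

What the generator does *not* emulate: physical SHG radiation (forward/
backward ratios, phase matching), Poisson photon statistics (additive
Gaussian noise is used; a realistic approximation at PMT count rates well
above the dark floor), fiber branching and crimp, and tissue-level intensity
gradients. Passing end-to-end tests therefore demonstrates that the
measurement chain recovers planted architectural differences, not that real
tissue classes will separate with these effect sizes.

Note one generator subtlety: per-step heading jitter accumulates, so a long
fiber's direction drifts by roughly jitter·√steps; at the default 5°/step a
200-step fascicle wanders ~70°. κ controls alignment of base headings, not
of every tangent, which compresses the measurable N range at high κ unless
the jitter is also reduced.

## Problem sizes

The end-to-end experiment uses the full default cohorts (88 vs 65 tiles at
512×512). Statistical calibration uses 200 replicate null cohort pairs of
20 images each at 96×96 with a sparse low-κ configuration — small enough to
make 9,600 measured tiles cheap, large enough per-cohort for the t-test's
normal approximation to hold for skewed parameters. Orientation-recovery
sweeps use 256×256 fields with 20 seeds per κ level.

## Known limitations

- Tiles are treated as independent replicates in the comparison stage; tiles
  from the same specimen are correlated in real studies and would need a
  hierarchical model.
- The orientation index summarizes global anisotropy only; it cannot see
  spatially heterogeneous alignment within a tile.
- The box-count dimension depends on the binarization; it inherits any
  instability of the Triangle threshold on low-contrast tiles.
- 16-bit tiles are min–max rescaled per tile for thresholding and GLCM, so
  absolute intensity calibration across tiles is not preserved in those
  parameters (the histogram moments retain native units).
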