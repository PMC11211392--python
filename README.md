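# shgtex

Quantitative texture and structure analysis of second-harmonic-generation
(SHG) collagen images, with a built-in synthetic fiber-field generator and a
two-group statistical comparison stage.

## The problem

In colonic polyps, epithelial misplacement ("pseudoinvasion") mimics invasive
carcinoma under routine histology, but the surrounding collagen stroma differs:
invasive lesions show desmoplasia — dense deposits of long, partially aligned
collagen fascicles — while pseudoinvasive regions contain short fibers with no
consistent alignment. SHG microscopy images fibrillar collagen directly, and
these architectural differences can be captured by image-texture statistics.
`shgtex` implements the full quantification chain for researchers who want to
score SHG tiles reproducibly and test whether two groups of tiles differ.

## What it computes

Twelve parameters per grayscale tile:

| group | parameters |
|---|---|
| histogram | mean, SD, skewness g₁ = m₃/m₂^1.5, excess kurtosis g₂ = m₄/m₂² − 3 |
| thresholding | TC-ratio: fraction of pixels above the Triangle (Zack) automatic threshold |
| co-occurrence (GLCM, distance 1, four directions averaged) | contrast Σp(i,j)(i−j)², homogeneity Σp(i,j)/(1+(i−j)²), energy Σp(i,j)², entropy −Σp log₂p, correlation Σ(i−μᵢ)(j−μⱼ)p/(σᵢσⱼ) |
| FFT | orientation index N = 1 − S/L from the minor/major semi-axes of an ellipse fitted to the binarized power spectrum (0 = random, 1 = aligned) |
| fractal | box-counting dimension D of the Triangle-thresholded mask (slope of log N(s) vs log 1/s) |

The comparison stage runs, per parameter, a two-sided unpaired Student's
t-test (pooled variance; Welch optional), D'Agostino–Pearson normality flags,
95% confidence half-widths of the group means, and a star significance tier.

The synthetic generator renders fiber fields as jittered random-walk
polylines with a von Mises orientation distribution, Gaussian PSF blur and
additive detector noise, so the whole chain is testable end-to-end with
planted ground truth — no image downloads required.

## Worked example

```sh
python examples/compare_cohorts.py
```

generates 20 invasion-like and 20 pseudoinvasion-like tiles and compares them:

```
        parameter  n1  n2     mean1    mean2  ...  t_stat   p_value  tier
             mean  20  20     46.36    23.84  ...   32.96 1.469e-29  ****
               sd  20  20     39.21    17.69  ...   33.44 8.598e-30  ****
         tc_ratio  20  20     0.321  0.05533  ...   35.27 1.203e-30  ****
orientation_index  20  20    0.4338   0.2521  ...   6.158 3.454e-07  ****
fractal_dimension  20  20     1.755    1.305  ...   30.47 2.613e-28  ****
...
12 of 12 parameters significant at p < 0.05
```

The invasion-like class is denser (higher mean intensity and TC-ratio) and
more aligned (higher orientation index), and every parameter separates the two
classes decisively at this effect size. Other examples: `measure_tiles.py`
(per-tile parameter vectors), `orientation_sweep.py` (N recovers planted
alignment monotonically), `threshold_and_fractal.py` (threshold level, mask
area, box-count fit).

A thin CLI wraps the same library functions:

```sh
shgtex simulate --preset invasion --n 88 --seed 1 --outdir tiles/
shgtex measure tiles/*.tif --out params.csv
shgtex compare params_a.csv params_b.csv --alpha 0.05 --out comparison.csv
```

## Layout

- `src/shgtex/` — library modules: `image_io`, `first_order`, `thresholding`,
  `glcm_texture`, `fft_orientation`, `fractal`, `group_comparison`,
  `synthetic_fibers`, `pipeline`, `cli`
- `examples/` — narrative scripts, one per capability
- `docs/methods.md` — model, conventions, parameter defaults and limitations
- `tests/` — unit, property and end-to-end suites
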