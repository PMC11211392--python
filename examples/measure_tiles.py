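"""Measure the twelve texture/structure parameters on a few synthetic tiles.

Generates three pseudoinvasion-like fiber-field tiles, runs the full
measurement pipeline and prints one parameter vector per tile. Columns:
histogram moments (mean, sd, skewness, kurtosis), the collagen area
fraction above the Triangle threshold (tc_ratio), the five co-occurrence
texture features, the FFT orientation index (0 random - 1 aligned) and
the box-count fractal dimension of the thresholded mask.
"""

from shgtex import generate_cohort, measure_images

images, _ = generate_cohort("pseudoinvasion", 3, master_seed=7)
table = measure_images(images)

with __import__("pandas").option_context("display.width", 200, "display.float_format", "{:.4f}".format):
    print(table.to_string(index=False))
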