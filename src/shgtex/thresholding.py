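"""Triangle automatic thresholding and the total collagen area ratio.

The TC-ratio is the fraction of pixels whose SHG intensity strictly
surpasses an automatically chosen threshold — a density proxy for
fibrillar collagen, which dominates the bright tail of the histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .image_io import IntensityImage

HIST_BINS = 256  # thresholding histogram resolution for both bit depths


@dataclass(frozen=True)
class ThresholdResult:
    level: float  # native intensity units
    mask: np.ndarray  # boolean collagen-positive mask
    tc_ratio: float  # foreground fraction in [0, 1]


def triangle_threshold(histogram: np.ndarray) -> int:
    """Triangle (Zack) threshold of an intensity histogram.

    Geometric construction: draw a line from the histogram peak to the
    farthest nonzero tail bin and return the bin index between them at
    maximum perpendicular distance below that line. When both tails are
    equidistant from the peak the bright (right) side is used, since
    collagen occupies the bright tail of an SHG histogram.
    """
    hist = np.asarray(histogram, dtype=np.float64)
    if hist.ndim != 1 or hist.size == 0:
        raise ValueError("histogram must be a non-empty 1-D array of counts")
    if hist.min() < 0:
        raise ValueError("histogram counts must be non-negative")
    nonzero = np.flatnonzero(hist)
    if nonzero.size < 2:
        raise ValueError("degenerate histogram: fewer than 2 nonzero bins")

    peak = int(np.argmax(hist))
    left_end, right_end = int(nonzero[0]), int(nonzero[-1])
    # pick the longer tail; tie goes to the bright side
    if (right_end - peak) >= (peak - left_end):
        end = right_end
    else:
        end = left_end
    if end == peak:
        raise ValueError("degenerate histogram: peak coincides with the selected tail end")

    lo, hi = (peak, end) if peak < end else (end, peak)
    bins = np.arange(lo, hi + 1)
    # perpendicular distance from (bin, count) to the peak-to-tail chord;
    # the constant 1/norm factor does not change the argmax
    x1, y1 = peak, hist[peak]
    x2, y2 = end, hist[end]
    dist = np.abs((y2 - y1) * bins - (x2 - x1) * hist[lo : hi + 1] + x2 * y1 - y2 * x1)
    return int(bins[np.argmax(dist)])


def _rescale_to_bins(pixels: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Min-max rescale intensities onto the 0..HIST_BINS-1 grid."""
    lo = float(pixels.min())
    hi = float(pixels.max())
    if hi == lo:
        raise ValueError("degenerate histogram: constant image")
    scaled = np.round((pixels.astype(np.float64) - lo) * (HIST_BINS - 1) / (hi - lo))
    return scaled.astype(np.int64), lo, hi


def triangle_threshold_image(image: IntensityImage) -> ThresholdResult:
    """Threshold a tile with the Triangle method and compute its TC-ratio.

    The histogram uses 256 bins for both bit depths (16-bit data are
    min-max rescaled); the selected bin is mapped back to a native
    intensity level before the strict ``>`` binarization.
    """
    if image.bit_depth == 8:
        hist = np.bincount(image.pixels.ravel().astype(np.int64), minlength=HIST_BINS)
        level = float(triangle_threshold(hist))
    else:
        scaled, lo, hi = _rescale_to_bins(image.pixels)
        hist = np.bincount(scaled.ravel(), minlength=HIST_BINS)
        bin_level = triangle_threshold(hist)
        level = lo + bin_level * (hi - lo) / (HIST_BINS - 1)
    mask = binarize(image, level)
    return ThresholdResult(level=level, mask=mask, tc_ratio=tc_ratio(mask))


def binarize(image: IntensityImage, level: float) -> np.ndarray:
    """Boolean mask of pixels strictly above ``level``."""
    return image.pixels > level


def tc_ratio(mask: np.ndarray) -> float:
    """Foreground pixel count divided by total pixel count."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    return float(np.count_nonzero(mask)) / mask.size
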