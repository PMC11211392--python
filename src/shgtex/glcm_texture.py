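"""Gray-level co-occurrence texture features.

The co-occurrence matrix is accumulated at pixel distance 1 in the four
standard directions (0°, 45°, 90°, 135°), symmetrized and normalized;
five features — contrast, homogeneity (inverse difference moment),
energy (angular second moment), entropy (base-2) and correlation — are
averaged over the four directions.

Gray levels: 8-bit tiles are used at native 256 levels; 16-bit tiles are
min-max rescaled to 256 levels before accumulation so the matrix stays
bounded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import graycomatrix

from .image_io import IntensityImage

#: direction name -> skimage angle (radians)
DIRECTIONS = {
    0: 0.0,
    45: np.pi / 4,
    90: np.pi / 2,
    135: 3 * np.pi / 4,
}

DEFAULT_LEVELS = 256


@dataclass(frozen=True)
class TextureFeatures:
    contrast: float
    homogeneity: float
    energy: float
    entropy: float
    correlation: float  # NaN for a constant image (zero marginal variance)


def quantize(image: IntensityImage, levels: int = DEFAULT_LEVELS) -> np.ndarray:
    """Map intensities onto 0..levels-1 integer gray levels."""
    px = image.pixels
    if image.bit_depth == 8 and levels == 256:
        return px.astype(np.uint8)
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        return np.zeros_like(px, dtype=np.uint16 if levels > 256 else np.uint8)
    q = np.round((px.astype(np.float64) - lo) * (levels - 1) / (hi - lo))
    return q.astype(np.uint16 if levels > 256 else np.uint8)


def compute_glcm(
    image: IntensityImage | np.ndarray,
    direction: int,
    levels: int = DEFAULT_LEVELS,
) -> np.ndarray:
    """Symmetric, normalized co-occurrence matrix at distance 1.

    ``direction`` is one of 0, 45, 90, 135 (degrees). Pre-quantized
    integer arrays are accepted as-is.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}, got {direction}")
    if isinstance(image, IntensityImage):
        arr = quantize(image, levels)
    else:
        arr = np.asarray(image)
        if arr.max() >= levels:
            raise ValueError("quantized values exceed the stated level count")
    needs_rows = direction != 0  # vertical/diagonal offsets step across rows
    needs_cols = direction != 90
    if (needs_rows and arr.shape[0] < 2) or (needs_cols and arr.shape[1] < 2):
        raise ValueError(
            f"image of shape {arr.shape} too small for a distance-1 offset at {direction} deg"
        )
    glcm = graycomatrix(
        arr, distances=[1], angles=[DIRECTIONS[direction]], levels=levels,
        symmetric=True, normed=True,
    )
    return glcm[:, :, 0, 0]


def glcm_features(glcm: np.ndarray) -> TextureFeatures:
    """The five texture features of a normalized co-occurrence matrix.

    contrast    = sum p(i,j) (i-j)^2
    homogeneity = sum p(i,j) / (1 + (i-j)^2)
    energy      = sum p(i,j)^2                (angular second moment)
    entropy     = -sum p(i,j) log2 p(i,j)     (0 log 0 := 0)
    correlation = sum (i-mu_i)(j-mu_j) p(i,j) / (sigma_i sigma_j)
    """
    p = np.asarray(glcm, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("GLCM must be a square 2-D matrix")
    total = p.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise ValueError(f"GLCM must be normalized to sum 1 (got {total})")

    n = p.shape[0]
    idx = np.arange(n, dtype=np.float64)
    i = idx[:, None]
    j = idx[None, :]
    diff2 = (i - j) ** 2

    contrast = float(np.sum(p * diff2))
    homogeneity = float(np.sum(p / (1.0 + diff2)))
    energy = float(np.sum(p**2))
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))

    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.sum(idx * pi))
    mu_j = float(np.sum(idx * pj))
    var_i = float(np.sum((idx - mu_i) ** 2 * pi))
    var_j = float(np.sum((idx - mu_j) ** 2 * pj))
    if var_i <= 0.0 or var_j <= 0.0:
        warnings.warn(
            "zero marginal variance: GLCM correlation is undefined", RuntimeWarning, stacklevel=2
        )
        correlation = np.nan
    else:
        correlation = float(
            np.sum((i - mu_i) * (j - mu_j) * p) / np.sqrt(var_i * var_j)
        )
    return TextureFeatures(contrast, homogeneity, energy, entropy, correlation)


def averaged_features(
    image: IntensityImage, levels: int = DEFAULT_LEVELS
) -> TextureFeatures:
    """Arithmetic mean of each feature over the four directions.

    An undefined correlation in any direction propagates as NaN.
    """
    arr = quantize(image, levels)
    feats = [glcm_features(compute_glcm(arr, d, levels)) for d in DIRECTIONS]
    return TextureFeatures(
        contrast=float(np.mean([f.contrast for f in feats])),
        homogeneity=float(np.mean([f.homogeneity for f in feats])),
        energy=float(np.mean([f.energy for f in feats])),
        entropy=float(np.mean([f.entropy for f in feats])),
        correlation=float(np.mean([f.correlation for f in feats])),
    )
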