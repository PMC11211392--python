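"""Box-counting fractal dimension of a binary collagen mask.

The mask is tiled by s-by-s grids anchored at the image origin; the
number of boxes containing foreground follows N(s) ~ s^-D for a
structure of box-count dimension D, estimated as the least-squares slope
of log N against log(1/s) over a power-of-two size ladder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import block_reduce


@dataclass(frozen=True)
class FractalResult:
    D: float
    box_sizes: tuple[int, ...]
    counts: tuple[int, ...]
    r2: float  # goodness of the log-log fit


def default_box_sizes(shape: tuple[int, int]) -> list[int]:
    """Powers of 2 from 2 up to min(height, width)/4."""
    limit = min(shape) // 4
    sizes = []
    s = 2
    while s <= limit:
        sizes.append(s)
        s *= 2
    return sizes


def box_count(mask: np.ndarray, sizes) -> list[int]:
    """Occupied-box counts for each grid size (origin-anchored grid).

    Partial boxes at the right/bottom edges count like full boxes.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("no foreground: cannot box-count an empty mask")
    counts = []
    for s in sizes:
        s = int(s)
        if s < 2 or s > min(mask.shape):
            raise ValueError(f"box size {s} out of range for mask of shape {mask.shape}")
        occupied = block_reduce(mask, (s, s), np.max)  # pads edge blocks with background
        counts.append(int(np.count_nonzero(occupied)))
    return counts


def fractal_dimension(mask: np.ndarray, sizes=None) -> FractalResult:
    """Box-count dimension of a binary mask over the default size ladder."""
    mask = np.asarray(mask, dtype=bool)
    if sizes is None:
        sizes = default_box_sizes(mask.shape)
    sizes = [int(s) for s in sizes]
    if len(sizes) < 3:
        raise ValueError("need at least 3 box sizes for a stable log-log fit")
    counts = box_count(mask, sizes)
    log_inv_s = np.log(1.0 / np.asarray(sizes, dtype=np.float64))
    log_n = np.log(np.asarray(counts, dtype=np.float64))
    slope, intercept = np.polyfit(log_inv_s, log_n, 1)
    fitted = slope * log_inv_s + intercept
    ss_res = float(np.sum((log_n - fitted) ** 2))
    ss_tot = float(np.sum((log_n - log_n.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FractalResult(
        D=float(slope), box_sizes=tuple(sizes), counts=tuple(counts), r2=r2
    )
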