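"""First-order (histogram) statistics of a tile's pixel intensities.

Mean, standard deviation, skewness and kurtosis are computed over all
pixels with population (biased) moments; kurtosis is reported in excess
form, so a Gaussian intensity distribution scores 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image_io import IntensityImage


@dataclass(frozen=True)
class FirstOrderStats:
    mean: float
    sd: float
    skewness: float  # NaN when sd == 0
    kurtosis: float  # excess form; NaN when sd == 0


def first_order_stats(image: IntensityImage | np.ndarray) -> FirstOrderStats:
    """Population moments of the intensity histogram.

    skewness = m3 / m2^1.5, kurtosis = m4 / m2^2 - 3 where m_k are central
    moments over all pixels. A constant tile has sd 0 and undefined shape
    statistics, reported as NaN with a warning.
    """
    pixels = image.pixels if isinstance(image, IntensityImage) else np.asarray(image)
    x = pixels.astype(np.float64).ravel()
    if x.size == 0:
        raise ValueError("empty image")
    mean = float(x.mean())
    d = x - mean
    m2 = float(np.mean(d**2))
    sd = float(np.sqrt(m2))
    if m2 == 0.0:
        warnings.warn(
            "constant image: skewness and kurtosis are undefined", RuntimeWarning, stacklevel=2
        )
        return FirstOrderStats(mean=mean, sd=0.0, skewness=np.nan, kurtosis=np.nan)
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return FirstOrderStats(
        mean=mean,
        sd=sd,
        skewness=m3 / m2**1.5,
        kurtosis=m4 / m2**2 - 3.0,
    )
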