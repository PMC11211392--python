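"""Pipeline orchestration: per-tile parameter vectors and group comparison.

``compute_parameters`` runs every stage on one tile and assembles the
twelve-parameter vector; degenerate stages (constant tiles, empty
spectra or masks) yield NaN sentinels with a logged warning so batch
runs never abort on a single bad tile.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import fft_orientation, first_order, fractal, glcm_texture, thresholding
from .image_io import PARAMETER_NAMES, IntensityImage, read_image

logger = logging.getLogger(__name__)

try:  # py311+: stdlib TOML reader for config files
    import tomllib
except ModuleNotFoundError:  # pragma: no cover
    tomllib = None


@dataclass(frozen=True)
class AnalysisConfig:
    """Every paper-ambiguous convention, auditable and swappable."""

    glcm_levels: int = 256
    spectrum_threshold: str = "otsu"  # or "triangle"
    box_sizes: tuple[int, ...] | None = None  # None = power-of-2 ladder
    welch: bool = False
    correction: str | None = None
    alpha: float = 0.05

    @classmethod
    def from_toml(cls, path: str | Path) -> "AnalysisConfig":
        if tomllib is None:  # pragma: no cover
            raise RuntimeError("TOML config support requires Python >= 3.11")
        data = tomllib.loads(Path(path).read_text())
        if "box_sizes" in data and data["box_sizes"] is not None:
            data["box_sizes"] = tuple(int(s) for s in data["box_sizes"])
        return cls(**data)


def compute_parameters(
    image: IntensityImage, config: AnalysisConfig = AnalysisConfig()
) -> dict[str, float]:
    """The twelve-parameter vector of one tile."""
    params: dict[str, float] = dict.fromkeys(PARAMETER_NAMES, np.nan)

    fo = first_order.first_order_stats(image)
    params.update(mean=fo.mean, sd=fo.sd, skewness=fo.skewness, kurtosis=fo.kurtosis)

    mask = None
    try:
        thresh = thresholding.triangle_threshold_image(image)
        params["tc_ratio"] = thresh.tc_ratio
        mask = thresh.mask
    except ValueError as exc:
        logger.warning("%s: thresholding failed (%s)", image.source_id, exc)

    tex = glcm_texture.averaged_features(image, levels=config.glcm_levels)
    params.update(
        contrast=tex.contrast,
        homogeneity=tex.homogeneity,
        energy=tex.energy,
        entropy=tex.entropy,
        correlation=tex.correlation,
    )

    try:
        orient = fft_orientation.orientation_index(image, method=config.spectrum_threshold)
        params["orientation_index"] = orient.N
    except ValueError as exc:
        logger.warning("%s: orientation index failed (%s)", image.source_id, exc)

    if mask is not None:
        try:
            frac = fractal.fractal_dimension(mask, sizes=config.box_sizes)
            params["fractal_dimension"] = frac.D
        except ValueError as exc:
            logger.warning("%s: fractal dimension failed (%s)", image.source_id, exc)
    return params


def measure_images(
    images, config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Parameter table for a batch of tiles (paths or IntensityImages).

    Unreadable files are logged and skipped; the run fails only when no
    tile could be measured.
    """
    records = []
    for item in images:
        t0 = time.perf_counter()
        if isinstance(item, IntensityImage):
            img = item
        else:
            try:
                img = read_image(item)
            except (OSError, ValueError) as exc:
                logger.error("skipping %s: %s", item, exc)
                continue
        row = {"source_id": img.source_id}
        row.update(compute_parameters(img, config))
        records.append(row)
        logger.info("%s measured in %.2fs", img.source_id, time.perf_counter() - t0)
    if not records:
        raise ValueError("no readable images: nothing to measure")
    return pd.DataFrame.from_records(records, columns=["source_id"] + PARAMETER_NAMES)
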