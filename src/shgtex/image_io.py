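"""Reading grayscale image tiles and writing tabular results.

The unit of analysis is a single-channel intensity tile (8- or 16-bit).
RGB files whose channels are identical (grayscale saved as RGB) are
collapsed to one channel; genuinely colored input is rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

#: Canonical order of the twelve per-image parameters.
PARAMETER_NAMES = [
    "mean",
    "sd",
    "skewness",
    "kurtosis",
    "tc_ratio",
    "contrast",
    "homogeneity",
    "energy",
    "entropy",
    "correlation",
    "orientation_index",
    "fractal_dimension",
]

TABLE_COLUMNS = ["source_id"] + PARAMETER_NAMES


@dataclass
class IntensityImage:
    """A single-channel grayscale tile.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative integer intensities.
    bit_depth : int
        8 or 16; all intensities must fit in the stated depth.
    source_id : str
        Free-text provenance label (file stem for images read from disk).
    """

    pixels: np.ndarray
    bit_depth: int = 8
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D single-channel image, got shape {self.pixels.shape}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        h, w = self.pixels.shape
        if h < 8 or w < 8:
            raise ValueError(f"image too small ({h}x{w}); need at least 8x8")
        if self.pixels.min() < 0:
            raise ValueError("negative intensities are not allowed")
        if self.pixels.max() > 2**self.bit_depth - 1:
            raise ValueError(
                f"intensity {self.pixels.max()} exceeds {self.bit_depth}-bit range"
            )

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def read_image(path: str | Path) -> IntensityImage:
    """Read a TIFF/PNG tile as an :class:`IntensityImage`.

    RGB input is accepted only when all channels are identical.
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise OSError(f"cannot read image file {path!s}: {exc}") from exc

    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop fully-opaque alpha
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            if not (np.array_equal(arr[..., 0], arr[..., 1]) and np.array_equal(arr[..., 0], arr[..., 2])):
                raise ValueError(
                    f"{path!s} is RGB with differing channels; extract the channel of "
                    "interest explicitly before analysis"
                )
            arr = arr[..., 0]
        else:
            raise ValueError(f"{path!s}: unsupported channel count {arr.shape[2]}")
    elif arr.ndim != 2:
        raise ValueError(f"{path!s}: unsupported image dimensionality {arr.ndim}")

    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"{path!s}: unsupported dtype {arr.dtype}; expected uint8 or uint16")
    return IntensityImage(pixels=arr, bit_depth=depth, source_id=path.stem)


def write_image(image: IntensityImage, path: str | Path) -> None:
    """Write a tile to TIFF or PNG at its native bit depth."""
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    iio.imwrite(Path(path), image.pixels.astype(dtype))


def write_parameter_table(rows, path: str | Path) -> None:
    """Write (source_id, parameter dict) rows as a CSV parameter table.

    Values are rendered with 12 significant digits so a read-back
    reproduces them; the column order is fixed and locale-independent.
    """
    rows = list(rows)
    if not rows:
        raise ValueError("parameter table must contain at least one row")
    records = []
    for source_id, params in rows:
        rec = {"source_id": source_id}
        for name in PARAMETER_NAMES:
            rec[name] = params[name]
        records.append(rec)
    df = pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"output directory {path.parent!s} does not exist")
    df.to_csv(path, index=False, float_format="%.12g")


def read_parameter_table(path: str | Path) -> pd.DataFrame:
    """Read a parameter table CSV, validating the canonical schema."""
    df = pd.read_csv(path)
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path!s}: missing required column(s) {missing}")
    return df[TABLE_COLUMNS]
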