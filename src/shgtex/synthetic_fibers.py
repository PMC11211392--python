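"""Synthetic SHG-like collagen fiber fields with planted structure.

Fibers are rendered as jittered random-walk polylines: each fiber draws
a base heading from a von Mises distribution (kappa 0 = isotropic, large
kappa = aligned), walks a log-normal number of unit steps with per-step
heading jitter, and is stamped at a given width and intensity. The field
is blurred by a Gaussian PSF and corrupted by additive Gaussian noise,
emulating PMT-detected SHG at moderate photon flux.

Two class presets emulate the qualitative stromal contrast between
invasive and pseudoinvasive colon polyp regions: dense fields of long,
partially aligned fascicles versus sparse fields of short fibers with no
consistent alignment.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.morphology import dilation, disk

from .image_io import IntensityImage, write_image


@dataclass(frozen=True)
class FiberFieldConfig:
    """Generative parameters for one synthetic fiber field."""

    image_size: int = 512
    n_fibers: int = 60
    length_mean: float = 100.0  # pixels, log-normal mean
    length_sd: float = 30.0  # pixels, log-normal sd
    width: int = 3  # stamped fiber width, pixels
    orientation_mu: float = 0.0  # degrees
    orientation_kappa: float = 0.0  # von Mises concentration; 0 = random
    fiber_intensity: float = 150.0
    curvature_jitter: float = 5.0  # degrees of heading jitter per unit step
    psf_sigma: float = 1.5  # Gaussian PSF, pixels
    background_level: float = 20.0  # detector offset, kept above the noise floor
    noise_sd: float = 8.0
    bit_depth: int = 8
    seed: int = 0

    def replace(self, **kwargs) -> "FiberFieldConfig":
        return dataclasses.replace(self, **kwargs)


#: Class presets: dense long aligned fascicles (invasion-like stroma)
#: versus sparse short randomly oriented fibers (pseudoinvasion-like).
#: These are generator conventions chosen to mirror the qualitative
#: contrast between the two stromal architectures.
CLASS_PRESETS: dict[str, FiberFieldConfig] = {
    "invasion": FiberFieldConfig(
        n_fibers=120, length_mean=200.0, length_sd=60.0, orientation_kappa=6.0
    ),
    "pseudoinvasion": FiberFieldConfig(
        n_fibers=45, length_mean=60.0, length_sd=20.0, orientation_kappa=0.5
    ),
}


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given arithmetic mean/sd."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_fiber_image(config: FiberFieldConfig) -> IntensityImage:
    """Render one fiber field; byte-identical for identical (config, seed)."""
    rng = np.random.default_rng(config.seed)
    size = config.image_size
    mask = np.zeros((size, size), dtype=bool)

    if config.n_fibers > 0:
        mu_rad = np.radians(config.orientation_mu)
        log_mu, log_sigma = _lognormal_params(config.length_mean, config.length_sd)
        for _ in range(config.n_fibers):
            if config.orientation_kappa > 0:
                heading0 = rng.vonmises(mu_rad, config.orientation_kappa)
            else:
                heading0 = rng.uniform(-np.pi, np.pi)
            n_steps = max(2, int(round(rng.lognormal(log_mu, log_sigma))))
            jitter = rng.normal(0.0, np.radians(config.curvature_jitter), size=n_steps)
            headings = heading0 + np.cumsum(jitter)
            start = rng.uniform(0, size, size=2)
            # x along columns, y up the rows (image row index decreases)
            xs = start[0] + np.concatenate(([0.0], np.cumsum(np.cos(headings))))
            ys = start[1] + np.concatenate(([0.0], np.cumsum(np.sin(headings))))
            cols = np.round(xs).astype(int)
            rows = np.round(size - 1 - ys).astype(int)
            keep = (rows >= 0) & (rows < size) & (cols >= 0) & (cols < size)
            mask[rows[keep], cols[keep]] = True
        if config.width > 1 and mask.any():
            mask = dilation(mask, disk(config.width // 2))

    field = config.fiber_intensity * mask.astype(np.float64)
    if config.psf_sigma > 0:
        field = gaussian_filter(field, config.psf_sigma)
    field += config.background_level
    field += rng.normal(0.0, config.noise_sd, size=field.shape)
    cap = 2**config.bit_depth - 1
    pixels = np.clip(np.round(field), 0, cap)
    dtype = np.uint8 if config.bit_depth == 8 else np.uint16
    return IntensityImage(
        pixels=pixels.astype(dtype),
        bit_depth=config.bit_depth,
        source_id=f"synthetic_seed{config.seed}",
    )


#: relative within-class jitter applied per image in a cohort
COHORT_JITTER = {
    "n_fibers": 0.15,
    "length_mean": 0.15,
    "orientation_kappa": 0.20,
    "fiber_intensity": 0.08,
}


def jittered_config(
    base: FiberFieldConfig, rng: np.random.Generator, seed: int
) -> FiberFieldConfig:
    """Per-image draw of generative parameters around a class preset.

    Multiplicative Gaussian jitter creates within-class variance; the
    in-plane alignment axis is uniform per image since tiles have no
    preferred laboratory orientation.
    """
    n_fibers = max(0, int(round(base.n_fibers * rng.normal(1.0, COHORT_JITTER["n_fibers"]))))
    length_mean = max(4.0, base.length_mean * rng.normal(1.0, COHORT_JITTER["length_mean"]))
    kappa = max(0.0, base.orientation_kappa * rng.normal(1.0, COHORT_JITTER["orientation_kappa"]))
    intensity = max(1.0, base.fiber_intensity * rng.normal(1.0, COHORT_JITTER["fiber_intensity"]))
    mu = float(rng.uniform(0.0, 180.0))
    return base.replace(
        n_fibers=n_fibers,
        length_mean=length_mean,
        orientation_kappa=kappa,
        fiber_intensity=intensity,
        orientation_mu=mu,
        seed=seed,
    )


def generate_cohort(
    preset: str | FiberFieldConfig, n: int, master_seed: int
) -> tuple[list[IntensityImage], list[FiberFieldConfig]]:
    """Generate ``n`` images of one class, reproducible from master_seed.

    Returns the images and the per-image ground-truth configurations.
    """
    if isinstance(preset, str):
        if preset not in CLASS_PRESETS:
            raise ValueError(
                f"unknown preset {preset!r}; available: {sorted(CLASS_PRESETS)}"
            )
        base = CLASS_PRESETS[preset]
    else:
        base = preset
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    rng = np.random.default_rng(master_seed)
    images, configs = [], []
    for i in range(n):
        seed = int(rng.integers(0, 2**31 - 1))
        cfg = jittered_config(base, rng, seed)
        img = generate_fiber_image(cfg)
        img.source_id = f"{getattr(base, 'name', 'cohort')}_{i:03d}_seed{seed}"
        images.append(img)
        configs.append(cfg)
    return images, configs


def write_cohort(
    images: list[IntensityImage],
    configs: list[FiberFieldConfig],
    outdir: str | Path,
    prefix: str = "tile",
) -> list[Path]:
    """Write a cohort as TIFFs plus a ground-truth JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    sidecar = {}
    for i, (img, cfg) in enumerate(zip(images, configs)):
        name = f"{prefix}_{i:03d}.tif"
        write_image(img, outdir / name)
        paths.append(outdir / name)
        sidecar[name] = dataclasses.asdict(cfg)
    (outdir / f"{prefix}_ground_truth.json").write_text(json.dumps(sidecar, indent=1))
    return paths
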