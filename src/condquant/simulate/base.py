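"""Shared machinery for the synthetic-scene generators.

All generators are pure functions of (config, seed): one seeded generator
per call, with sub-streams derived deterministically per object so adding
an object never perturbs earlier ones. The optical model is an isotropic
Gaussian PSF (σ given in nm, converted via the pixel size) followed by the
standard fluorescence-camera noise model: Poisson photon noise on the
blurred intensity, then additive Gaussian read noise.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, Field, field_validator
from scipy.ndimage import gaussian_filter

from ..scene import DEFAULT_PIXEL_SIZE_NM


class NoiseConfig(BaseModel, extra="forbid"):
    """Camera noise. ``poisson_scale`` is photons per intensity unit
    (0 disables shot noise); ``read_sigma`` is Gaussian read noise in
    intensity units (0 disables it)."""

    poisson_scale: float = Field(default=0.0, ge=0)
    read_sigma: float = Field(default=0.0, ge=0)

    @property
    def enabled(self) -> bool:
        return self.poisson_scale > 0 or self.read_sigma > 0


class SceneConfig(BaseModel, extra="forbid"):
    """Geometry, optics and noise of a simulated acquisition.

    ``image_shape`` is (y, x) or (z, y, x) in pixels; every axis must be at
    least 8 px. ``pixel_size`` is nm/px (default: a 106.3 µm field sampled
    at 512 px). ``psf_sigma`` is the Gaussian PSF σ in nm. The seed fully
    determines the output: same config, same arrays, bit for bit.
    """

    image_shape: tuple[int, ...] = (128, 128)
    pixel_size: float = Field(default=DEFAULT_PIXEL_SIZE_NM, gt=0)
    psf_sigma: float = Field(default=250.0, ge=0)
    noise: NoiseConfig = Field(
        default_factory=lambda: NoiseConfig(poisson_scale=20.0, read_sigma=0.2)
    )
    seed: int = 0

    @field_validator("image_shape")
    @classmethod
    def _check_shape(cls, v: tuple[int, ...]) -> tuple[int, ...]:
        if len(v) not in (2, 3):
            raise ValueError("image_shape must be 2D (y, x) or 3D (z, y, x)")
        if any(d < 8 for d in v):
            raise ValueError("all image dimensions must be >= 8 px")
        return v

    @property
    def psf_sigma_px(self) -> float:
        return self.psf_sigma / self.pixel_size


def substream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic child RNG for (seed, key...)."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def apply_psf(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Blur with a normalized Gaussian kernel.

    Periodic boundary handling makes the blur exactly intensity-conserving,
    which the generators rely on for their ground-truth bookkeeping; objects
    are placed away from the image edge so wrap-around is negligible.
    """
    if sigma_px <= 0:
        return image
    return gaussian_filter(image, sigma=sigma_px, mode="wrap")


def apply_noise(image: np.ndarray, noise: NoiseConfig, rng: np.random.Generator) -> np.ndarray:
    """Poisson shot noise then Gaussian read noise; clipped at zero."""
    out = image
    if noise.poisson_scale > 0:
        out = rng.poisson(np.clip(out, 0, None) * noise.poisson_scale) / noise.poisson_scale
    if noise.read_sigma > 0:
        out = out + rng.normal(0.0, noise.read_sigma, size=out.shape)
    return np.clip(out, 0.0, None)
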