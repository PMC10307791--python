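"""Two-phase condensate scenes: dense spherical objects over a dilute background.

Channel 0 carries the scaffold protein (dense intensity inside spheres,
dilute intensity outside); channel 1 carries a client partitioned between
the phases, plus an optional bleedthrough fraction of channel 0. The
exported ground truth (true separation factor, partition coefficient) is
computed from the noiseless, pre-blur object model, never re-estimated
from the rendered image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, Field

from ..scene import ImageScene
from .base import SceneConfig, apply_noise, apply_psf, substream


class CondensateParams(BaseModel, extra="forbid"):
    """Object model of a condensate scene.

    Intensities are arbitrary units; the dense phase must be brighter than
    the dilute phase. ``client_partition`` is the client's dense/dilute
    concentration ratio P; ``bleedthrough`` is the fraction of channel-0
    signal leaking into channel 1.
    """

    n_objects: int = Field(default=7, ge=0)
    radius_nm: tuple[float, float] = (600.0, 1200.0)  # min, max
    dense_intensity: float = Field(default=10.0, gt=0)
    dilute_intensity: float = Field(default=1.0, ge=0)
    client_partition: float = Field(default=5.0, gt=0)
    client_dilute: float = Field(default=1.0, gt=0)
    bleedthrough: float = Field(default=0.0, ge=0, lt=1)
    min_separation_px: float = Field(default=4.0, ge=0)
    max_attempts: int = Field(default=10_000, ge=1)

    def model_post_init(self, __context) -> None:
        if self.dense_intensity <= self.dilute_intensity:
            raise ValueError("dense intensity must exceed dilute intensity")
        if self.radius_nm[0] > self.radius_nm[1]:
            raise ValueError("radius_nm must be (min, max) with min <= max")


@dataclass(frozen=True)
class CondensateSceneTruth:
    """Hidden parameters of a generated scene, for estimator validation."""

    centers_nm: np.ndarray  # (n, ndim)
    radii_nm: np.ndarray
    dense_intensity: float
    dilute_intensity: float
    client_partition: float
    bleedthrough_fraction: float
    true_separation_factor: float  # percent, from the noiseless pre-blur map

    def __post_init__(self) -> None:
        if not 0 <= self.true_separation_factor <= 100:
            raise ValueError("separation factor must lie in [0, 100]")


@dataclass
class CondensateScene:
    scene: ImageScene
    truth: CondensateSceneTruth
    label_map: np.ndarray
    params: CondensateParams = field(repr=False, default=None)


class PlacementError(RuntimeError):
    """Raised when non-overlapping object placement fails within the attempt cap."""


def _place_objects(
    config: SceneConfig, params: CondensateParams
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping sphere centers (px) and radii (px)."""
    shape = np.array(config.image_shape, dtype=float)
    centers: list[np.ndarray] = []
    radii: list[float] = []
    for i in range(params.n_objects):
        rng = substream(config.seed, 1, i)
        r_px = rng.uniform(*params.radius_nm) / config.pixel_size
        if r_px < 2.0:
            raise ValueError(
                f"object {i}: radius {r_px:.2f} px < 2 px at this calibration"
            )
        lo, hi = r_px + 1.0, shape - r_px - 1.0
        if np.any(hi <= lo):
            raise ValueError("condensates do not fit inside the image")
        for _ in range(params.max_attempts):
            c = rng.uniform(lo, hi)
            ok = all(
                np.linalg.norm(c - cj) >= r_px + rj + params.min_separation_px
                for cj, rj in zip(centers, radii)
            )
            if ok:
                centers.append(c)
                radii.append(r_px)
                break
        else:
            raise PlacementError(
                f"could not place object {i} without overlap after "
                f"{params.max_attempts} attempts (packing too dense)"
            )
    return np.array(centers).reshape(len(centers), len(shape)), np.array(radii)


def _rasterize(shape: tuple[int, ...], centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Label map: pixel centers within each sphere, labelled 1..n."""
    labels = np.zeros(shape, dtype=np.int32)
    grids = np.meshgrid(*[np.arange(d, dtype=float) for d in shape], indexing="ij")
    for i, (c, r) in enumerate(zip(centers, radii), start=1):
        d2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
        labels[d2 <= r**2] = i
    return labels


def generate_condensate_scene(
    config: SceneConfig, params: CondensateParams | None = None
) -> CondensateScene:
    """Render a two-channel condensate scene with exported ground truth.

    Returns the scene (PSF-blurred, noised), the noiseless-model truth and
    the pre-blur label map. Deterministic under ``config.seed``.
    """
    if params is None:
        params = CondensateParams()
    centers_px, radii_px = _place_objects(config, params)
    labels = _rasterize(config.image_shape, centers_px, radii_px)
    dense = labels > 0

    scaffold = np.where(dense, params.dense_intensity, params.dilute_intensity).astype(float)
    client = np.where(
        dense, params.client_partition * params.client_dilute, params.client_dilute
    ).astype(float)
    client = client + params.bleedthrough * scaffold

    total = scaffold.sum()
    true_sf = 100.0 * float(scaffold[dense].sum()) / float(total) if total > 0 else 0.0
    truth = CondensateSceneTruth(
        centers_nm=centers_px * config.pixel_size,
        radii_nm=radii_px * config.pixel_size,
        dense_intensity=params.dense_intensity,
        dilute_intensity=params.dilute_intensity,
        client_partition=params.client_partition,
        bleedthrough_fraction=params.bleedthrough,
        true_separation_factor=true_sf,
    )

    noise_rng = substream(config.seed, 2)
    channels = []
    for ch in (scaffold, client):
        rendered = apply_psf(ch, config.psf_sigma_px)
        rendered = apply_noise(rendered, config.noise, noise_rng)
        channels.append(rendered)

    if len(config.image_shape) == 2:
        data = np.stack(channels)  # (channel, y, x)
    else:
        data = np.stack(channels, axis=1)  # (z, channel, y, x)
    scene = ImageScene(
        data, pixel_size=config.pixel_size, channel_names=["scaffold", "client"]
    )
    return CondensateScene(scene=scene, truth=truth, label_map=labels, params=params)
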