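"""Curvilinear filament scenes with a tunable bundling parameter.

Renders smoothed random-walk curves of fixed total integrated intensity.
With probability ``b`` each path is re-drawn along one of a small number of
shared centerlines (plus sub-pixel jitter), concentrating the same amount
of signal into fewer structures — which is exactly what raises the image
coefficient of variation, the bundling readout. The expected CV is
strictly increasing in ``b`` at fixed total intensity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..scene import ImageScene
from .base import SceneConfig, apply_noise, apply_psf, substream


@dataclass(frozen=True)
class FilamentSceneTruth:
    bundling: float
    n_paths: int
    total_intensity: float


def _random_walk(
    rng: np.random.Generator, shape: tuple[int, int], n_steps: int, curvature: float
) -> np.ndarray:
    """A smooth persistent random walk, reflected at the image borders."""
    pos = rng.uniform([2.0, 2.0], np.array(shape, float) - 2.0)
    heading = rng.uniform(0, 2 * np.pi)
    pts = np.empty((n_steps, 2))
    for s in range(n_steps):
        heading += rng.normal(0.0, curvature)
        pos = pos + np.array([np.sin(heading), np.cos(heading)])
        for ax in (0, 1):  # reflect off borders
            if pos[ax] < 1:
                pos[ax] = 2 - pos[ax]
                heading = -heading if ax == 0 else np.pi - heading
            elif pos[ax] > shape[ax] - 2:
                pos[ax] = 2 * (shape[ax] - 2) - pos[ax]
                heading = -heading if ax == 0 else np.pi - heading
        pts[s] = pos
    return pts


def _deposit(image: np.ndarray, pts: np.ndarray, amount: float) -> None:
    """Deposit ``amount`` of intensity uniformly along a path (nearest pixel)."""
    idx = np.clip(
        np.round(pts).astype(int), 0, np.array(image.shape) - 1
    )
    per_point = amount / len(pts)
    np.add.at(image, (idx[:, 0], idx[:, 1]), per_point)


def generate_filament_scene(
    config: SceneConfig,
    n_paths: int = 30,
    bundling: float = 0.0,
    n_bundles: int = 3,
    path_length_px: int = 120,
    curvature: float = 0.15,
    jitter_px: float = 0.8,
    total_intensity: float = 1e5,
) -> tuple[ImageScene, FilamentSceneTruth]:
    """Render ``n_paths`` filaments at bundling strength ``bundling`` ∈ [0, 1].

    The bundling decision for each path draws from a sub-stream separate
    from the path-shape stream, so scenes at different ``b`` share their
    unbundled paths; a single path is never bundled (there is nothing to
    bundle it with), making ``b`` a no-op at ``n_paths=1``.
    """
    if not 0.0 <= bundling <= 1.0:
        raise ValueError("bundling must lie in [0, 1]")
    if n_paths < 1:
        raise ValueError("need at least one path")
    if len(config.image_shape) != 2:
        raise ValueError("filament scenes are 2D")
    shape = config.image_shape

    centerlines = [
        _random_walk(substream(config.seed, 3, k), shape, path_length_px, curvature)
        for k in range(n_bundles)
    ]
    image = np.zeros(shape, dtype=float)
    per_path = total_intensity / n_paths
    for i in range(n_paths):
        decide = substream(config.seed, 4, i)
        bundled = n_paths > 1 and decide.uniform() < bundling
        if bundled:
            k = decide.integers(n_bundles)
            jrng = substream(config.seed, 5, i)
            pts = centerlines[k] + jrng.normal(0.0, jitter_px, size=centerlines[k].shape)
        else:
            pts = _random_walk(substream(config.seed, 6, i), shape, path_length_px, curvature)
        _deposit(image, pts, per_path)

    rendered = apply_psf(image, config.psf_sigma_px)
    rendered = apply_noise(rendered, config.noise, substream(config.seed, 2))
    scene = ImageScene(rendered, pixel_size=config.pixel_size, channel_names=["filament"])
    truth = FilamentSceneTruth(
        bundling=bundling, n_paths=n_paths, total_intensity=total_intensity
    )
    return scene, truth
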