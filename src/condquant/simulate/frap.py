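"""Synthetic FRAP acquisitions with acquisition photobleaching.

The underlying relative recovery is
``r(t) = plateau + (bleach_depth - plateau)·exp(-t/tau)`` for t ≥ 0 and
1 before the bleach. Raw ROI and whole-cell signals are both multiplied by
an acquisition-bleaching envelope ``exp(-λ·(t - t_start))``, offset by
constant backgrounds and noised — the structure that double normalization
is designed to undo exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ..frap import FrapTrace
from .base import substream


@dataclass(frozen=True)
class FrapSeriesTruth:
    """Ground truth of a simulated bleaching event.

    ``tau`` is the recovery time constant (min); ``bleach_depth`` and
    ``plateau`` are fractions of the pre-bleach signal immediately after
    the bleach and at infinite time; ``photobleach_rate`` λ (per min) is
    the multiplicative acquisition-bleaching rate applied to all raw
    signals; ``background_level`` is a constant offset in intensity units.
    """

    tau: float
    bleach_depth: float = 0.4
    plateau: float = 0.9
    photobleach_rate: float = 0.0
    background_level: float = 0.0

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.bleach_depth <= self.plateau <= 1:
            raise ValueError("need 0 <= bleach_depth <= plateau <= 1")
        if self.photobleach_rate < 0 or self.background_level < 0:
            raise ValueError("rates and backgrounds must be non-negative")

    @property
    def t_half(self) -> float:
        return self.tau * math.log(2.0)

    def relative_recovery(self, time: np.ndarray) -> np.ndarray:
        t = np.asarray(time, dtype=float)
        rec = self.plateau + (self.bleach_depth - self.plateau) * np.exp(-t / self.tau)
        return np.where(t < 0, 1.0, rec)


def generate_frap_series(
    truth: FrapSeriesTruth,
    timepoints: np.ndarray,
    noise_sigma: float = 0.0,
    n_prebleach: int = 5,
    seed: int = 0,
    roi_fraction: float = 0.2,
    cell_intensity: float = 1000.0,
) -> FrapTrace:
    """Simulate the four raw signals of one bleaching event.

    ``timepoints`` (min) covers the whole acquisition with the first
    ``n_prebleach`` frames before the bleach (negative times) and t = 0 at
    the first post-bleach frame. ``noise_sigma`` is Gaussian, in intensity
    units. The exported truth carries the recovery half-time.
    """
    time = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(time) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if n_prebleach < 2:
        raise ValueError("need at least 2 pre-bleach frames")
    if n_prebleach >= len(time):
        raise ValueError("need at least one post-bleach frame")
    if time[n_prebleach - 1] >= 0 or time[n_prebleach] < 0:
        raise ValueError(
            "pre-bleach times must be negative and t=0 at the first post-bleach frame"
        )

    envelope = np.exp(-truth.photobleach_rate * (time - time[0]))
    cell = cell_intensity * envelope
    roi = roi_fraction * cell * truth.relative_recovery(time)
    bg = np.full_like(time, truth.background_level)

    rng = substream(seed, 7)
    def noised(x: np.ndarray) -> np.ndarray:
        return x + rng.normal(0.0, noise_sigma, size=x.shape) if noise_sigma > 0 else x

    return FrapTrace(
        time=time,
        roi=noised(roi + truth.background_level),
        roi_background=noised(bg.copy()),
        cell_total=noised(cell + truth.background_level),
        cell_background=noised(bg.copy()),
        n_prebleach=n_prebleach,
    )
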