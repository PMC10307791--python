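"""FRAP normalization, single-exponential recovery fitting and aggregation.

Two normalization modes are supported:

* ``in_vivo`` — double normalization: the background-corrected bleached-ROI
  intensity is divided by the background-corrected whole-cell intensity,
  which exactly cancels any multiplicative, frame-wise acquisition
  photobleaching shared by the two signals; the result is anchored so the
  pre-bleach mean is 100%.
* ``in_vitro`` — the background-corrected ROI intensity is anchored so the
  pre-bleach mean is 100% (no whole-cell reference is available in a
  droplet field).

Recovery is fitted with the single exponential ``y = y0 + A·exp(-x/t)``
on post-bleach points only (A is negative for a recovering signal); the
half-maximal recovery time is ``t_half = t·ln 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "FrapTrace",
    "FrapFit",
    "AggregateRecovery",
    "normalize_frap_trace",
    "fit_recovery",
    "aggregate_recovery",
]

LN2 = math.log(2.0)


@dataclass
class FrapTrace:
    """Raw signals of one bleaching event.

    ``time`` is in minutes with t = 0 at the first post-bleach frame
    (pre-bleach frames carry negative times). All series share one length;
    the first ``n_prebleach`` frames precede the bleach.
    """

    time: np.ndarray
    roi: np.ndarray
    roi_background: np.ndarray
    cell_total: np.ndarray
    cell_background: np.ndarray
    n_prebleach: int

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("roi", "roi_background", "cell_total", "cell_background"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != self.time.shape:
                raise ValueError(f"{name} must have the same length as time")
            setattr(self, name, arr)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not 1 <= self.n_prebleach < len(self.time):
            raise ValueError("need >= 1 pre-bleach and >= 1 post-bleach frame")

    @property
    def post_slice(self) -> slice:
        return slice(self.n_prebleach, None)


@dataclass(frozen=True)
class FrapFit:
    """Parameters of ``y = y0 + A·exp(-x/t)`` fitted to a recovery (percent).

    ``t`` is the recovery rate constant in minutes and ``t_half = t·ln 2``
    the half-maximal recovery time. ``immobile_fraction`` is a derived
    convenience metric (1 − mobile fraction, relative to a 100% pre-bleach
    anchor), not part of the original assay readout.
    """

    y0: float
    A: float
    t: float
    t_half: float
    rss: float
    converged: bool
    message: str = ""

    @property
    def mobile_fraction(self) -> float:
        start = self.y0 + self.A
        denom = 100.0 - start
        return float("nan") if denom == 0 else -self.A / denom

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.mobile_fraction


def normalize_frap_trace(trace: FrapTrace, mode: str = "in_vivo") -> np.ndarray:
    """Normalize a raw trace to percent of the pre-bleach signal.

    Raises if a background-corrected denominator is non-positive at any
    frame (the error names the frame).
    """
    if mode not in ("in_vivo", "in_vitro"):
        raise ValueError(f"mode must be 'in_vivo' or 'in_vitro', got {mode!r}")
    roi = trace.roi - trace.roi_background
    if mode == "in_vivo":
        cell = trace.cell_total - trace.cell_background
        bad = np.flatnonzero(cell <= 0)
        if bad.size:
            raise ValueError(
                f"non-positive corrected cell intensity at frame {bad[0]}"
            )
        rel = roi / cell
    else:
        rel = roi
    pre = rel[: trace.n_prebleach].mean()
    if pre <= 0:
        raise ValueError("non-positive pre-bleach mean; cannot anchor to 100%")
    return 100.0 * rel / pre


def _initial_guess(time: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    n_tail = max(1, int(round(0.1 * len(y))))
    y0 = float(y[-n_tail:].mean())
    A = float(y[0] - y0)
    target = y0 + A / math.e
    span = float(time[-1] - time[0])
    t0 = 0.5 * span if span > 0 else 1.0
    if A != 0:
        crossed = np.flatnonzero((y - target) * np.sign(A) <= 0)
        if crossed.size:
            t_cross = float(time[crossed[0]] - time[0])
            if t_cross > 0:
                t0 = t_cross
    return y0, A, t0


def fit_recovery(series: np.ndarray, time: np.ndarray) -> FrapFit:
    """Least-squares single-exponential fit of post-bleach recovery data.

    ``time`` starts at the first post-bleach frame. Deterministic: fixed
    initialization (plateau from the last 10% of points, amplitude from the
    first point, rate from the 1/e crossing), bounds t ∈ (0, 100×span], no
    random restarts. Non-convergence and degenerate (flat) series are
    reported via ``converged=False`` rather than raised.
    """
    time = np.asarray(time, dtype=float)
    y = np.asarray(series, dtype=float)
    if len(y) < 5:
        raise ValueError("need at least 5 post-bleach points to fit")
    if len(y) != len(time):
        raise ValueError("series and time must have equal length")

    y0_init, a_init, t_init = _initial_guess(time, y)
    span = float(time[-1] - time[0])
    t_max = 100.0 * span if span > 0 else 100.0
    x = time - time[0]

    def model(xv, y0, a, t):
        return y0 + a * np.exp(-xv / t)

    scale = max(1.0, float(np.abs(y).max()))
    if abs(a_init) < 1e-9 * scale:
        return FrapFit(
            y0=y0_init, A=0.0, t=float("nan"), t_half=float("nan"),
            rss=float(((y - y0_init) ** 2).sum()), converged=False,
            message="flat series: recovery amplitude ~0, rate unidentifiable",
        )
    try:
        popt, pcov = curve_fit(
            model,
            x,
            y,
            p0=(y0_init, a_init, min(max(t_init, 1e-6), t_max)),
            bounds=([-np.inf, -np.inf, 1e-12], [np.inf, np.inf, t_max]),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        return FrapFit(
            y0=y0_init, A=a_init, t=float("nan"), t_half=float("nan"),
            rss=float("nan"), converged=False, message=str(exc),
        )
    y0_f, a_f, t_f = (float(v) for v in popt)
    rss = float(((y - model(x, *popt)) ** 2).sum())
    identifiable = np.all(np.isfinite(pcov)) and abs(a_f) > 1e-9 * scale
    return FrapFit(
        y0=y0_f, A=a_f, t=t_f, t_half=t_f * LN2, rss=rss,
        converged=bool(identifiable), message="" if identifiable else "unidentifiable fit",
    )


@dataclass
class AggregateRecovery:
    """Mean ± STDEV recovery over events on a common grid, plus fits."""

    time: np.ndarray
    mean: np.ndarray
    stdev: np.ndarray
    pooled_fit: FrapFit
    event_fits: list[FrapFit] = field(default_factory=list)


def aggregate_recovery(
    traces: list[tuple[np.ndarray, np.ndarray]], n_grid: int = 50
) -> AggregateRecovery:
    """Aggregate ≥ 2 normalized post-bleach recoveries.

    Traces (``(time, values)`` pairs) are resampled by linear interpolation
    onto a common grid spanning their shared time range; the per-timepoint
    mean and population STDEV are reported together with a single fit of
    the mean curve and the per-event fits.
    """
    if len(traces) < 2:
        raise ValueError("need at least 2 bleaching events to aggregate")
    starts = [float(np.asarray(t)[0]) for t, _ in traces]
    ends = [float(np.asarray(t)[-1]) for t, _ in traces]
    lo, hi = max(starts), min(ends)
    if hi <= lo:
        raise ValueError("traces have disjoint time ranges")
    times = [np.asarray(t, float) for t, _ in traces]
    if all(len(t) == len(times[0]) and np.array_equal(t, times[0]) for t in times):
        grid = times[0]  # shared acquisition grid: no resampling bias
    else:
        grid = np.linspace(lo, hi, n_grid)
    resampled = np.vstack(
        [np.interp(grid, np.asarray(t, float), np.asarray(v, float)) for t, v in traces]
    )
    mean = resampled.mean(axis=0)
    stdev = resampled.std(axis=0)  # population
    return AggregateRecovery(
        time=grid,
        mean=mean,
        stdev=stdev,
        pooled_fit=fit_recovery(mean, grid),
        event_fits=[fit_recovery(np.asarray(v, float), np.asarray(t, float)) for t, v in traces],
    )
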