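"""Linearly decreasing A340 traces for the NADH-coupled GTPase assay.

The noiseless reaction trace follows
``A(t) = A0 - ε·l·(v + v_bg)·t`` and the no-enzyme control
``A(t) = A0 - ε·l·v_bg·t``, so control subtraction leaves a slope of
``-ε·l·v`` — the Beer–Lambert image of the enzymatic NADH oxidation
rate v alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..gtpase import EPSILON_NADH_340, LIGHT_PATH_CM, AbsorbanceTrace
from .base import substream


@dataclass(frozen=True)
class AbsorbanceTruth:
    """Hidden parameters: rates in M/min, absorbances in AU."""

    nadh_rate: float  # v: enzymatic NADH consumption
    background_rate: float = 0.0  # spontaneous hydrolysis + UV decomposition
    a0: float = 3.1  # 0.5 mM NADH over a 0.248 cm path plus buffer offset
    noise_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.nadh_rate < 0 or self.background_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


def generate_absorbance_trace(
    truth: AbsorbanceTruth,
    timepoints: np.ndarray,
    seed: int = 0,
    epsilon: float = EPSILON_NADH_340,
    light_path_cm: float = LIGHT_PATH_CM,
    enzyme_uM: float = 0.0,
) -> tuple[AbsorbanceTrace, AbsorbanceTrace]:
    """Paired (reaction, no-enzyme control) traces; deterministic under seed.

    Raises if NADH would be depleted (noiseless A(t) < 0) within the
    window, naming the time of depletion.
    """
    time = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(time) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    el = epsilon * light_path_cm
    reaction = truth.a0 - el * (truth.nadh_rate + truth.background_rate) * time
    control = truth.a0 - el * truth.background_rate * time
    if np.any(reaction < 0):
        t_dep = float(time[np.argmax(reaction < 0)])
        raise ValueError(f"NADH depleted (A340 < 0) at t = {t_dep:.2f} min")

    rng = substream(seed, 10)
    if truth.noise_sigma > 0:
        reaction = reaction + rng.normal(0.0, truth.noise_sigma, size=time.shape)
        control = control + rng.normal(0.0, truth.noise_sigma, size=time.shape)
    return (
        AbsorbanceTrace(time=time, a340=reaction, enzyme_uM=enzyme_uM, condition="reaction"),
        AbsorbanceTrace(time=time, a340=control, enzyme_uM=0.0, condition="control"),
    )
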