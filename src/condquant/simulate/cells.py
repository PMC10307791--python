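"""Single-cell snapshot populations with known cluster size scaling.

Cell lengths are sampled uniformly on a stated interval; each cell carries
one elliptical cluster whose long axis follows the linear scaling
``axis = intercept + slope·length (+ noise)`` and a total fluorescence of
``concentration × cell area``, i.e. a constant fluorescence concentration
across the population — the condensate size-scaling regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

from ..cells import CellRecord
from .base import substream


class SnapshotParams(BaseModel, extra="forbid"):
    """Population parameters. Lengths and axes in µm; intensities in AU."""

    slope: float = 0.12  # cluster long axis gained per µm of cell length
    intercept: float = 0.15  # µm
    concentration: float = Field(default=20.0, gt=0)  # AU per px of cell area
    length_range_um: tuple[float, float] = (3.0, 8.0)
    axis_noise_um: float = Field(default=0.0, ge=0)
    cell_width_um: float = Field(default=0.7, gt=0)
    cluster_aspect: float = Field(default=1.6, ge=1)
    cluster_fraction_of_total: float = Field(default=0.5, gt=0, lt=1)
    pixel_size_nm: float = Field(default=100.0, gt=0)
    margin_px: int = Field(default=3, ge=1)


@dataclass(frozen=True)
class SnapshotTruth:
    slope: float
    intercept: float
    concentration: float
    cell_lengths_um: np.ndarray
    cluster_axes_um: np.ndarray  # noise included: the value actually drawn


def _ellipse(shape, center, a_px, b_px) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / b_px) ** 2 + ((cc - center[1]) / a_px) ** 2 <= 1.0


def generate_cell_snapshots(
    n_cells: int,
    params: SnapshotParams | None = None,
    seed: int = 0,
) -> tuple[list[CellRecord], SnapshotTruth]:
    """Render ``n_cells`` snapshot cells with exported scaling truth.

    Each record is an independent small canvas with one rod cell and one
    midcell cluster. Total cell intensity is exactly ``concentration ×
    area``; the cluster holds a fixed fraction of it, spread over an
    ellipse whose long axis encodes the scaling law.
    """
    if n_cells < 2:
        raise ValueError("need at least 2 cells")
    if params is None:
        params = SnapshotParams()
    p = params
    px_um = p.pixel_size_nm / 1000.0

    records: list[CellRecord] = []
    lengths, axes = [], []
    for i in range(n_cells):
        rng = substream(seed, 9, i)
        length_um = rng.uniform(*p.length_range_um)
        axis_um = p.intercept + p.slope * length_um
        if p.axis_noise_um > 0:
            axis_um += rng.normal(0.0, p.axis_noise_um)
        axis_um = max(axis_um, 3 * px_um)  # keep the cluster resolvable

        length_px = max(8, int(round(length_um / px_um)))
        width_px = max(3, int(round(p.cell_width_um / px_um)))
        shape = (width_px + 2 * p.margin_px, length_px + 2 * p.margin_px)
        cell_mask = np.zeros(shape, dtype=bool)
        cell_mask[p.margin_px : p.margin_px + width_px, p.margin_px : p.margin_px + length_px] = True

        center = (p.margin_px + width_px // 2, p.margin_px + length_px // 2)
        a_px = max(1.0, 0.5 * axis_um / px_um)
        b_px = max(1.0, a_px / p.cluster_aspect)
        cluster = (_ellipse(shape, center, a_px, b_px) & cell_mask).astype(np.int32)

        area = int(cell_mask.sum())
        total = p.concentration * area
        cluster_total = p.cluster_fraction_of_total * total
        n_cpix = int((cluster > 0).sum())
        img = np.zeros(shape, dtype=float)
        img[cell_mask] = (total - cluster_total) / (area - n_cpix)
        if n_cpix:
            img[cluster > 0] = cluster_total / n_cpix

        records.append(
            CellRecord(
                cell_mask=cell_mask, cluster_mask=cluster, image=img,
                cell_length_um=length_um, pixel_size_nm=p.pixel_size_nm,
            )
        )
        lengths.append(length_um)
        axes.append(axis_um)

    truth = SnapshotTruth(
        slope=p.slope, intercept=p.intercept, concentration=p.concentration,
        cell_lengths_um=np.array(lengths), cluster_axes_um=np.array(axes),
    )
    return records, truth
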