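"""Rod-cell division time-lapses with cluster fission or disintegration.

A mother rod carries one bright cluster on a diffuse cytoplasmic
background; after division two daughter rods appear. In *fission* mode the
mother's cluster intensity M reappears in the daughters' clusters as
``c·f·M`` and ``c·(1-f)·M`` (c = conservation, f = asymmetry); in
*disintegration* mode the daughters carry no clusters and a fraction c of
the mother's **total** signal is redistributed diffusely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field

from ..cells import CellRecord
from .base import substream


@dataclass(frozen=True)
class DivisionTruth:
    """Hidden parameters of one simulated division event."""

    conservation: float  # c: fraction of signal recovered in the daughters
    asymmetry: float = 0.5  # f: fraction of conserved cluster signal in daughter 1
    mode: Literal["fission", "disintegration"] = "fission"

    def __post_init__(self) -> None:
        if not 0 <= self.conservation <= 1:
            raise ValueError("conservation must lie in [0, 1]")
        if not 0 <= self.asymmetry <= 1:
            raise ValueError("asymmetry must lie in [0, 1]")
        if self.mode not in ("fission", "disintegration"):
            raise ValueError("mode must be 'fission' or 'disintegration'")


class DivisionGeometry(BaseModel, extra="forbid"):
    """Cell and cluster geometry in pixels; intensities in arbitrary units."""

    mother_length_px: int = Field(default=60, ge=20)
    width_px: int = Field(default=9, ge=3)
    septum_px: int = Field(default=2, ge=1)
    cluster_radius_px: int = Field(default=3, ge=1)
    diffuse_level: float = Field(default=5.0, gt=0)
    cluster_intensity: float = Field(default=500.0, gt=0)
    min_daughter_length_px: int = Field(default=8, ge=4)
    margin_px: int = Field(default=4, ge=1)
    noise_sigma: float = Field(default=0.5, ge=0)
    pixel_size_nm: float = Field(default=100.0, gt=0)


def _rod(canvas_shape, row0, col0, length, width) -> np.ndarray:
    mask = np.zeros(canvas_shape, dtype=bool)
    mask[row0 : row0 + width, col0 : col0 + length] = True
    return mask


def _disc(canvas_shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: canvas_shape[0], : canvas_shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_division_timelapse(
    truth: DivisionTruth,
    geometry: DivisionGeometry | None = None,
    seed: int = 0,
) -> tuple[CellRecord, tuple[CellRecord, CellRecord], DivisionTruth]:
    """Simulate one division: mother frame, then two daughters.

    Returns (mother record, (daughter 1, daughter 2), truth). The mother's
    cluster sits at midcell; daughters inherit half the rod each. Masks are
    consistent across frames; Gaussian noise (``geometry.noise_sigma``) is
    added inside the cells only, so background correction stays exact at 0.
    """
    if geometry is None:
        geometry = DivisionGeometry()
    g = geometry
    daughter_len = (g.mother_length_px - g.septum_px) // 2
    if daughter_len < g.min_daughter_length_px:
        raise ValueError(
            f"mother of {g.mother_length_px} px splits into daughters of "
            f"{daughter_len} px < minimum {g.min_daughter_length_px} px"
        )

    shape = (g.width_px + 2 * g.margin_px, g.mother_length_px + 2 * g.margin_px)
    row0, col0 = g.margin_px, g.margin_px
    rng = substream(seed, 8)

    def render(cell_mask, cluster_label, cluster_amounts, diffuse):
        # cluster pixels carry exactly the cluster's integrated intensity,
        # so mask-based accounting recovers the generator's bookkeeping
        img = np.zeros(shape, dtype=float)
        img[cell_mask] = diffuse
        for lab, amount in cluster_amounts.items():
            pix = cluster_label == lab
            if pix.any() and amount > 0:
                img[pix] = amount / pix.sum()
        if g.noise_sigma > 0:
            img[cell_mask] += rng.normal(0.0, g.noise_sigma, size=int(cell_mask.sum()))
            img = np.clip(img, 0.0, None)
        return img

    # --- mother frame -----------------------------------------------------
    mother_mask = _rod(shape, row0, col0, g.mother_length_px, g.width_px)
    center = (row0 + g.width_px // 2, col0 + g.mother_length_px // 2)
    mother_cluster = np.where(
        _disc(shape, center, g.cluster_radius_px) & mother_mask, 1, 0
    ).astype(np.int32)
    mother_img = render(mother_mask, mother_cluster, {1: g.cluster_intensity}, g.diffuse_level)
    px_nm = g.pixel_size_nm
    mother = CellRecord(
        cell_mask=mother_mask, cluster_mask=mother_cluster, image=mother_img,
        cell_length_um=g.mother_length_px * px_nm / 1000.0, pixel_size_nm=px_nm,
    )

    # --- daughter frame ---------------------------------------------------
    n_cluster_px = int((mother_cluster > 0).sum())
    mother_total = (
        g.diffuse_level * (mother_mask.sum() - n_cluster_px) + g.cluster_intensity
    )
    d_records = []
    for i in range(2):
        col = col0 + i * (daughter_len + g.septum_px)
        d_mask = _rod(shape, row0, col, daughter_len, g.width_px)
        d_center = (row0 + g.width_px // 2, col + daughter_len // 2)
        if truth.mode == "fission":
            share = truth.asymmetry if i == 0 else 1.0 - truth.asymmetry
            amount = truth.conservation * share * g.cluster_intensity
            d_cluster = (
                np.where(_disc(shape, d_center, g.cluster_radius_px) & d_mask, 1, 0)
                if amount > 0
                else np.zeros(shape, dtype=int)
            ).astype(np.int32)
            diffuse = g.diffuse_level
        else:  # disintegration: c of the mother's *total* signal, all diffuse
            d_cluster = np.zeros(shape, dtype=np.int32)
            amount = 0.0
            diffuse = truth.conservation * mother_total / (2 * d_mask.sum())
        d_img = render(d_mask, d_cluster, {1: amount}, diffuse)
        d_records.append(
            CellRecord(
                cell_mask=d_mask, cluster_mask=d_cluster, image=d_img,
                cell_length_um=daughter_len * px_nm / 1000.0, pixel_size_nm=px_nm,
            )
        )
    return mother, (d_records[0], d_records[1]), truth
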