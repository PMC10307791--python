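"""Per-cell cluster quantification from segmentation masks.

Quantities measured from a fluorescence image plus cell and cluster masks:
background-corrected total/cluster/cytoplasm intensities and areas, the
corresponding *fluorescence concentrations* (intensity per area, a proxy
for protein concentration), the cluster-over-cytoplasm enrichment factor,
cluster geometry (ellipse-equivalent axes from mask moments), cluster-size
vs cell-length scaling, mother→daughter intensity conservation across
division, per-cell cluster counting, and the colocalization of division
constrictions with clusters.

Cell outlines (and their midline lengths) are inputs: they come from an
external phase-contrast segmentation, not from this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from skimage import measure

__all__ = [
    "CellRecord",
    "CellMeasures",
    "DivisionEvent",
    "measure_cell",
    "cluster_geometry",
    "axis_length_regression",
    "measure_cluster_axes",
    "division_conservation",
    "count_clusters",
    "constriction_colocalization",
    "absolute_concentration",
]


@dataclass
class CellRecord:
    """One cell: masks, image and metadata.

    ``cluster_mask`` is a label image (0 = no cluster) that must lie inside
    the boolean ``cell_mask``; ``cell_length_um`` is the midline length
    supplied with the mask; ``background`` is the per-image scalar
    background level (mean intensity outside all cell masks).
    """

    cell_mask: np.ndarray
    cluster_mask: np.ndarray
    image: np.ndarray
    cell_length_um: float
    background: float = 0.0
    pixel_size_nm: float = 1.0

    def __post_init__(self) -> None:
        self.cell_mask = np.asarray(self.cell_mask, dtype=bool)
        self.cluster_mask = np.asarray(self.cluster_mask)
        self.image = np.asarray(self.image, dtype=float)
        if not (self.cell_mask.shape == self.cluster_mask.shape == self.image.shape):
            raise ValueError("cell mask, cluster mask and image must be congruent")
        if self.cell_length_um <= 0:
            raise ValueError("cell length must be positive (µm)")
        if np.any((self.cluster_mask > 0) & ~self.cell_mask):
            raise ValueError("cluster pixels found outside the cell mask")

    @property
    def n_clusters(self) -> int:
        labels = np.unique(self.cluster_mask)
        return int((labels > 0).sum())


@dataclass(frozen=True)
class CellMeasures:
    """Background-corrected intensity accounting of one cell.

    Intensities and areas satisfy total = cluster + cytoplasm exactly;
    concentrations are intensity/area; the enrichment factor is the cluster
    concentration over the cytoplasm concentration (NaN and flagged when
    the cell has no cluster).
    """

    total_intensity: float
    cluster_intensity: float
    cytoplasm_intensity: float
    total_area: int
    cluster_area: int
    cytoplasm_area: int
    cell_concentration: float
    cluster_concentration: float
    cytoplasm_concentration: float
    enrichment_factor: float
    has_cluster: bool


def measure_cell(record: CellRecord) -> CellMeasures:
    """Compute the :class:`CellMeasures` accounting for one cell."""
    corrected = record.image - record.background
    cell, cluster = record.cell_mask, (record.cluster_mask > 0)
    cyto = cell & ~cluster

    total_i = float(corrected[cell].sum())
    cluster_i = float(corrected[cluster].sum())
    cyto_i = float(corrected[cyto].sum())
    total_a, cluster_a, cyto_a = int(cell.sum()), int(cluster.sum()), int(cyto.sum())
    if total_a == 0:
        raise ValueError("empty cell mask")

    cell_c = total_i / total_a
    cluster_c = cluster_i / cluster_a if cluster_a else float("nan")
    cyto_c = cyto_i / cyto_a if cyto_a else float("nan")
    enrich = (
        cluster_c / cyto_c
        if cluster_a and cyto_a and cyto_c != 0
        else float("nan")
    )
    return CellMeasures(
        total_intensity=total_i,
        cluster_intensity=cluster_i,
        cytoplasm_intensity=cyto_i,
        total_area=total_a,
        cluster_area=cluster_a,
        cytoplasm_area=cyto_a,
        cell_concentration=cell_c,
        cluster_concentration=cluster_c,
        cytoplasm_concentration=cyto_c,
        enrichment_factor=enrich,
        has_cluster=cluster_a > 0,
    )


def cluster_geometry(
    cluster_mask: np.ndarray, pixel_size_nm: float
) -> tuple[float, float, float]:
    """Ellipse-equivalent (long_axis_um, short_axis_um, aspect_ratio).

    Axes are the major/minor axis lengths of the ellipse with the same
    second central moments as the (intensity-unweighted) mask; the aspect
    ratio is long/short ≥ 1.
    """
    mask = np.asarray(cluster_mask) > 0
    if not mask.any():
        raise ValueError("empty cluster mask")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    long_um = props.axis_major_length * pixel_size_nm / 1000.0
    short_um = props.axis_minor_length * pixel_size_nm / 1000.0
    ar = long_um / short_um if short_um > 0 else float("inf")
    return float(long_um), float(short_um), float(ar)


def axis_length_regression(
    cell_lengths_um: np.ndarray, axis_lengths_um: np.ndarray
) -> tuple[float, float, float]:
    """OLS of cluster axis length against cell length: (slope, intercept, r²)."""
    x = np.asarray(cell_lengths_um, dtype=float)
    y = np.asarray(axis_lengths_um, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 cells for the scaling regression")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in cell length")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def measure_cluster_axes(
    records: list[CellRecord], axis: str = "long"
) -> tuple[np.ndarray, np.ndarray]:
    """(cell lengths, measured cluster axis lengths) over cells with one cluster."""
    if axis not in ("long", "short"):
        raise ValueError("axis must be 'long' or 'short'")
    lengths, axes = [], []
    for rec in records:
        if rec.n_clusters == 0:
            continue
        long_um, short_um, _ = cluster_geometry(rec.cluster_mask, rec.pixel_size_nm)
        lengths.append(rec.cell_length_um)
        axes.append(long_um if axis == "long" else short_um)
    return np.array(lengths), np.array(axes)


@dataclass(frozen=True)
class DivisionEvent:
    """Mother→daughters intensity accounting across one division."""

    mother: CellMeasures
    daughters: tuple[CellMeasures, CellMeasures]
    conservation_cluster: float  # percent of mother's cluster intensity
    conservation_total: float  # percent of mother's total intensity


def division_conservation(
    mother: CellRecord, daughters: tuple[CellRecord, CellRecord]
) -> DivisionEvent:
    """Fraction of the mother's signal recovered in her daughters.

    ``conservation_cluster`` = 100 × Σ daughter cluster intensity / mother
    cluster intensity (near 100% for clusters that undergo fission, 0 for
    clusters that disintegrate); ``conservation_total`` is the same ratio
    for total cellular intensity. Both are background-corrected.
    """
    m = measure_cell(mother)
    d = tuple(measure_cell(rec) for rec in daughters)
    if m.cluster_intensity <= 0:
        raise ValueError("mother cluster intensity must be positive")
    cons_cluster = 100.0 * sum(x.cluster_intensity for x in d) / m.cluster_intensity
    if m.total_intensity <= 0:
        raise ValueError("mother total intensity must be positive")
    cons_total = 100.0 * sum(x.total_intensity for x in d) / m.total_intensity
    return DivisionEvent(
        mother=m, daughters=d,
        conservation_cluster=cons_cluster, conservation_total=cons_total,
    )


@dataclass(frozen=True)
class ClusterCountSummary:
    counts: np.ndarray
    histogram: dict[int, int]
    mean_with_cluster: float  # mean over cells with >= 1 cluster; NaN if none
    n_cells: int
    n_cells_with_cluster: int


def count_clusters(records: list[CellRecord]) -> ClusterCountSummary:
    """Per-cell cluster-count distribution.

    The mean is computed over cells with at least one cluster only (cells
    without clusters are excluded from the mean, not from the histogram);
    with no clustered cells the mean is NaN.
    """
    counts = np.array([rec.n_clusters for rec in records], dtype=int)
    values, freq = np.unique(counts, return_counts=True)
    with_cluster = counts[counts > 0]
    mean = float(with_cluster.mean()) if with_cluster.size else float("nan")
    return ClusterCountSummary(
        counts=counts,
        histogram=dict(zip(values.tolist(), freq.tolist())),
        mean_with_cluster=mean,
        n_cells=len(counts),
        n_cells_with_cluster=int(with_cluster.size),
    )


def constriction_colocalization(
    constriction_positions_um: np.ndarray,
    cluster_centroids_um: np.ndarray,
    tolerance_um: float = 0.5,
) -> float:
    """Fraction of division constrictions with a cluster within tolerance.

    Positions are 1D coordinates along the cell long axis in µm. Returns 0
    for an empty cluster list; raises on an empty constriction list.
    """
    cons = np.atleast_1d(np.asarray(constriction_positions_um, dtype=float))
    clus = np.atleast_1d(np.asarray(cluster_centroids_um, dtype=float))
    if cons.size == 0:
        raise ValueError("no constrictions supplied")
    if clus.size == 0:
        return 0.0
    dists = np.abs(cons[:, None] - clus[None, :]).min(axis=1)
    return float((dists <= tolerance_um).mean())


def absolute_concentration(
    enrichment_factor: float,
    cytoplasm_concentration_uM: float,
    cluster_volume_fraction: float = 1.0,
) -> float:
    """Cluster concentration in µM from an enrichment factor.

    Converts a measured (2D, area-based) enrichment factor and an
    independently estimated cytoplasmic concentration into an absolute
    cluster concentration, with a user-supplied volume fraction correcting
    for the projection of a 3D cluster into the 2D measurement. The volume
    assumptions are the caller's; no default beyond the identity is implied.
    """
    if cytoplasm_concentration_uM <= 0 or cluster_volume_fraction <= 0:
        raise ValueError("concentration and volume fraction must be positive")
    return enrichment_factor * cytoplasm_concentration_uM / cluster_volume_fraction
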