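"""Contact-graph construction, structural validation metrics and sectioning.

The four metrics used to check that simulated aggregates look like real
embryoid bodies: projected radius, projected circularity, per-cell connection
count and per-edge connection length.  Also provides the virtual confocal
section (a 10 µm slab projected to 2D) and the connected-component helper
used by the cluster statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import Aggregate, CellAgent, _contact_pairs

__all__ = [
    "DEFAULT_CONTACT_SLACK",
    "SectionView",
    "StructureReport",
    "build_contact_graph",
    "aggregate_radius",
    "circularity",
    "footprint_metrics",
    "connection_stats",
    "virtual_section",
    "structure_report",
    "state_cluster_sizes",
    "count_state_clusters",
]

#: "Adjacent" means centre distance within (r_i + r_j) times (1 + slack).
DEFAULT_CONTACT_SLACK = 0.05

#: Raster resolution for projected-footprint measurements (µm per pixel).
FOOTPRINT_RESOLUTION = 0.25

_AXES = {"x": 0, "y": 1, "z": 2}


def build_contact_graph(
    cells: Aggregate | list[CellAgent],
    contact_slack: float = DEFAULT_CONTACT_SLACK,
) -> Aggregate:
    """Build (or rebuild) the contact graph of an aggregate.

    Accepts an :class:`Aggregate` (updated in place and returned) or a list of
    :class:`CellAgent`.  Edge (i, j) exists iff the centre distance is at most
    (r_i + r_j)(1 + contact_slack); edge length is the centre distance.
    """
    agg = cells if isinstance(cells, Aggregate) else Aggregate.from_cells(cells)
    agg.refresh_edges(contact_slack=contact_slack)
    return agg


def _footprint_mask(
    agg: Aggregate, projection_axis: str = "z", resolution: float = FOOTPRINT_RESOLUTION
) -> np.ndarray:
    """Boolean raster of the union of projected disks."""
    if agg.n_cells == 0:
        raise ValueError("empty aggregate")
    ax = _AXES[projection_axis]
    keep = [a for a in range(3) if a != ax]
    xy = agg.positions[:, keep]
    r = agg.radii
    lo = (xy - r[:, None]).min(axis=0) - resolution
    hi = (xy + r[:, None]).max(axis=0) + resolution
    nx_, ny_ = (np.ceil((hi - lo) / resolution)).astype(int) + 1
    mask = np.zeros((nx_, ny_), dtype=bool)
    # paint each disk into its local bounding patch
    for k in range(agg.n_cells):
        cx, cy = (xy[k] - lo) / resolution
        rr = r[k] / resolution
        x0, x1 = int(cx - rr) - 1, int(cx + rr) + 2
        y0, y1 = int(cy - rr) - 1, int(cy + rr) + 2
        gx = np.arange(max(x0, 0), min(x1, nx_))
        gy = np.arange(max(y0, 0), min(y1, ny_))
        if len(gx) == 0 or len(gy) == 0:
            continue
        dx = (gx - cx)[:, None]
        dy = (gy - cy)[None, :]
        mask[np.ix_(gx, gy)] |= dx * dx + dy * dy <= rr * rr
    return mask


def footprint_metrics(
    agg: Aggregate, projection_axis: str = "z", resolution: float = FOOTPRINT_RESOLUTION
) -> tuple[float, float]:
    """(equivalent-circle radius µm, circularity) of the projected footprint.

    Radius is that of the circle whose area equals the projected 2D footprint
    (union of projected disks).  Circularity is the minor/major axis ratio of
    the second-moment-equivalent ellipse of the footprint mask, in (0, 1].
    """
    mask = _footprint_mask(agg, projection_axis, resolution)
    area = mask.sum() * resolution**2
    radius = float(np.sqrt(area / np.pi))
    pts = np.argwhere(mask).astype(float)
    pts -= pts.mean(axis=0)
    cov = pts.T @ pts / len(pts)
    eig = np.linalg.eigvalsh(cov)
    eig = np.clip(eig, 0.0, None)
    circ = 1.0 if eig[1] == 0 else float(np.sqrt(eig[0] / eig[1]))
    return radius, min(circ, 1.0)


def aggregate_radius(
    agg: Aggregate, projection_axis: str = "z", resolution: float = FOOTPRINT_RESOLUTION
) -> float:
    """Radius (µm) of the circle matching the projected footprint area."""
    return footprint_metrics(agg, projection_axis, resolution)[0]


def circularity(
    agg: Aggregate, projection_axis: str = "z", resolution: float = FOOTPRINT_RESOLUTION
) -> float:
    """Minor/major axis ratio of the footprint's moment-equivalent ellipse."""
    return footprint_metrics(agg, projection_axis, resolution)[1]


@dataclass
class ConnectionStats:
    mean_count: float
    sd_count: float
    mean_length: float
    sd_length: float


def connection_stats(agg: Aggregate) -> ConnectionStats:
    """Per-cell degree and per-edge length statistics of the contact graph."""
    if agg.n_cells == 0 or len(agg.edges) == 0:
        warnings.warn("connection_stats on an empty contact graph", stacklevel=2)
        return ConnectionStats(0.0, 0.0, 0.0, 0.0)
    deg = agg.degrees()
    lengths = agg.edge_lengths
    return ConnectionStats(
        float(deg.mean()),
        float(deg.std()),
        float(lengths.mean()),
        float(lengths.std()),
    )


@dataclass
class SectionView:
    """Cells whose centres fall inside a slab, projected to 2D.

    Mimics a confocal slice: default thickness 10 µm, positions are the two
    in-plane coordinates.
    """

    z_center: float
    thickness: float
    positions: np.ndarray  # (k, 2) µm
    radii: np.ndarray
    states: np.ndarray
    ids: np.ndarray
    indices: np.ndarray  # positional indices into the source aggregate

    @property
    def n_cells(self) -> int:
        return len(self.positions)


def virtual_section(
    agg: Aggregate,
    z_center: float | None = None,
    thickness: float = 10.0,
    projection_axis: str = "z",
) -> SectionView:
    """Extract the virtual section centred at ``z_center``.

    Default placement mimics confocal practice: 25 µm below the top of the
    aggregate along the projection axis.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    ax = _AXES[projection_axis]
    keep_axes = [a for a in range(3) if a != ax]
    z = agg.positions[:, ax]
    if z_center is None:
        z_center = float(z.max() - 25.0)
    inside = np.abs(z - z_center) <= thickness / 2.0
    if not inside.any():
        warnings.warn("virtual section outside the aggregate: empty section", stacklevel=2)
    idx = np.flatnonzero(inside)
    return SectionView(
        z_center=float(z_center),
        thickness=float(thickness),
        positions=agg.positions[np.ix_(idx, keep_axes)].copy(),
        radii=agg.radii[idx].copy(),
        states=agg.states[idx].copy(),
        ids=agg.ids[idx].copy(),
        indices=idx,
    )


@dataclass
class StructureReport:
    """The four structural validation metrics of one aggregate."""

    aggregate_radius: float
    circularity: float
    connection_counts: np.ndarray = field(repr=False)
    connection_lengths: np.ndarray = field(repr=False)
    mean_connection_count: float = 0.0
    sd_connection_count: float = 0.0
    mean_connection_length: float = 0.0
    sd_connection_length: float = 0.0


def structure_report(agg: Aggregate, projection_axis: str = "z") -> StructureReport:
    """Compute radius, circularity and connection statistics in one pass."""
    if len(agg.edges) == 0 and agg.n_cells > 1:
        agg.refresh_edges()
    radius, circ = footprint_metrics(agg, projection_axis)
    stats = connection_stats(agg)
    return StructureReport(
        aggregate_radius=radius,
        circularity=circ,
        connection_counts=agg.degrees(),
        connection_lengths=agg.edge_lengths.copy(),
        mean_connection_count=stats.mean_count,
        sd_connection_count=stats.sd_count,
        mean_connection_length=stats.mean_length,
        sd_connection_length=stats.sd_length,
    )


def state_cluster_sizes(n: int, edges: np.ndarray, member_mask: np.ndarray) -> np.ndarray:
    """Sizes of connected components of the subgraph induced by ``member_mask``.

    Every member cell belongs to exactly one component; isolated members form
    size-1 components.  Non-members are excluded entirely.
    """
    members = np.flatnonzero(member_mask)
    if len(members) == 0:
        return np.empty(0, dtype=np.int64)
    remap = -np.ones(n, dtype=np.intp)
    remap[members] = np.arange(len(members))
    if len(edges):
        both = member_mask[edges[:, 0]] & member_mask[edges[:, 1]]
        e = remap[edges[both]]
    else:
        e = np.empty((0, 2), dtype=np.intp)
    m = len(members)
    if len(e):
        adj = csr_matrix(
            (np.ones(2 * len(e)), (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
            shape=(m, m),
        )
        _, labels = connected_components(adj, directed=False)
    else:
        labels = np.arange(m)
    return np.bincount(labels).astype(np.int64)


def count_state_clusters(
    n: int, edges: np.ndarray, member_mask: np.ndarray, min_size: int = 2
) -> int:
    """Number of same-state connected components with at least ``min_size`` cells."""
    sizes = state_cluster_sizes(n, edges, member_mask)
    return int((sizes >= min_size).sum())
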