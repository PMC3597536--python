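"""Domain types and sphere geometry shared by every simulation stage.

Cells are incompressible rigid spheres carrying a binary pluripotency state
(Oct4+ / Oct4-).  An :class:`Aggregate` is the simulation substrate: a set of
spheres plus the undirected contact graph linking physically adjacent cells.
Positions are continuous 3D coordinates in micrometres (µm); time is in hours.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "CellState",
    "CellAgent",
    "RadiusDistribution",
    "Aggregate",
    "sample_radii",
    "sphere_sa_v_ratio",
    "generate_fcc_lattice",
    "OVERLAP_TOLERANCE",
    "FCC_PACKING_FRACTION",
    "REPORTED_PACKING_FRACTION",
]

#: Two spheres may interpenetrate by at most this fraction of the smaller radius
#: after mechanical relaxation.
OVERLAP_TOLERANCE = 0.01

#: Analytic packing fraction of an infinite FCC/HCP sphere packing, pi/sqrt(18).
FCC_PACKING_FRACTION = math.pi / math.sqrt(18.0)

#: Close-packing constant used for cell-count/radius conversions (configurable;
#: differs from the analytic value in the fourth decimal).
REPORTED_PACKING_FRACTION = 0.7408


class CellState(enum.IntEnum):
    """Binary pluripotency state; the transition POS -> NEG is irreversible."""

    OCT4_NEG = 0
    OCT4_POS = 1


@dataclass
class CellAgent:
    """One cell: position, radius, binary Oct4 state and division clock.

    ``next_division_time`` is only meaningful in the dynamic (growing) model
    and is ``None`` otherwise.
    """

    id: int
    center: np.ndarray
    radius: float
    state: CellState = CellState.OCT4_POS
    next_division_time: float | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        self.state = CellState(self.state)


@dataclass(frozen=True)
class RadiusDistribution:
    """Population distribution of cell *diameters* (µm).

    Defaults emulate Coulter-counter measurements of dissociated mouse ESCs:
    mean diameter 6.6 µm with a small right-skewed spread, hence the lognormal
    default family.
    """

    family: str = "lognormal"
    mean_diameter: float = 6.6
    sd_diameter: float = 0.33

    _FAMILIES = ("lognormal", "truncated_normal")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {self._FAMILIES}")
        if self.mean_diameter <= 0:
            raise ValueError("mean_diameter must be positive")
        if self.sd_diameter < 0:
            raise ValueError("sd_diameter must be non-negative")


def sample_radii(
    n: int,
    dist: RadiusDistribution | None = None,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Draw ``n`` cell radii (µm) from a diameter distribution.

    The distribution is parameterised by the mean and standard deviation of
    the *diameter*; returned values are radii (half-diameters), strictly
    positive, and reproducible for a given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    dist = dist or RadiusDistribution()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m, s = dist.mean_diameter, dist.sd_diameter
    if s == 0:
        diameters = np.full(n, m)
    elif dist.family == "lognormal":
        # moment-match: E[D]=m, SD[D]=s
        sigma2 = math.log1p((s / m) ** 2)
        mu = math.log(m) - sigma2 / 2.0
        diameters = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n)
    else:  # truncated_normal, truncated at zero
        diameters = rng.normal(m, s, size=n)
        bad = diameters <= 0
        while bad.any():
            diameters[bad] = rng.normal(m, s, size=int(bad.sum()))
            bad = diameters <= 0
    return diameters / 2.0


def sphere_sa_v_ratio(radius: float) -> float:
    """Normalised surface-area-to-volume ratio SA·r/V of a sphere.

    Dimensionless; equals 3.00 for any radius, which is the reference value a
    spherical cell model is judged against.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    r = float(radius)
    return (4.0 * math.pi * r**2 * r) / ((4.0 / 3.0) * math.pi * r**3)


def _contact_pairs(
    positions: np.ndarray, radii: np.ndarray, contact_slack: float
) -> tuple[np.ndarray, np.ndarray]:
    """Index pairs (i<j) whose centre distance <= (r_i+r_j)(1+slack), + lengths."""
    n = len(positions)
    if n < 2:
        return np.empty((0, 2), dtype=np.intp), np.empty(0)
    rmax = float(np.max(radii))
    tree = cKDTree(positions)
    pairs = tree.query_pairs(2.0 * rmax * (1.0 + contact_slack), output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=np.intp), np.empty(0)
    d = np.linalg.norm(positions[pairs[:, 0]] - positions[pairs[:, 1]], axis=1)
    cutoff = (radii[pairs[:, 0]] + radii[pairs[:, 1]]) * (1.0 + contact_slack)
    keep = d <= cutoff
    return pairs[keep], d[keep]


@dataclass
class Aggregate:
    """A multicellular spheroid: spheres plus their undirected contact graph.

    Stored as flat arrays for speed; :attr:`cells` materialises the
    per-cell :class:`CellAgent` view.  ``edges`` holds positional index pairs
    (i < j); ``ids`` maps positions to stable cell identifiers.
    """

    positions: np.ndarray  # (n, 3) µm
    radii: np.ndarray  # (n,) µm
    states: np.ndarray  # (n,) int8; 1 = OCT4_POS
    ids: np.ndarray | None = None
    edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=np.intp))
    edge_lengths: np.ndarray = field(default_factory=lambda: np.empty(0))
    time: float = 0.0
    next_division_time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float)
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.ids is None:
            self.ids = np.arange(self.n_cells, dtype=np.int64)
        else:
            self.ids = np.asarray(self.ids, dtype=np.int64)
            if len(np.unique(self.ids)) != len(self.ids):
                raise ValueError("cell ids must be unique within an aggregate")
        if np.any(self.radii <= 0):
            raise ValueError("all radii must be positive")

    # -- construction ---------------------------------------------------
    @classmethod
    def from_cells(cls, cells: Sequence[CellAgent], time: float = 0.0) -> "Aggregate":
        positions = np.array([c.center for c in cells], dtype=float)
        radii = np.array([c.radius for c in cells], dtype=float)
        states = np.array([int(c.state) for c in cells], dtype=np.int8)
        ids = np.array([c.id for c in cells], dtype=np.int64)
        ndt = np.array(
            [np.nan if c.next_division_time is None else c.next_division_time for c in cells]
        )
        agg = cls(positions, radii, states, ids=ids, time=time)
        if not np.isnan(ndt).all():
            agg.next_division_time = ndt
        return agg

    # -- views -----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.positions)

    @property
    def cells(self) -> list[CellAgent]:
        ndt = self.next_division_time
        return [
            CellAgent(
                id=int(self.ids[i]),
                center=self.positions[i].copy(),
                radius=float(self.radii[i]),
                state=CellState(int(self.states[i])),
                next_division_time=None if ndt is None or np.isnan(ndt[i]) else float(ndt[i]),
            )
            for i in range(self.n_cells)
        ]

    def copy(self) -> "Aggregate":
        agg = Aggregate(
            self.positions.copy(),
            self.radii.copy(),
            self.states.copy(),
            ids=self.ids.copy(),
            edges=self.edges.copy(),
            edge_lengths=self.edge_lengths.copy(),
            time=self.time,
        )
        if self.next_division_time is not None:
            agg.next_division_time = self.next_division_time.copy()
        return agg

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=0)

    def radial_positions(self, normalized: bool = True) -> np.ndarray:
        """Distance of each cell centre from the centroid, optionally
        normalised by the maximum such distance (1.0 for a single cell)."""
        r = np.linalg.norm(self.positions - self.centroid(), axis=1)
        if normalized:
            rmax = r.max()
            return r / rmax if rmax > 0 else np.ones_like(r)
        return r

    # -- contact graph ---------------------------------------------------
    def refresh_edges(self, contact_slack: float = 0.05) -> None:
        """Rebuild the contact graph in place.

        Edge (i, j) exists iff centre distance <= (r_i + r_j)(1 + slack);
        its length is the Euclidean centre distance.
        """
        self.edges, self.edge_lengths = _contact_pairs(self.positions, self.radii, contact_slack)

    def adjacency(self):
        """Symmetric sparse CSR adjacency matrix over positional indices."""
        from scipy.sparse import csr_matrix

        n = self.n_cells
        if len(self.edges) == 0:
            return csr_matrix((n, n))
        i, j = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(i))
        return csr_matrix((data, (np.r_[i, j], np.r_[j, i])), shape=(n, n))

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=np.int64)
        if len(self.edges):
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def graph(self):
        """Export the contact graph as a networkx.Graph keyed by cell id."""
        import networkx as nx

        g = nx.Graph()
        for i in range(self.n_cells):
            g.add_node(
                int(self.ids[i]),
                pos=tuple(self.positions[i]),
                radius=float(self.radii[i]),
                state=CellState(int(self.states[i])).name,
            )
        for (i, j), length in zip(self.edges, self.edge_lengths):
            g.add_edge(int(self.ids[i]), int(self.ids[j]), length=float(length))
        return g

    def subset(self, indices: Iterable[int]) -> "Aggregate":
        """Sub-aggregate of the given positional indices with induced edges."""
        idx = np.asarray(list(indices), dtype=np.intp)
        remap = -np.ones(self.n_cells, dtype=np.intp)
        remap[idx] = np.arange(len(idx))
        sub = Aggregate(
            self.positions[idx].copy(),
            self.radii[idx].copy(),
            self.states[idx].copy(),
            ids=self.ids[idx].copy(),
            time=self.time,
        )
        if len(self.edges):
            keep = (remap[self.edges[:, 0]] >= 0) & (remap[self.edges[:, 1]] >= 0)
            e = remap[self.edges[keep]]
            e.sort(axis=1)
            sub.edges = e.astype(np.intp)
            sub.edge_lengths = self.edge_lengths[keep].copy()
        return sub

    # -- invariants -------------------------------------------------------
    def max_overlap_fraction(self) -> float:
        """Largest pairwise interpenetration as a fraction of the smaller radius."""
        pairs, d = _contact_pairs(self.positions, self.radii, 0.0)
        if len(pairs) == 0:
            return 0.0
        ri = self.radii[pairs[:, 0]]
        rj = self.radii[pairs[:, 1]]
        overlap = (ri + rj) - d
        return float(np.max(overlap / np.minimum(ri, rj)))

    def validate(self, overlap_tolerance: float = OVERLAP_TOLERANCE) -> None:
        """Raise ValueError if an aggregate invariant is violated."""
        if len(self.edges):
            d = np.linalg.norm(
                self.positions[self.edges[:, 0]] - self.positions[self.edges[:, 1]], axis=1
            )
            if not np.allclose(d, self.edge_lengths, rtol=1e-9, atol=1e-9):
                raise ValueError("edge lengths inconsistent with cell positions")
            if np.any(self.edges[:, 0] == self.edges[:, 1]):
                raise ValueError("self-edges are not allowed")
        if self.max_overlap_fraction() > overlap_tolerance + 1e-9:
            raise ValueError("sphere overlap exceeds tolerance")


def generate_fcc_lattice(
    shells: int, radius: float = 3.3, contact_slack: float = 0.01
) -> Aggregate:
    """Equal spheres on a face-centred-cubic lattice, all Oct4+.

    Sites out to ``shells`` nearest-neighbour distances from the central
    sphere are included (``shells=1`` gives the centre plus its 12 kissing
    neighbours).  Nearest-neighbour centre distance is exactly ``2*radius``,
    so every interior sphere touches 12 others.
    """
    if shells < 1:
        raise ValueError("shells must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    # FCC as the even-parity sublattice of a simple cubic grid: sites
    # (i, j, k) with i+j+k even, scaled so the nearest-neighbour distance
    # sqrt(2) maps to 2*radius.
    extent = int(math.ceil(shells * math.sqrt(2.0))) + 1
    axis = np.arange(-extent, extent + 1)
    ii, jj, kk = np.meshgrid(axis, axis, axis, indexing="ij")
    sites = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    sites = sites[(sites.sum(axis=1) % 2) == 0]
    scale = radius * math.sqrt(2.0)
    norms = np.linalg.norm(sites, axis=1) * scale
    keep = norms <= shells * 2.0 * radius * (1.0 + 1e-9)
    positions = sites[keep] * scale
    # deterministic ordering: by distance from origin, then lexicographic
    order = np.lexsort((positions[:, 2], positions[:, 1], positions[:, 0],
                        np.round(np.linalg.norm(positions, axis=1), 9)))
    positions = positions[order].astype(float)
    n = len(positions)
    agg = Aggregate(positions, np.full(n, float(radius)), np.ones(n, dtype=np.int8))
    agg.refresh_edges(contact_slack=contact_slack)
    return agg
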