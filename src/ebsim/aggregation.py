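"""Formation of spheroidal aggregates from dispersed cells.

Cells are seeded at random non-overlapping positions in a cubic box and then
driven toward a gravitational point source (the attractor) under an
overdamped scheme: each iteration every cell moves a fixed step along the
unit vector toward the attractor and all pairwise sphere overlaps are then
resolved by a symmetric projection along the centre line.  Only the final
packed structure matters downstream, not the transient trajectory.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    Aggregate,
    CellAgent,
    OVERLAP_TOLERANCE,
    RadiusDistribution,
    sample_radii,
)
from .structure import DEFAULT_CONTACT_SLACK

__all__ = ["AggregationParams", "seed_cells_in_box", "aggregate_cells", "build_aggregate"]


@dataclass
class AggregationParams:
    """Controls for the aggregation stage.

    ``step_size`` is the per-iteration displacement toward the attractor (µm);
    convergence is declared when the largest net per-iteration displacement
    falls below ``convergence_displacement``.
    """

    n_cells: int = 250
    box_side: float | None = None  # default: sized from total cell volume
    attractor: np.ndarray | None = None  # default: box centre
    step_size: float = 1.0
    max_iterations: int = 10_000
    convergence_displacement: float = 0.01

    def __post_init__(self) -> None:
        if self.step_size <= 0:
            raise ValueError("step_size must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def default_box_side(radii: np.ndarray, volume_factor: float = 8.0) -> float:
    """Cube side giving ``volume_factor`` times the total sphere volume."""
    total = float(np.sum(4.0 / 3.0 * np.pi * np.asarray(radii) ** 3))
    return (volume_factor * total) ** (1.0 / 3.0)


def seed_cells_in_box(
    n: int,
    radii: np.ndarray,
    box_side: float | None = None,
    seed: int | np.random.Generator = 0,
) -> list[CellAgent]:
    """Place ``n`` non-overlapping spheres uniformly at random in a cube.

    Rejection sampling against previously accepted spheres; raises if the box
    is too small (feasibility requires box volume >= 4x total sphere volume).
    """
    radii = np.asarray(radii, dtype=float)
    if len(radii) != n:
        raise ValueError("need one radius per cell")
    if box_side is None:
        box_side = default_box_side(radii)
    total_volume = float(np.sum(4.0 / 3.0 * np.pi * radii**3))
    if box_side**3 < 4.0 * total_volume:
        raise ValueError("box volume must be at least 4x the total sphere volume")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # largest first makes packing easier
    order = np.argsort(-radii)
    positions = np.empty((n, 3))
    placed = 0
    attempts = 0
    max_attempts = 20_000 * n
    while placed < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"failed to place {n} spheres in a {box_side:.1f} µm box "
                f"after {max_attempts} attempts"
            )
        r = radii[order[placed]]
        p = rng.uniform(r, box_side - r, size=3)
        attempts += 1
        if placed:
            d = np.linalg.norm(positions[:placed] - p, axis=1)
            if np.any(d < radii[order[:placed]] + r):
                continue
        positions[placed] = p
        placed += 1
    # restore caller order
    out_pos = np.empty_like(positions)
    out_pos[order] = positions
    return [
        CellAgent(id=i, center=out_pos[i], radius=float(radii[i])) for i in range(n)
    ]


def _resolve_overlaps(
    positions: np.ndarray,
    radii: np.ndarray,
    rng: np.random.Generator,
    max_passes: int = 30,
    relaxation: float = 1.0,
    tolerance: float = OVERLAP_TOLERANCE,
) -> None:
    """Push overlapping sphere pairs apart symmetrically, in place.

    All violating pairs are corrected simultaneously per pass (accumulated,
    under-relaxed displacements), which is free of ordering bias; coincident
    centres are separated along a random seeded direction.
    """
    n = len(positions)
    if n < 2:
        return
    rmax = float(radii.max())
    for _ in range(max_passes):
        tree = cKDTree(positions)
        pairs = tree.query_pairs(2.0 * rmax, output_type="ndarray")
        if len(pairs) == 0:
            return
        i, j = pairs[:, 0], pairs[:, 1]
        dvec = positions[j] - positions[i]
        dist = np.linalg.norm(dvec, axis=1)
        target = radii[i] + radii[j]
        allowed = tolerance * np.minimum(radii[i], radii[j])
        viol = (target - dist) > 0.5 * allowed
        if not viol.any():
            return
        i, j, dvec, dist, target = i[viol], j[viol], dvec[viol], dist[viol], target[viol]
        zero = dist < 1e-12
        if zero.any():
            rand = rng.normal(size=(int(zero.sum()), 3))
            rand /= np.linalg.norm(rand, axis=1, keepdims=True)
            dvec[zero] = rand
            dist[zero] = 1.0
        unit = dvec / dist[:, None]
        push = relaxation * 0.5 * (target - dist)
        delta = np.zeros_like(positions)
        np.add.at(delta, j, unit * push[:, None])
        np.add.at(delta, i, -unit * push[:, None])
        positions += delta


def _detached_mask(
    positions: np.ndarray, radii: np.ndarray, contact_slack: float, attractor: np.ndarray
) -> np.ndarray:
    """Cells that should keep feeling the full attraction while the packed
    core anneals: members of contact-graph components other than the core
    component (the one holding the cell nearest the attractor), plus any
    contact-free cell that has not yet reached the attractor."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    from .geometry import _contact_pairs

    n = len(positions)
    pairs, _ = _contact_pairs(positions, radii, contact_slack)
    degree = np.zeros(n, dtype=np.int64)
    if len(pairs) == 0:
        labels = np.arange(n)
    else:
        np.add.at(degree, pairs[:, 0], 1)
        np.add.at(degree, pairs[:, 1], 1)
        adj = csr_matrix(
            (
                np.ones(2 * len(pairs)),
                (np.r_[pairs[:, 0], pairs[:, 1]], np.r_[pairs[:, 1], pairs[:, 0]]),
            ),
            shape=(n, n),
        )
        _, labels = connected_components(adj, directed=False)
    dist = np.linalg.norm(positions - attractor, axis=1)
    core = labels[int(np.argmin(dist))]
    return (labels != core) | ((degree == 0) & (dist > 1e-9))


def aggregate_cells(
    cells: list[CellAgent] | Aggregate,
    params: AggregationParams | None = None,
    seed: int | np.random.Generator = 0,
    contact_slack: float = DEFAULT_CONTACT_SLACK,
) -> Aggregate:
    """Drive dispersed cells into a packed spheroid around the attractor.

    Iterates attraction + overlap resolution until the largest net per-cell
    displacement in an iteration drops below ``convergence_displacement``
    (the attraction step is annealed once the packing stalls so the system
    settles instead of jittering).  Radii are never modified.  On
    non-convergence the best state is returned with ``converged=False`` set
    on the result and a warning.
    """
    agg = cells if isinstance(cells, Aggregate) else Aggregate.from_cells(cells)
    params = params or AggregationParams(n_cells=agg.n_cells)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = agg.positions
    radii = agg.radii
    if params.attractor is None:
        attractor = positions.mean(axis=0)
    else:
        attractor = np.asarray(params.attractor, dtype=float)

    # radius of the fully packed spheroid (random close packing ~0.60);
    # once every centre is inside ~1.3x this, the cloud is packed and the
    # attraction step is annealed so the packing settles instead of shearing
    packed_radius = (float(np.sum(radii**3)) / 0.60) ** (1.0 / 3.0)
    step = float(params.step_size)
    transit = True
    converged = False
    detached = np.zeros(agg.n_cells, dtype=bool)
    for it in range(params.max_iterations):
        prev = positions.copy()
        d = attractor - positions
        dist = np.linalg.norm(d, axis=1)
        move = np.minimum(step, dist)
        if not transit:
            # stragglers disconnected from the main cluster keep feeling the
            # full attraction even while the packed core anneals
            if it % 5 == 0:
                detached = _detached_mask(positions, radii, contact_slack, attractor)
            if detached.any():
                move = np.where(detached, np.minimum(params.step_size, dist), move)
        nz = dist > 1e-12
        positions[nz] += d[nz] / dist[nz, None] * move[nz, None]
        _resolve_overlaps(positions, radii, rng, max_passes=8 if transit else 25)
        net = float(np.max(np.linalg.norm(positions - prev, axis=1))) if agg.n_cells else 0.0
        if net < params.convergence_displacement:
            converged = True
            break
        if transit:
            far = float(np.max(np.linalg.norm(positions - attractor, axis=1)))
            if far <= 1.3 * packed_radius + float(radii.max()):
                transit = False
        else:
            # anneal the attraction all the way off; the packing then relaxes
            # until no overlap exceeds tolerance and all motion stops
            step = step * 0.8 if step > 1e-4 else 0.0
    # final cleanup passes to meet the overlap invariant
    _resolve_overlaps(positions, radii, rng, max_passes=100, relaxation=1.0)
    if not converged:
        warnings.warn(
            f"aggregation did not converge within {params.max_iterations} iterations",
            stacklevel=2,
        )
    agg.refresh_edges(contact_slack=contact_slack)
    agg.converged = converged  # type: ignore[attr-defined]
    return agg


def build_aggregate(
    n: int,
    dist: RadiusDistribution | None = None,
    seed: int = 0,
    params: AggregationParams | None = None,
    contact_slack: float = DEFAULT_CONTACT_SLACK,
) -> Aggregate:
    """Convenience pipeline: sample radii, seed in a box, aggregate.

    All randomness derives from ``seed``; the same call is bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    radii = sample_radii(n, dist or RadiusDistribution(), rng)
    params = params or AggregationParams(n_cells=n)
    cells = seed_cells_in_box(n, radii, box_side=params.box_side, seed=rng)
    return aggregate_cells(cells, params, seed=rng, contact_slack=contact_slack)
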