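"""Deterministic generators of labelled test aggregates.

Each fixture realises one of the canonical spatial patterns (shell patterns,
two connected blobs, a random checkerboard, uniform states) on a relaxed
random packing, so analysis code can be exercised against aggregates whose
ground-truth pattern class is known by construction.  The FCC lattice is the
one lattice fixture (exact 12-neighbour geometry).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .aggregation import build_aggregate
from .geometry import Aggregate, CellState, RadiusDistribution, generate_fcc_lattice
from .structure import state_cluster_sizes

__all__ = ["FixtureKind", "FixtureSpec", "make_fixture"]


class FixtureKind(enum.Enum):
    FCC_LATTICE = "fcc-lattice"
    SHELL_INSIDE_OUT = "shell-inside-out"
    SHELL_OUTSIDE_IN = "shell-outside-in"
    TWO_BLOB_CONNECTED = "two-blob-connected"
    CHECKERBOARD_RANDOM = "checkerboard-random"
    UNIFORM_STATE = "uniform-state"


@dataclass(frozen=True)
class FixtureSpec:
    kind: FixtureKind
    size: int = 250
    seed: int = 0
    #: SHELL fixtures: normalised radial boundary of the Oct4− region.
    shell_boundary: float = 0.5
    #: CHECKERBOARD/UNIFORM: probability (or indicator) of the Oct4+ state.
    fraction_pos: float = 0.5
    #: TWO_BLOB: fraction of cells assigned to the Oct4− blobs.
    minority_fraction: float = 0.3


def _base_packing(spec: FixtureSpec) -> Aggregate:
    dist = RadiusDistribution()
    return build_aggregate(spec.size, dist, seed=spec.seed)


def _grow_blobs(agg: Aggregate, seeds: list[int], n_target: int) -> np.ndarray:
    """Breadth-first growth of contiguous regions from seed cells."""
    adj = [[] for _ in range(agg.n_cells)]
    for i, j in agg.edges:
        adj[i].append(j)
        adj[j].append(i)
    chosen = np.zeros(agg.n_cells, dtype=bool)
    frontier = list(seeds)
    chosen[seeds] = True
    count = len(seeds)
    while frontier and count < n_target:
        nxt = []
        for c in frontier:
            for nb in adj[c]:
                if not chosen[nb]:
                    chosen[nb] = True
                    nxt.append(nb)
                    count += 1
                    if count >= n_target:
                        return chosen
        frontier = nxt
    return chosen


def make_fixture(spec: FixtureSpec) -> Aggregate:
    """Build the aggregate described by ``spec``; reproducible under its seed."""
    if spec.kind is FixtureKind.FCC_LATTICE:
        shells = max(1, int(round(spec.size ** (1.0 / 3.0))))
        return generate_fcc_lattice(shells=shells)

    agg = _base_packing(spec)
    rng = np.random.default_rng(spec.seed + 1)
    radial = agg.radial_positions(normalized=True)

    if spec.kind is FixtureKind.UNIFORM_STATE:
        state = CellState.OCT4_POS if spec.fraction_pos >= 0.5 else CellState.OCT4_NEG
        agg.states[:] = int(state)
    elif spec.kind is FixtureKind.SHELL_INSIDE_OUT:
        # differentiated (Oct4-) core, undifferentiated rim
        agg.states[:] = int(CellState.OCT4_POS)
        agg.states[radial < spec.shell_boundary] = int(CellState.OCT4_NEG)
    elif spec.kind is FixtureKind.SHELL_OUTSIDE_IN:
        # differentiated rim, undifferentiated core; thicken the rim until it
        # is a single connected shell on this packing's contact graph
        agg.states[:] = int(CellState.OCT4_POS)
        cut = 1.0 - spec.shell_boundary * 0.7
        while cut > 0.4:
            rim = radial > cut
            sizes = state_cluster_sizes(agg.n_cells, agg.edges, rim)
            if np.sum(sizes >= 2) == 1 and sizes.max() >= 0.9 * rim.sum():
                break
            cut -= 0.05
        agg.states[radial > cut] = int(CellState.OCT4_NEG)
    elif spec.kind is FixtureKind.CHECKERBOARD_RANDOM:
        agg.states = (rng.random(agg.n_cells) < spec.fraction_pos).astype(np.int8)
    elif spec.kind is FixtureKind.TWO_BLOB_CONNECTED:
        # two contiguous Oct4- regions grown from mid-radius cells on
        # opposite sides, so neither a shell nor a random pattern results
        agg.states[:] = int(CellState.OCT4_POS)
        x = agg.positions[:, 0] - agg.centroid()[0]
        mid = np.abs(radial - 0.5) < 0.25
        left = np.flatnonzero(mid & (x < 0))
        right = np.flatnonzero(mid & (x > 0))
        if len(left) == 0 or len(right) == 0:  # degenerate tiny aggregate
            left, right = np.array([0]), np.array([agg.n_cells - 1])
        seeds = [int(left[np.argmin(x[left])]), int(right[np.argmax(x[right])])]
        n_target = max(2, int(round(spec.minority_fraction * agg.n_cells)))
        chosen = _grow_blobs(agg, seeds, n_target)
        agg.states[chosen] = int(CellState.OCT4_NEG)
    else:
        raise ValueError(f"unknown fixture kind {spec.kind!r}")
    return agg
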