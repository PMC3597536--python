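"""Growing-aggregate simulation: mass-spring mechanics plus cell division.

Cells remain rigid spheres of fixed radius; contacting pairs are joined by
springs that hold the aggregate together while complete pairwise collision
detection keeps overlaps within tolerance.  Division is symmetric (daughters
inherit the parent's state and radius) and unsynchronised: waiting times are
exponential with rate ln2 / T for a state-specific doubling time T, so the
population grows exponentially with exactly that doubling time.  The
differentiation rules of the static model are evaluated at a fixed cadence
during growth, with the competing rule down-weighted.

Also provides the growth-rate utilities used to calibrate doubling times
from aggregate sizes: r = ln(N2/N1)/Δt and T = ln2/r, with cell counts
recovered from an aggregate radius via a close-packing correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .aggregation import _resolve_overlaps
from .geometry import Aggregate, CellState, REPORTED_PACKING_FRACTION
from .rules import RuleParams, RuleKind, step_states
from .structure import DEFAULT_CONTACT_SLACK, count_state_clusters, footprint_metrics

__all__ = [
    "GrowthParams",
    "GrowthTrajectory",
    "estimate_growth_rate",
    "doubling_time",
    "cells_from_radius",
    "schedule_division",
    "divide_cell",
    "spring_relax",
    "run_dynamic_simulation",
    "fit_doubling_time",
]

LN2 = math.log(2.0)


@dataclass
class GrowthParams:
    """Parameters of the growing-aggregate model.

    Doubling times are population doubling times in hours (18 h for Oct4+
    stem cells, 51 h for differentiated cells).  ``spring_stiffness`` is an
    overdamped relaxation rate (per hour): each mechanics step moves the two
    endpoints of a contact spring a fraction ``spring_stiffness *
    mechanics_dt`` of the way to the rest length ``spring_rest_length_factor
    * (r_i + r_j)``.  The run stops at ``duration`` hours, when
    ``changed_fraction_stop`` of the cells have differentiated, or at
    ``max_cells``, whichever comes first.
    """

    doubling_time_pos: float = 18.0
    doubling_time_neg: float = 51.0
    spring_stiffness: float = 5.0
    spring_rest_length_factor: float = 1.0
    mechanics_dt: float = 0.1
    rule_dt: float = 1.0
    duration: float = 144.0
    changed_fraction_stop: float = 0.99
    max_cells: int = 40_000
    competing_weight: float = 0.01
    contact_slack: float = DEFAULT_CONTACT_SLACK

    def __post_init__(self) -> None:
        if self.doubling_time_pos <= 0 or self.doubling_time_neg <= 0:
            raise ValueError("doubling times must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0.0 < self.changed_fraction_stop <= 1.0:
            raise ValueError("changed_fraction_stop must be in (0, 1]")
        if self.max_cells < 1:
            raise ValueError("max_cells must be >= 1")
        if self.mechanics_dt <= 0 or self.rule_dt <= 0:
            raise ValueError("time steps must be positive")


def estimate_growth_rate(n1: float, n2: float, t1: float, t2: float) -> float:
    """Exponential growth rate (per hour) between two census points:
    r = ln(n2/n1) / (t2 − t1)."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("cell counts must be positive")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return math.log(n2 / n1) / (t2 - t1)


def doubling_time(r: float) -> float:
    """Population doubling time T = ln2 / r for growth rate r > 0 per hour."""
    if r <= 0:
        raise ValueError("growth rate must be positive")
    return LN2 / r


def cells_from_radius(
    eb_radius: float,
    cell_diameter: float = 6.6,
    packing: float = REPORTED_PACKING_FRACTION,
) -> int:
    """Cell count of a spheroid of radius ``eb_radius`` assuming close packing.

    floor(packing · (R / r_cell)³): the aggregate volume, corrected by the
    close-packing fraction, divided by the single-cell volume.
    """
    if eb_radius <= 0 or cell_diameter <= 0:
        raise ValueError("radius and diameter must be positive")
    if not 0.0 < packing <= 1.0:
        raise ValueError("packing must be in (0, 1]")
    return int(math.floor(packing * (eb_radius / (cell_diameter / 2.0)) ** 3))


def _division_doubling_time(state: int, params: GrowthParams) -> float:
    return (
        params.doubling_time_pos
        if state == int(CellState.OCT4_POS)
        else params.doubling_time_neg
    )


def schedule_division(
    cell_state: int | CellState,
    now: float,
    params: GrowthParams,
    rng: np.random.Generator,
) -> float:
    """Next division time: now + Exp(rate = ln2/T) for the state's doubling
    time T.  Memoryless waiting times leave divisions unsynchronised and make
    population growth exactly exponential with doubling time T."""
    T = _division_doubling_time(int(cell_state), params)
    return now + rng.exponential(T / LN2)


def divide_cell(agg: Aggregate, cell_id: int, rng: np.random.Generator,
                params: GrowthParams | None = None) -> Aggregate:
    """Symmetric division of one cell, in place.

    The daughter inherits the parent's state and radius and is placed one
    parent-radius away in a uniformly random direction; both cells draw fresh
    division schedules.  Mechanical relaxation resolves the initial overlap.
    """
    params = params or GrowthParams()
    where = np.flatnonzero(agg.ids == cell_id)
    if len(where) == 0:
        raise KeyError(f"no cell with id {cell_id}")
    return _divide_indices(agg, where, rng, params)


def _random_unit_vectors(k: int, rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=(k, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _divide_indices(
    agg: Aggregate, idx: np.ndarray, rng: np.random.Generator, params: GrowthParams
) -> Aggregate:
    """Divide the cells at positional indices ``idx`` (batched), in place."""
    k = len(idx)
    if k == 0:
        return agg
    dirs = _random_unit_vectors(k, rng)
    new_pos = agg.positions[idx] + dirs * agg.radii[idx, None]
    next_id = int(agg.ids.max()) + 1
    agg.positions = np.vstack([agg.positions, new_pos])
    agg.radii = np.concatenate([agg.radii, agg.radii[idx]])
    agg.states = np.concatenate([agg.states, agg.states[idx]])
    agg.ids = np.concatenate([agg.ids, np.arange(next_id, next_id + k, dtype=np.int64)])
    if agg.next_division_time is None:
        agg.next_division_time = np.full(agg.n_cells, np.nan)
    now = agg.time
    parent_next = np.array(
        [schedule_division(int(agg.states[i]), now, params, rng) for i in idx]
    )
    daughter_next = np.array(
        [schedule_division(int(agg.states[i]), now, params, rng) for i in idx]
    )
    ndt = np.concatenate([agg.next_division_time, daughter_next])
    ndt[idx] = parent_next
    agg.next_division_time = ndt
    return agg


def spring_relax(
    agg: Aggregate,
    params: GrowthParams | None = None,
    rng: np.random.Generator | None = None,
    n_overlap_passes: int = 10,
) -> float:
    """One overdamped mechanics step, in place; returns max displacement (µm).

    Each contact spring pulls/pushes its endpoints a fraction
    ``spring_stiffness * mechanics_dt`` of the way toward its rest length,
    then complete pairwise collision detection projects residual overlaps
    apart.  Contact edges must be current.
    """
    params = params or GrowthParams()
    rng = rng or np.random.default_rng(0)
    before = agg.positions.copy()
    if len(agg.edges):
        i, j = agg.edges[:, 0], agg.edges[:, 1]
        dvec = agg.positions[j] - agg.positions[i]
        dist = np.linalg.norm(dvec, axis=1)
        rest = params.spring_rest_length_factor * (agg.radii[i] + agg.radii[j])
        frac = min(1.0, params.spring_stiffness * params.mechanics_dt)
        ok = dist > 1e-12
        # each endpoint takes half the correction toward the rest length
        corr = np.zeros_like(dvec)
        corr[ok] = (dvec[ok] / dist[ok, None]) * (frac * 0.5 * (dist[ok] - rest[ok]))[:, None]
        delta = np.zeros_like(agg.positions)
        np.add.at(delta, i, corr)
        np.add.at(delta, j, -corr)
        agg.positions += delta
    _resolve_overlaps(agg.positions, agg.radii, rng, max_passes=n_overlap_passes)
    return float(np.max(np.linalg.norm(agg.positions - before, axis=1)))


@dataclass
class GrowthTrajectory:
    """Time series of a growing-aggregate run plus its stop reason.

    ``data`` columns: time_h, n_cells, radius_um, density, circularity,
    mean_connection_count, interior_connection_count (surface layer
    excluded), mean_connection_length, fraction_pos, ucn_per_cell,
    dcn_per_cell.  UCN/DCN are normalised by the (growing) cell number.
    """

    data: pd.DataFrame
    final: Aggregate
    stop_reason: str
    seed: int | None
    snapshots: list[Aggregate] | None = None  # one per recorded row, if requested


def _record_row(agg: Aggregate) -> dict:
    radius, circ = footprint_metrics(agg)
    total_cell_volume = float(np.sum(4.0 / 3.0 * np.pi * agg.radii**3))
    density = total_cell_volume / (4.0 / 3.0 * np.pi * radius**3)
    deg = agg.degrees()
    pos_mask = agg.states == int(CellState.OCT4_POS)
    n = agg.n_cells
    # bulk coordination: cells more than ~1.5 cell diameters below the
    # surface, where the packing is size-independent
    r = np.linalg.norm(agg.positions - agg.positions.mean(axis=0), axis=1)
    interior = (r.max() - r) > 10.0
    interior_deg = float(deg[interior].mean()) if interior.sum() >= 10 else float("nan")
    return {
        "time_h": agg.time,
        "n_cells": n,
        "radius_um": radius,
        "density": density,
        "circularity": circ,
        "mean_connection_count": float(deg.mean()),
        "interior_connection_count": interior_deg,
        "mean_connection_length": float(agg.edge_lengths.mean()) if len(agg.edges) else 0.0,
        "fraction_pos": float(pos_mask.mean()),
        "ucn_per_cell": count_state_clusters(n, agg.edges, pos_mask) / n,
        "dcn_per_cell": count_state_clusters(n, agg.edges, ~pos_mask) / n,
    }


def run_dynamic_simulation(
    initial: Aggregate,
    rule: RuleParams | None,
    growth: GrowthParams | None = None,
    seed: int | None = 0,
    record_snapshots: bool = False,
) -> GrowthTrajectory:
    """Grow an aggregate under division + mechanics, applying a rule if given.

    Event loop: every ``mechanics_dt`` hours due divisions fire and one
    mechanics step runs; every ``rule_dt`` hours the rule (if any) is
    evaluated with its static per-step probabilities — the competing rule
    additionally scaled by ``competing_weight`` — and a trajectory row is
    recorded.  Stops at the first satisfied criterion: duration elapsed,
    ``changed_fraction_stop`` of cells differentiated, or ``max_cells``
    reached.  ``rule=None`` gives the growth-only control.
    """
    growth = growth or GrowthParams()
    rng = np.random.default_rng(seed)
    agg = initial.copy()
    agg.time = 0.0
    if agg.next_division_time is None or np.isnan(agg.next_division_time).any():
        agg.next_division_time = np.array(
            [schedule_division(int(s), 0.0, growth, rng) for s in agg.states]
        )
    if rule is not None and rule.kind is RuleKind.COMPETING_FEEDBACK:
        rule = RuleParams(
            kind=rule.kind,
            alpha=rule.alpha,
            epsilon=rule.epsilon,
            weight=growth.competing_weight,
            competing_exponent=rule.competing_exponent,
        )
    agg.refresh_edges(growth.contact_slack)
    rows = [_record_row(agg)]
    snaps: list[Aggregate] | None = [agg.copy()] if record_snapshots else None
    stop_reason = "duration"
    steps_per_rule = max(1, round(growth.rule_dt / growth.mechanics_dt))
    n_steps = int(round(growth.duration / growth.mechanics_dt))
    for step in range(1, n_steps + 1):
        agg.time = step * growth.mechanics_dt
        due = np.flatnonzero(agg.next_division_time <= agg.time)
        if len(due):
            _divide_indices(agg, due, rng, growth)
        agg.refresh_edges(growth.contact_slack)
        spring_relax(agg, growth, rng)
        agg.refresh_edges(growth.contact_slack)
        if agg.n_cells >= growth.max_cells:
            rows.append(_record_row(agg))
            if snaps is not None:
                snaps.append(agg.copy())
            stop_reason = "max_cells"
            break
        if step % steps_per_rule == 0:
            if rule is not None:
                step_states(agg, rule, rng)
            rows.append(_record_row(agg))
            if snaps is not None:
                snaps.append(agg.copy())
            changed = 1.0 - rows[-1]["fraction_pos"]
            if changed >= growth.changed_fraction_stop:
                stop_reason = "changed_fraction"
                break
    data = pd.DataFrame(rows)
    return GrowthTrajectory(
        data=data, final=agg, stop_reason=stop_reason, seed=seed, snapshots=snaps
    )


def fit_doubling_time(traj: GrowthTrajectory) -> tuple[float, float]:
    """(doubling time in hours, R²) from a log-linear fit of cell counts.

    Regresses ln(count) on time over the recorded rows and converts the
    fitted slope back with T = ln2 / slope.
    """
    d = traj.data
    if len(d) < 3:
        raise ValueError("trajectory too short to fit")
    res = stats.linregress(d["time_h"], np.log(d["n_cells"]))
    if res.slope <= 0:
        raise ValueError("population did not grow; cannot fit a doubling time")
    return LN2 / res.slope, float(res.rvalue**2)
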