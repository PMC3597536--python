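"""Probabilistic differentiation rules and the static-structure simulation.

Each undifferentiated (Oct4+) cell decides once per time step whether to
differentiate, with a probability set by one of three rules:

* ``RANDOM`` — a constant basal probability α (default 1%).
* ``POSITIVE_FEEDBACK`` — differentiated neighbours push the transition:
  P = or_gate(α, β/ε), where β counts Oct4− neighbours and ε is the maximum
  possible neighbour count (12, the FCC/HCP kissing number).
* ``COMPETING_FEEDBACK`` — differentiated neighbours promote and
  undifferentiated neighbours inhibit: P = or_gate(α, w·β^k/(β^k + γ^k)),
  a sigmoid in the neighbour composition with no separate half-saturation
  constant (k defaults to 2; the weight w is 1 for static structures and is
  down-weighted in the growing model).

The transition is binary, instantaneous and irreversible; updates are
synchronous (all probabilities evaluated on the start-of-step states).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .geometry import Aggregate, CellState
from .structure import count_state_clusters

__all__ = [
    "RuleKind",
    "RuleParams",
    "NeighborhoodState",
    "StateTrajectory",
    "or_gate",
    "p_random",
    "p_positive_feedback",
    "p_competing_feedback",
    "transition_probabilities",
    "step_states",
    "run_static_simulation",
]


class RuleKind(enum.Enum):
    RANDOM = "random"
    POSITIVE_FEEDBACK = "positive"
    COMPETING_FEEDBACK = "competing"


@dataclass(frozen=True)
class RuleParams:
    """Rule kind plus the parameters of its transition probability."""

    kind: RuleKind = RuleKind.COMPETING_FEEDBACK
    alpha: float = 0.01  # basal per-step transition probability
    epsilon: int = 12  # maximum possible number of neighbours
    weight: float = 1.0  # competing-rule scaling (0.01 in the dynamic model)
    competing_exponent: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be a probability in [0, 1]")
        if self.epsilon < 1:
            raise ValueError("epsilon must be >= 1")
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must be in [0, 1]")
        if self.competing_exponent <= 0:
            raise ValueError("competing_exponent must be positive")


@dataclass(frozen=True)
class NeighborhoodState:
    """Neighbour composition of one cell: β Oct4− and γ Oct4+ neighbours."""

    beta: int
    gamma: int

    def __post_init__(self) -> None:
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("neighbour counts must be non-negative")


def or_gate(p1, p2):
    """Probabilistic union of two independent mechanisms: 1 − (1−p1)(1−p2).

    Commutative, bounded below by max(p1, p2); accepts scalars or arrays.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any(p1 < 0) or np.any(p1 > 1) or np.any(p2 < 0) or np.any(p2 > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    out = 1.0 - (1.0 - p1) * (1.0 - p2)
    return float(out) if out.ndim == 0 else out


def p_random(params: RuleParams) -> float:
    """Basal transition probability, independent of the neighbourhood."""
    if params.kind is not RuleKind.RANDOM:
        raise ValueError("p_random requires kind=RANDOM")
    return params.alpha


def p_positive_feedback(nb: NeighborhoodState, params: RuleParams) -> float:
    """or_gate(α, β/ε); β/ε clamps to 1 when contact slack admits >ε contacts."""
    if params.kind is not RuleKind.POSITIVE_FEEDBACK:
        raise ValueError("p_positive_feedback requires kind=POSITIVE_FEEDBACK")
    frac = min(nb.beta / params.epsilon, 1.0)
    return or_gate(params.alpha, frac)


def p_competing_feedback(nb: NeighborhoodState, params: RuleParams) -> float:
    """or_gate(α, w·β^k/(β^k+γ^k)); the isolated-cell case (β=γ=0) feels only α."""
    if params.kind is not RuleKind.COMPETING_FEEDBACK:
        raise ValueError("p_competing_feedback requires kind=COMPETING_FEEDBACK")
    k = params.competing_exponent
    denom = nb.beta**k + nb.gamma**k
    f = 0.0 if denom == 0 else nb.beta**k / denom
    return or_gate(params.alpha, params.weight * f)


def transition_probabilities(agg: Aggregate, params: RuleParams) -> np.ndarray:
    """Per-cell transition probability under the rule, vectorised.

    Computed for every cell; only Oct4+ cells ever use theirs.
    """
    n = agg.n_cells
    if params.kind is RuleKind.RANDOM:
        return np.full(n, params.alpha)
    adj = agg.adjacency()
    neg = (agg.states == int(CellState.OCT4_NEG)).astype(float)
    beta = adj @ neg
    if params.kind is RuleKind.POSITIVE_FEEDBACK:
        return or_gate(np.full(n, params.alpha), np.minimum(beta / params.epsilon, 1.0))
    pos = (agg.states == int(CellState.OCT4_POS)).astype(float)
    gamma = adj @ pos
    k = params.competing_exponent
    bk = beta**k
    denom = bk + gamma**k
    with np.errstate(invalid="ignore"):
        f = np.where(denom > 0, bk / np.where(denom > 0, denom, 1.0), 0.0)
    return or_gate(np.full(n, params.alpha), params.weight * f)


def step_states(
    agg: Aggregate, params: RuleParams, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """One synchronous update of the state vector, in place.

    Exactly one uniform variate is drawn per cell (in index order) so a run
    can be replayed from its seed; only Oct4+ cells may transition and they
    never revert.  Returns (state vector, number of transitions).
    """
    p = transition_probabilities(agg, params)
    draws = rng.random(agg.n_cells)
    pos = agg.states == int(CellState.OCT4_POS)
    flip = pos & (draws < p)
    agg.states[flip] = int(CellState.OCT4_NEG)
    return agg.states, int(flip.sum())


@dataclass
class StateTrajectory:
    """Per-step record of one static-structure simulation.

    ``states`` has one row per recorded step (row 0 is the homogeneous
    initial population); ``tau`` is step/K with K the completion step (or the
    step cutoff when ``completed`` is False).
    """

    aggregate: Aggregate
    states: np.ndarray  # (K+1, n) int8
    steps: np.ndarray  # (K+1,) step index 0..K
    tau: np.ndarray
    ucn: np.ndarray
    dcn: np.ndarray
    fraction_pos: np.ndarray
    completed: bool
    seed: int | None
    params: RuleParams = field(default=None)  # type: ignore[assignment]

    @property
    def n_steps(self) -> int:
        return int(self.steps[-1])


def _cluster_counts(agg: Aggregate) -> tuple[int, int]:
    pos_mask = agg.states == int(CellState.OCT4_POS)
    ucn = count_state_clusters(agg.n_cells, agg.edges, pos_mask)
    dcn = count_state_clusters(agg.n_cells, agg.edges, ~pos_mask)
    return ucn, dcn


def run_static_simulation(
    agg: Aggregate,
    params: RuleParams,
    max_steps: int = 500,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> StateTrajectory:
    """Run a rule on a fixed structure from a homogeneous Oct4+ population.

    Stops at the first step with zero Oct4+ cells or after ``max_steps``
    (default 500); per-step UCN/DCN and %Oct4+ are recorded along a
    normalised time axis.  Deterministic for a given seed.  The input
    aggregate is not modified.
    """
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    work = agg.copy()
    work.states[:] = int(CellState.OCT4_POS)
    if len(work.edges) == 0 and work.n_cells > 1:
        work.refresh_edges()
    rng = rng if rng is not None else np.random.default_rng(seed)

    states_hist = [work.states.copy()]
    ucn0, dcn0 = _cluster_counts(work)
    ucn, dcn, frac = [ucn0], [dcn0], [1.0]
    completed = False
    k = 0
    for k in range(1, max_steps + 1):
        step_states(work, params, rng)
        states_hist.append(work.states.copy())
        u, d = _cluster_counts(work)
        ucn.append(u)
        dcn.append(d)
        f = float(np.mean(work.states == int(CellState.OCT4_POS)))
        frac.append(f)
        if f == 0.0:
            completed = True
            break
    total = k if completed else max_steps
    steps = np.arange(len(states_hist))
    return StateTrajectory(
        aggregate=agg,
        states=np.array(states_hist, dtype=np.int8),
        steps=steps,
        tau=steps / total,
        ucn=np.array(ucn),
        dcn=np.array(dcn),
        fraction_pos=np.array(frac),
        completed=completed,
        seed=seed,
        params=params,
    )
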