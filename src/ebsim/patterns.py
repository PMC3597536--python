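"""Spatial pattern classification and cluster-trajectory analytics.

Six pattern classes describe Oct4 expression in an aggregate or section:
uniformly undifferentiated (OCT4_POS, >=90% Oct4+), uniformly differentiated
(OCT4_NEG, <=10% Oct4+), and four transition patterns — INSIDE_OUT (Oct4−
core), OUTSIDE_IN (Oct4− rim), CONNECTED (few large same-state regions) and
RANDOM (no identifiable organisation).

Quantitative metrics: UCN and DCN, the numbers of connected same-state
clusters (two or more cells) of the undifferentiated and differentiated
populations, tracked along a normalised time axis τ = step / steps-to-completion.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Aggregate, CellState
from .structure import SectionView, count_state_clusters, state_cluster_sizes

__all__ = [
    "PatternClass",
    "PatternMetrics",
    "ClassifierParams",
    "count_clusters",
    "pattern_metrics",
    "classify",
    "classify_section",
    "snapshot",
    "normalize_time",
    "TrajectorySummary",
    "trajectory_summary",
    "pattern_distribution",
]


class PatternClass(enum.Enum):
    OCT4_POS = "oct4_pos"
    INSIDE_OUT = "inside_out"
    OUTSIDE_IN = "outside_in"
    CONNECTED = "connected"
    RANDOM = "random"
    OCT4_NEG = "oct4_neg"


@dataclass(frozen=True)
class PatternMetrics:
    """UCN/DCN plus composition and radial-bias summaries of one snapshot."""

    ucn: int
    dcn: int
    fraction_pos: float
    mean_radial_pos: float  # NaN when no Oct4+ cells
    mean_radial_neg: float  # NaN when no Oct4- cells


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the six-class decision rule.

    ``hi``/``lo`` are the uniform-class boundaries (fractions Oct4+, boundary
    inclusive).  Transition subtypes: a radial-bias test first (mean
    normalised radius of the two states differing by more than
    ``radial_delta`` while each state forms at most ``max_shell_clusters``
    clusters reads as a shell pattern), then a clustering test for CONNECTED
    versus RANDOM.  With ``method="permutation"`` (default) the minority
    state counts as clustered when its number of connected components is more
    than ``z_threshold`` permutation-null standard deviations below the mean
    under random relabelling; ``method="clustered_fraction"`` instead asks
    whether at least ``connected_min_frac`` of minority cells sit in clusters
    of two or more.
    """

    hi: float = 0.90
    lo: float = 0.10
    radial_delta: float = 0.15
    max_shell_clusters: int = 2
    method: str = "permutation"
    z_threshold: float = 2.0
    n_permutations: int = 30
    permutation_seed: int = 0
    connected_min_frac: float = 0.6


def count_clusters(agg: Aggregate, state: CellState | int) -> int:
    """Number of connected components (>= 2 cells) of cells in ``state``.

    A lone cell is not a cluster.
    """
    mask = agg.states == int(state)
    return count_state_clusters(agg.n_cells, agg.edges, mask)


def pattern_metrics(agg: Aggregate) -> PatternMetrics:
    """UCN, DCN, %Oct4+ and centroid-normalised mean radial position per state."""
    if agg.n_cells == 0:
        raise ValueError("empty aggregate")
    pos_mask = agg.states == int(CellState.OCT4_POS)
    radial = agg.radial_positions(normalized=True)
    return PatternMetrics(
        ucn=count_clusters(agg, CellState.OCT4_POS),
        dcn=count_clusters(agg, CellState.OCT4_NEG),
        fraction_pos=float(pos_mask.mean()),
        mean_radial_pos=float(radial[pos_mask].mean()) if pos_mask.any() else float("nan"),
        mean_radial_neg=float(radial[~pos_mask].mean()) if (~pos_mask).any() else float("nan"),
    )


def _minority_is_clustered(agg: Aggregate, minority_mask: np.ndarray, p: ClassifierParams) -> bool:
    n_min = int(minority_mask.sum())
    if n_min < 2:
        return False
    if p.method == "clustered_fraction":
        sizes = state_cluster_sizes(agg.n_cells, agg.edges, minority_mask)
        return float(sizes[sizes >= 2].sum()) / n_min >= p.connected_min_frac
    if p.method != "permutation":
        raise ValueError(f"unknown classifier method {p.method!r}")
    # chance-corrected clustering: compare the observed number of minority
    # components (singletons included) with its null under random relabelling
    # of the same number of cells on the same contact graph
    obs = len(state_cluster_sizes(agg.n_cells, agg.edges, minority_mask))
    rng = np.random.default_rng(p.permutation_seed)
    null = np.empty(p.n_permutations)
    shuffled = np.zeros(agg.n_cells, dtype=bool)
    for t in range(p.n_permutations):
        shuffled[:] = False
        shuffled[rng.choice(agg.n_cells, size=n_min, replace=False)] = True
        null[t] = len(state_cluster_sizes(agg.n_cells, agg.edges, shuffled))
    mu, sd = float(null.mean()), float(null.std())
    if sd == 0:
        return obs < mu
    return obs < mu - p.z_threshold * sd


def classify(agg: Aggregate, params: ClassifierParams | None = None) -> PatternClass:
    """Assign one of the six pattern classes to an aggregate snapshot.

    Invariant to rigid rotation/translation (all statistics derive from the
    contact graph and centroid-relative radii) and deterministic for a given
    input.
    """
    p = params or ClassifierParams()
    if agg.n_cells == 0:
        raise ValueError("cannot classify an empty aggregate")
    m = pattern_metrics(agg)
    if m.fraction_pos >= p.hi:
        return PatternClass.OCT4_POS
    if m.fraction_pos <= p.lo:
        return PatternClass.OCT4_NEG
    # transition subtypes
    radial_gap = m.mean_radial_neg - m.mean_radial_pos
    few_clusters = m.ucn <= p.max_shell_clusters and m.dcn <= p.max_shell_clusters
    if np.isfinite(radial_gap) and abs(radial_gap) > p.radial_delta and few_clusters:
        return PatternClass.INSIDE_OUT if radial_gap < 0 else PatternClass.OUTSIDE_IN
    pos_mask = agg.states == int(CellState.OCT4_POS)
    minority = pos_mask if m.fraction_pos <= 0.5 else ~pos_mask
    if _minority_is_clustered(agg, minority, p):
        return PatternClass.CONNECTED
    return PatternClass.RANDOM


def classify_section(
    agg: Aggregate, section: SectionView, params: ClassifierParams | None = None
) -> PatternClass:
    """Classify a virtual section using the 3D contact graph restricted to
    the section's member cells."""
    return classify(agg.subset(section.indices), params)


def snapshot(traj, step_index: int) -> Aggregate:
    """Aggregate with the state vector of a trajectory at a recorded step."""
    agg = traj.aggregate.copy()
    agg.states = traj.states[step_index].copy()
    return agg


def normalize_time(traj) -> np.ndarray:
    """Normalised time axis τ_k = k / K for a trajectory with K total steps.

    For an incomplete run (cutoff reached before every cell changed state)
    τ is taken relative to the step cutoff; the trajectory's ``completed``
    flag distinguishes the two cases.
    """
    steps = np.asarray(traj.steps)
    total = steps[-1] if traj.completed else max(int(steps[-1]), 1)
    return steps / total


def _resample(traj, values: np.ndarray, grid: np.ndarray) -> np.ndarray:
    """Nearest-step lookup of per-step values onto a common τ grid."""
    tau = normalize_time(traj)
    idx = np.abs(tau[None, :] - np.asarray(grid)[:, None]).argmin(axis=1)
    return np.asarray(values)[idx]


@dataclass
class TrajectorySummary:
    """Across-replicate mean/variance curves of UCN and DCN on a τ grid."""

    grid: np.ndarray
    ucn_mean: np.ndarray
    ucn_var: np.ndarray
    dcn_mean: np.ndarray
    dcn_var: np.ndarray
    cumulative_variance_ucn: float
    cumulative_variance_dcn: float

    @property
    def cumulative_variance(self) -> float:
        """Summed UCN + DCN variance over the τ grid (trajectory spread)."""
        return self.cumulative_variance_ucn + self.cumulative_variance_dcn


def trajectory_summary(runs: list, grid: np.ndarray | None = None) -> TrajectorySummary:
    """Mean and sample-variance UCN/DCN curves across replicate runs.

    ``grid`` defaults to 21 evenly spaced τ values in [0, 1]; the cumulative
    variance is the sum of the per-grid-point variances.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for variance curves")
    grid = np.linspace(0.0, 1.0, 21) if grid is None else np.asarray(grid, dtype=float)
    ucn = np.array([_resample(t, t.ucn, grid) for t in runs], dtype=float)
    dcn = np.array([_resample(t, t.dcn, grid) for t in runs], dtype=float)
    ucn_var = ucn.var(axis=0, ddof=1)
    dcn_var = dcn.var(axis=0, ddof=1)
    return TrajectorySummary(
        grid=grid,
        ucn_mean=ucn.mean(axis=0),
        ucn_var=ucn_var,
        dcn_mean=dcn.mean(axis=0),
        dcn_var=dcn_var,
        cumulative_variance_ucn=float(ucn_var.sum()),
        cumulative_variance_dcn=float(dcn_var.sum()),
    )


def pattern_distribution(
    runs: list,
    times: np.ndarray | None = None,
    params: ClassifierParams | None = None,
) -> pd.DataFrame:
    """Fraction of each pattern class across runs at each τ grid point.

    Rows are τ values, columns the six classes; every row sums to 1.
    """
    times = np.linspace(0.0, 1.0, 11) if times is None else np.asarray(times, dtype=float)
    counts = pd.DataFrame(
        0.0, index=times, columns=[c.value for c in PatternClass]
    )
    for traj in runs:
        tau = normalize_time(traj)
        for t in times:
            k = int(np.abs(tau - t).argmin())
            cls = classify(snapshot(traj, k), params)
            counts.loc[t, cls.value] += 1
    counts /= len(runs)
    counts.index.name = "tau"
    return counts
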