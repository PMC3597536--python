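import numpy as np
import pytest

from ebsim import (
    Aggregate,
    CellState,
    ClassifierParams,
    FixtureKind,
    FixtureSpec,
    PatternClass,
    classify,
    classify_section,
    count_clusters,
    make_fixture,
    normalize_time,
    pattern_distribution,
    pattern_metrics,
    snapshot,
    trajectory_summary,
    virtual_section,
)
from ebsim import RuleKind, RuleParams, run_static_simulation


def _graph_aggregate(n, edges, states):
    """Synthetic aggregate with an arbitrary prescribed contact graph."""
    pos = np.random.default_rng(0).uniform(0, 100, size=(n, 3))
    agg = Aggregate(pos, np.full(n, 3.0), np.asarray(states, dtype=np.int8))
    e = np.array(sorted(tuple(sorted(p)) for p in edges), dtype=np.intp).reshape(-1, 2)
    agg.edges = e
    agg.edge_lengths = (
        np.linalg.norm(pos[e[:, 0]] - pos[e[:, 1]], axis=1) if len(e) else np.empty(0)
    )
    return agg


def _dfs_components_oracle(n, edges, mask):
    """Independent depth-first component count (>= 2 members)."""
    adj = {i: [] for i in range(n)}
    for a, b in edges:
        if mask[a] and mask[b]:
            adj[a].append(b)
            adj[b].append(a)
    seen = set()
    count = 0
    for start in range(n):
        if not mask[start] or start in seen:
            continue
        stack, comp = [start], 0
        seen.add(start)
        while stack:
            v = stack.pop()
            comp += 1
            for w in adj[v]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        if comp >= 2:
            count += 1
    return count


class TestCountClusters:
    def test_lone_cell_is_not_a_cluster(self):
        agg = _graph_aggregate(3, [(0, 1)], [1, 1, 0])
        assert count_clusters(agg, CellState.OCT4_NEG) == 0

    def test_two_adjacent_cells_form_one_cluster(self):
        agg = _graph_aggregate(2, [(0, 1)], [0, 0])
        assert count_clusters(agg, CellState.OCT4_NEG) == 1

    def test_matches_dfs_oracle_on_random_graphs(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            n = int(rng.integers(2, 50))
            edges = set()
            for _ in range(int(rng.integers(0, 3 * n))):
                a, b = rng.integers(0, n, size=2)
                if a != b:
                    edges.add(tuple(sorted((int(a), int(b)))))
            states = rng.integers(0, 2, size=n).astype(np.int8)
            agg = _graph_aggregate(n, edges, states)
            for state in (CellState.OCT4_POS, CellState.OCT4_NEG):
                mask = states == int(state)
                assert count_clusters(agg, state) == _dfs_components_oracle(n, edges, mask)

    def test_ucn_plus_dcn_bounded_by_half_the_cells(self, packing_250):
        rng = np.random.default_rng(9)
        for _ in range(10):
            agg = packing_250.copy()
            agg.states = rng.integers(0, 2, size=agg.n_cells).astype(np.int8)
            m = pattern_metrics(agg)
            assert m.ucn + m.dcn <= agg.n_cells / 2


class TestPatternMetrics:
    def test_uniform_positive(self, packing_100):
        m = pattern_metrics(packing_100)
        assert (m.ucn, m.dcn, m.fraction_pos) == (1, 0, 1.0)
        assert np.isnan(m.mean_radial_neg)

    def test_uniform_negative(self, packing_100):
        agg = packing_100.copy()
        agg.states[:] = int(CellState.OCT4_NEG)
        m = pattern_metrics(agg)
        assert (m.ucn, m.dcn, m.fraction_pos) == (0, 1, 0.0)

    def test_shell_fixture_radial_ordering(self):
        fx = make_fixture(FixtureSpec(kind=FixtureKind.SHELL_INSIDE_OUT, size=300, seed=2))
        m = pattern_metrics(fx)
        assert m.mean_radial_neg < m.mean_radial_pos


class TestClassify:
    def _with_k_positive(self, packing, k, seed=0):
        agg = packing.copy()
        agg.states[:] = int(CellState.OCT4_NEG)
        idx = np.random.default_rng(seed).choice(agg.n_cells, size=k, replace=False)
        agg.states[idx] = int(CellState.OCT4_POS)
        return agg

    def test_ninety_percent_boundary(self, packing_100):
        assert classify(self._with_k_positive(packing_100, 90)) is PatternClass.OCT4_POS
        assert classify(self._with_k_positive(packing_100, 89)) is not PatternClass.OCT4_POS

    def test_ten_percent_boundary(self, packing_100):
        assert classify(self._with_k_positive(packing_100, 10)) is PatternClass.OCT4_NEG
        assert classify(self._with_k_positive(packing_100, 11)) is not PatternClass.OCT4_NEG

    def test_shell_fixtures(self):
        io = make_fixture(FixtureSpec(kind=FixtureKind.SHELL_INSIDE_OUT, size=400, seed=1))
        oi = make_fixture(FixtureSpec(kind=FixtureKind.SHELL_OUTSIDE_IN, size=400, seed=1))
        assert classify(io) is PatternClass.INSIDE_OUT
        assert classify(oi) is PatternClass.OUTSIDE_IN

    def test_two_blob_fixture_is_connected(self):
        fx = make_fixture(FixtureSpec(kind=FixtureKind.TWO_BLOB_CONNECTED, size=400, seed=1))
        assert classify(fx) is PatternClass.CONNECTED

    def test_checkerboard_is_random_with_high_probability(self, packing_250):
        # i.i.d. states are chance-level clustered, so the chance-corrected
        # test should almost never call them CONNECTED
        rng = np.random.default_rng(11)
        calls = []
        for _ in range(20):
            agg = packing_250.copy()
            agg.states = (rng.random(agg.n_cells) < 0.5).astype(np.int8)
            calls.append(classify(agg))
        assert calls.count(PatternClass.RANDOM) >= 18

    def test_rigid_motion_invariance(self, packing_250):
        agg = packing_250.copy()
        agg.states = (np.random.default_rng(4).random(agg.n_cells) < 0.6).astype(np.int8)
        base = classify(agg)
        theta = 1.1
        rot = np.array(
            [[1, 0, 0], [0, np.cos(theta), -np.sin(theta)], [0, np.sin(theta), np.cos(theta)]]
        )
        moved = agg.copy()
        moved.positions = agg.positions @ rot.T + np.array([50.0, -20.0, 5.0])
        assert classify(moved) is base

    def test_clustered_fraction_method_available(self):
        fx = make_fixture(FixtureSpec(kind=FixtureKind.TWO_BLOB_CONNECTED, size=300, seed=0))
        params = ClassifierParams(method="clustered_fraction")
        assert classify(fx, params) is PatternClass.CONNECTED

    def test_empty_input_rejected(self):
        agg = Aggregate(np.zeros((1, 3)), np.ones(1), np.ones(1, dtype=np.int8))
        with pytest.raises(ValueError):
            classify(agg.subset([]))

    def test_section_classification(self, packing_250):
        agg = packing_250.copy()
        agg.states[:] = int(CellState.OCT4_POS)
        sec = virtual_section(agg, z_center=float(agg.positions[:, 2].mean()), thickness=12.0)
        assert classify_section(agg, sec) is PatternClass.OCT4_POS


class TestTimeAndSummaries:
    def _trajectories(self, packing, kind=RuleKind.COMPETING_FEEDBACK, n=3):
        return [
            run_static_simulation(packing, RuleParams(kind=kind), seed=s) for s in range(n)
        ]

    def test_normalize_time_closed_form(self, packing_100):
        traj = self._trajectories(packing_100, n=1)[0]
        tau = normalize_time(traj)
        K = traj.n_steps
        assert tau[0] == 0.0
        assert tau[-1] == pytest.approx(1.0)
        if K >= 10:
            assert tau[6] == pytest.approx(6 / K)

    def test_single_step_run(self, packing_100):
        traj = run_static_simulation(
            packing_100, RuleParams(kind=RuleKind.RANDOM, alpha=1.0), seed=0
        )
        assert list(normalize_time(traj)) == [0.0, 1.0]

    def test_resampling_preserves_endpoints(self, packing_100):
        traj = self._trajectories(packing_100, n=1)[0]
        from ebsim.patterns import _resample

        grid = np.array([0.0, 1.0])
        res = _resample(traj, traj.ucn, grid)
        assert res[0] == traj.ucn[0] and res[-1] == traj.ucn[-1]

    def test_identical_runs_have_zero_variance(self, packing_100):
        traj = self._trajectories(packing_100, n=1)[0]
        summary = trajectory_summary([traj, traj])
        assert summary.cumulative_variance == 0.0

    def test_constant_offset_variance_closed_form(self, packing_100):
        # two runs offset by c in UCN: sample variance c^2/2 at every grid
        # point, so the cumulative variance is len(grid) * c^2 / 2
        import copy

        traj = self._trajectories(packing_100, n=1)[0]
        shifted = copy.copy(traj)
        c = 3.0
        shifted.ucn = traj.ucn + c
        grid = np.linspace(0, 1, 11)
        summary = trajectory_summary([traj, shifted], grid=grid)
        assert summary.cumulative_variance_ucn == pytest.approx(len(grid) * c**2 / 2)
        assert summary.cumulative_variance_dcn == pytest.approx(0.0)

    def test_summary_requires_two_runs(self, packing_100):
        with pytest.raises(ValueError):
            trajectory_summary(self._trajectories(packing_100, n=1))

    def test_pattern_distribution_rows_sum_to_one(self, packing_100):
        runs = self._trajectories(packing_100, n=3)
        dist = pattern_distribution(runs)
        assert np.allclose(dist.sum(axis=1), 1.0)

    def test_pattern_distribution_degenerate_single_class(self, packing_100):
        traj = run_static_simulation(
            packing_100, RuleParams(kind=RuleKind.POSITIVE_FEEDBACK, alpha=0.0), max_steps=5, seed=0
        )
        dist = pattern_distribution([traj], times=np.array([0.0, 0.5, 1.0]))
        assert (dist["oct4_pos"] == 1.0).all()

    def test_snapshot_reflects_recorded_states(self, packing_100):
        traj = self._trajectories(packing_100, n=1)[0]
        agg = snapshot(traj, traj.n_steps)
        assert (agg.states == int(CellState.OCT4_NEG)).all() or not traj.completed
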