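"""The three stochastic update rules and the trajectory runner."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swarmgraph.graph_core import CellGraph, ConfigurationError, make_empty_graph
from swarmgraph.processes import (
    Model,
    ProcessConfig,
    run_process,
    run_single,
    step_model1,
    step_model2,
    step_model3,
)


class TestProcessConfig:
    def test_model2_requires_p_edge(self):
        with pytest.raises(ConfigurationError):
            ProcessConfig(model=Model.MODEL2, n_cells=10, t_max=5)

    def test_model3_requires_p_death(self):
        with pytest.raises(ConfigurationError):
            ProcessConfig(model=Model.MODEL3, n_cells=10, t_max=5, p_edge=0.1)

    def test_threshold_must_not_exceed_n(self):
        with pytest.raises(ConfigurationError):
            ProcessConfig(model=Model.MODEL1, n_cells=4, t_max=5, threshold_m=5)

    def test_model_accepts_string(self):
        cfg = ProcessConfig(model="model1", n_cells=4, t_max=1)
        assert cfg.model is Model.MODEL1

    def test_replicate_streams_are_reproducible(self):
        cfg = ProcessConfig(model=Model.MODEL1, n_cells=4, t_max=1, seed=42,
                            replicates=3)
        a = cfg.replicate_rng(2).integers(0, 1 << 30, 4)
        b = cfg.replicate_rng(2).integers(0, 1 << 30, 4)
        c = cfg.replicate_rng(1).integers(0, 1 << 30, 4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestStepModel1:
    def test_specific_pair_probability(self, rng):
        """On an empty 4-vertex graph a given pair gains its edge w.p. 2/16."""
        hits = 0
        trials = 40_000
        for _ in range(trials):
            g = make_empty_graph(4)
            step_model1(g, rng)
            hits += (0, 1) in g.edges
        # Binomial(40000, 0.125): 5 sigma band
        assert abs(hits / trials - 0.125) < 5 * np.sqrt(0.125 * 0.875 / trials)

    def test_saturated_graph_is_absorbing(self, rng):
        g = CellGraph(n_vertices=3, edges={(0, 1), (1, 2), (0, 2)})
        for _ in range(50):
            step_model1(g, rng)
        assert g.n_edges == 3

    def test_at_most_one_edge_per_step(self, rng):
        g = make_empty_graph(10)
        for t in range(1, 30):
            step_model1(g, rng)
            assert g.n_edges <= t


class TestStepModel2:
    def test_p_zero_is_noop(self, rng):
        g = make_empty_graph(8)
        assert step_model2(g, 0.0, rng) == 0
        assert g.n_edges == 0

    def test_p_one_on_three_vertices_gives_triangle(self, rng):
        """With P=1 every pair is eligible when visited: one sweep closes
        the triangle regardless of visit order."""
        for _ in range(20):
            g = make_empty_graph(3)
            step_model2(g, 1.0, rng)
            assert g.edges == {(0, 1), (0, 2), (1, 2)}
            assert g.degree == [2, 2, 2]

    def test_first_sweep_edge_count_matches_binomial_mean(self):
        """N=1000, P=1e-4: ~Binomial(N(N-1)/2, P) edges in the first sweep."""
        p = 1e-4
        n_pairs = 1000 * 999 // 2
        added = []
        for rep in range(10):
            g = make_empty_graph(1000)
            added.append(step_model2(g, p, np.random.default_rng(rep)))
        mean = np.mean(added)
        sd_of_mean = np.sqrt(n_pairs * p * (1 - p) / 10)
        assert abs(mean - n_pairs * p) < 4 * sd_of_mean

    def test_invalid_probability(self, rng):
        with pytest.raises(ConfigurationError):
            step_model2(make_empty_graph(3), 1.5, rng)

    @given(n=st.integers(2, 12), p=st.floats(0.0, 1.0), seed=st.integers(0, 99))
    @settings(max_examples=40)
    def test_graph_invariants_after_sweep(self, n, p, seed):
        g = make_empty_graph(n)
        rng = np.random.default_rng(seed)
        for _ in range(3):
            step_model2(g, p, rng)
        assert max(g.degree) <= 2
        assert all(i < j for i, j in g.edges)
        # degree array consistent with edge set
        deg = [0] * n
        for i, j in g.edges:
            deg[i] += 1
            deg[j] += 1
        assert deg == g.degree


class TestStepModel3:
    def test_death_zero_reduces_to_model2_stats(self):
        """p_D=0: edge counts across replicates match Model 2's law."""
        added2, added3 = [], []
        for rep in range(40):
            g2, g3 = make_empty_graph(60), make_empty_graph(60)
            added2.append(step_model2(g2, 0.05, np.random.default_rng(rep)))
            added3.append(
                step_model3(g3, 0.05, 0.0, np.random.default_rng(1000 + rep))[0]
            )
        assert abs(np.mean(added2) - np.mean(added3)) < 3 * (
            np.std(added2) + np.std(added3)
        ) / np.sqrt(40)

    def test_death_one_clears_all_edges(self, rng):
        g = CellGraph(n_vertices=5, edges={(0, 1), (1, 2), (3, 4)})
        step_model3(g, 0.0, 1.0, rng)
        assert g.n_edges == 0
        assert g.degree == [0] * 5

    def test_death_zeroes_row_and_column(self):
        """3-cycle on {0,1,2}: killing vertex 1 leaves only edge {0,2}."""
        g = CellGraph(n_vertices=3, edges={(0, 1), (1, 2), (0, 2)})
        g.kill_vertex(1)
        assert g.edges == {(0, 2)}
        assert g.degree == [1, 0, 1]

    def test_dead_cell_can_reconnect(self, rng):
        g = CellGraph(n_vertices=2, edges={(0, 1)})
        g.kill_vertex(0)
        assert g.n_edges == 0
        step_model2(g, 1.0, rng)
        assert g.edges == {(0, 1)}


class TestRunProcess:
    def test_zero_horizon_trajectory(self):
        cfg = ProcessConfig(model=Model.MODEL1, n_cells=4, t_max=0)
        (tr,) = run_process(cfg)
        assert len(tr) == 1
        assert tr.edge_counts[0] == 0
        assert tr.giant_sizes[0] == 1

    def test_invalid_config_fails_before_simulation(self):
        with pytest.raises(ConfigurationError):
            ProcessConfig(model=Model.MODEL2, n_cells=10, t_max=5, p_edge=2.0)

    @pytest.mark.parametrize(
        "cfg_kwargs",
        [
            dict(model=Model.MODEL1, n_cells=30, t_max=200),
            dict(model=Model.MODEL2, n_cells=30, t_max=50, p_edge=0.01),
        ],
    )
    def test_monotone_models_never_shrink(self, cfg_kwargs):
        """Models 1-2 are monotone graph processes: edges and giant size
        are non-decreasing along every trajectory."""
        cfg = ProcessConfig(seed=7, replicates=3, **cfg_kwargs)
        for tr in run_process(cfg):
            assert np.all(np.diff(tr.edge_counts) >= 0)
            assert np.all(np.diff(tr.giant_sizes) >= 0)
            if cfg.model is Model.MODEL1:
                assert np.all(tr.edge_counts <= tr.times)

    def test_determinism_same_seed_same_bytes(self):
        cfg = ProcessConfig(model=Model.MODEL3, n_cells=25, t_max=40,
                            p_edge=0.02, p_death=0.05, seed=11, replicates=2)
        a, b = run_process(cfg), run_process(cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.edge_counts, tb.edge_counts)
            assert np.array_equal(ta.giant_sizes, tb.giant_sizes)

    def test_snapshots_conserve_cells(self):
        cfg = ProcessConfig(model=Model.MODEL2, n_cells=50, t_max=30,
                            p_edge=0.05, seed=3, snapshot_times=(0, 10, 30))
        (tr,) = run_process(cfg)
        for t, sizes in tr.snapshots.items():
            assert sizes.sum() == 50

    def test_saturation_padding_keeps_full_length(self):
        """Early saturation freezes the state; series are padded to t_max."""
        cfg = ProcessConfig(model=Model.MODEL2, n_cells=6, t_max=200,
                            p_edge=1.0, seed=1)
        tr = run_single(cfg)
        assert len(tr.edge_counts) == 201
        assert tr.edge_counts[-1] == tr.edge_counts[100]

    def test_model2_stochastic_dominance_in_p(self):
        """Larger P gives a larger mean giant component at fixed time."""
        means = []
        for p in (0.002, 0.02):
            cfg = ProcessConfig(model=Model.MODEL2, n_cells=60, t_max=40,
                                p_edge=p, seed=5, replicates=10)
            means.append(np.mean([tr.giant_sizes[-1] for tr in run_process(cfg)]))
        assert means[1] > means[0]

    def test_model3_high_death_rate_prevents_growth(self):
        """With aggressive death the giant component stays far below N."""
        cfg = ProcessConfig(model=Model.MODEL3, n_cells=80, t_max=300,
                            p_edge=0.01, p_death=0.2, seed=9, replicates=3)
        for tr in run_process(cfg):
            assert tr.giant_sizes.max() < 80
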