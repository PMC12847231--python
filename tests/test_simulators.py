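import numpy as np
import pytest

from epelearn import simulators as sim


class TestSecondMomentAndPosterior:
    @pytest.mark.parametrize("y, expected", [
        ([1, 1, 1, 1], 1.0),
        ([0, 0], 0.0),
        ([1, -1, 2, 0], 1.5),
    ])
    def test_second_moment(self, y, expected):
        assert sim.second_moment(np.asarray(y)) == pytest.approx(expected)

    def test_second_moment_empty_rejected(self):
        with pytest.raises(ValueError):
            sim.second_moment(np.array([]))

    @pytest.mark.parametrize("args, expected", [
        ((1.5, 1.0, 4, 0.3), (3.5, 1.6)),
        ((2.0, 2.0, 0, 5.0), (2.0, 2.0)),  # no data: posterior = prior
        ((2.0, 2.0, 10, 1.0), (7.0, 7.0)),
    ])
    def test_conjugate_update(self, args, expected):
        assert sim.gamma_posterior(*args) == pytest.approx(expected)

    def test_negative_second_moment_rejected(self):
        with pytest.raises(ValueError):
            sim.gamma_posterior(1.5, 1.0, 4, -0.1)


class TestGammaToy:
    def test_prior_mean_and_structure(self, rng):
        table = sim.simulate_gamma_toy(1.5, 1.0, 4, 50_000, rng)
        assert table.payloads.shape == (50_000, 4, 1)
        assert np.all(table.params > 0)
        assert table.params.mean() == pytest.approx(1.5, rel=0.02)
        # stored summaries are the per-dataset second moments
        assert np.allclose(table.summaries[:, 0],
                           np.mean(table.payloads[:, :, 0] ** 2, axis=1))

    def test_posterior_mean_consistency(self, rng):
        # with n large the posterior mean recovers the generating precision
        theta = 1.7
        y = rng.standard_normal(10_000) / np.sqrt(theta)
        alpha, beta = sim.gamma_posterior(1.5, 1.0, y.size, sim.second_moment(y))
        assert alpha / beta == pytest.approx(theta, rel=0.05)

    def test_reflected_variant_symmetry(self, rng):
        table = sim.simulate_reflected_gamma_toy(1.5, 1.0, 4, 100_000, rng)
        theta = table.params[:, 0]
        assert np.mean(theta) == pytest.approx(0.0, abs=0.03)
        assert np.mean(np.abs(theta)) == pytest.approx(1.5, rel=0.02)
        assert np.mean(theta > 0) == pytest.approx(0.5, abs=0.01)


class TestPiecewise:
    def test_branch_moments(self, rng):
        # negative parameters code the variance, positive ones the mean
        left = sim.simulate_piecewise(-1.0, 1e-9, 2000, 200, rng)
        assert left.payloads.var() == pytest.approx(np.exp(-1.0), rel=0.05)
        right = sim.simulate_piecewise(1.0, 1e-9, 2000, 200, rng)
        assert right.payloads.mean() == pytest.approx(1.0, abs=0.01)
        assert right.payloads.var() == pytest.approx(1.0, rel=0.05)


class TestBenchmark:
    def test_unit_variance_for_any_theta(self, rng):
        table = sim.simulate_benchmark(10, 100_000, rng)
        z1 = table.payloads[:, :, 0]
        assert np.mean(z1) == pytest.approx(0.0, abs=0.01)
        assert np.mean(z1 ** 2) == pytest.approx(1.0, rel=0.01)
        assert np.mean(z1 ** 3) == pytest.approx(0.0, abs=0.02)

    def test_theta_zero_is_standard_normal(self, rng):
        # tanh(0) = 0 collapses the mixture to a standard normal
        tau = np.tanh(0.0)
        assert tau == 0.0

    @pytest.mark.parametrize("z, expected", [
        (np.ones((5, 2)), np.ones(6)),
        (np.zeros((5, 2)), np.zeros(6)),
        (np.array([[1.0, 0.0], [-1.0, 0.0]]), [1, 1, 1, 0, 0, 0]),
    ])
    def test_candidate_moments(self, z, expected):
        assert np.allclose(sim.benchmark_candidate_summaries(z), expected)

    def test_candidate_moments_require_two_columns(self):
        with pytest.raises(ValueError):
            sim.benchmark_candidate_summaries(np.ones((5, 3)))


class TestTrees:
    def test_two_node_tree_is_single_edge(self, rng):
        tree = sim.simulate_tree(0.7, 2, rng)
        assert tree.edges.tolist() == [[0, 1]]

    def test_validity_over_many_draws(self, rng):
        edges = sim.simulate_trees(rng.uniform(0, 2, 200), 30, rng)
        for e in edges:
            tree = sim.Tree(30, e)  # validates connectivity and edge count
            assert tree.degrees().sum() == 2 * 29

    def test_uniform_attachment_when_theta_zero(self, rng):
        # theta = 0 gives the random recursive tree: the third node attaches
        # to nodes 0 and 1 with equal probability
        edges = sim.simulate_trees(np.zeros(4000), 3, rng)
        frac = np.mean(edges[:, 1, 0] == 0)
        assert frac == pytest.approx(0.5, abs=0.03)

    def test_superlinear_attachment_gives_stars(self, rng):
        edges = sim.simulate_trees(np.full(300, 10.0), 100, rng)
        max_deg = [sim.tree_degrees(e, 100).max() for e in edges]
        assert np.mean(np.asarray(max_deg) == 99) >= 0.95

    def test_invalid_tree_rejected(self):
        with pytest.raises(ValueError):
            sim.Tree(4, np.array([[0, 1], [2, 3], [0, 1]]))  # disconnected/duplicate

    def test_reproducibility(self):
        a = sim.simulate_trees(np.linspace(0, 2, 50), 40, np.random.default_rng(5))
        b = sim.simulate_trees(np.linspace(0, 2, 50), 40, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestTreeSummaries:
    def test_path_graph_hand_values(self):
        path = sim.Tree(4, np.array([[0, 1], [1, 2], [2, 3]]))
        std, gini, diam, bet = sim.tree_candidate_summaries(path)
        assert std == pytest.approx(0.5)
        assert gini == pytest.approx(1 / 6)
        assert diam == 3
        # central nodes each carry 2 + 2 = ... pairs: computed below vs networkx

    def test_star_graph_hand_values(self):
        star = sim.Tree(4, np.array([[0, 1], [0, 2], [0, 3]]))
        std, gini, diam, bet = sim.tree_candidate_summaries(star)
        assert std == pytest.approx(np.sqrt(0.75))
        assert diam == 2
        assert bet == pytest.approx(3.0)  # all three leaf pairs route via hub

    def test_matches_networkx_on_random_trees(self, rng):
        import networkx as nx

        for _ in range(10):
            tree = sim.Tree(25, sim.simulate_trees(rng.uniform(0, 2, 1), 25, rng)[0])
            g = tree.to_networkx()
            _, _, diam, bet = sim.tree_candidate_summaries(tree)
            assert diam == nx.diameter(g)
            nx_bet = max(nx.betweenness_centrality(g, normalized=False).values())
            assert bet == pytest.approx(nx_bet)


class TestReferenceTable:
    def test_hdf5_roundtrip(self, rng, tmp_path):
        table = sim.simulate_benchmark(5, 20, rng)
        path = tmp_path / "table.h5"
        table.to_hdf5(path)
        back = sim.ReferenceTable.from_hdf5(path)
        assert np.array_equal(back.params, table.params)
        assert np.array_equal(back.payloads, table.payloads)
        assert back.payload_kind == "matrix"

    def test_tree_table_roundtrip(self, rng, tmp_path):
        table = sim.simulate_tree_table(0, 2, 10, 7, rng)
        path = tmp_path / "trees.h5"
        table.to_hdf5(path)
        back = sim.ReferenceTable.from_hdf5(path)
        assert np.array_equal(back.payloads, table.payloads)
        assert back.tree(3).node_count == 10

    def test_edge_csv_export(self, rng, tmp_path):
        import pandas as pd

        tree = sim.simulate_tree(1.0, 6, rng)
        path = tmp_path / "edges.csv"
        tree.to_edge_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["source", "target"]
        assert np.array_equal(frame.to_numpy(), tree.edges)

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            sim.ReferenceTable(params=np.ones((3, 1)), payloads=np.ones((4, 2, 1)),
                               payload_kind="matrix")
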