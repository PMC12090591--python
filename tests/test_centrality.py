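"""Centrality indices against hand computations and exhaustive enumeration."""

import numpy as np
import pytest

from oracles import brute_betweenness, brute_closeness, brute_distances
from symptomnet import (
    WeightedNetwork,
    betweenness,
    centrality_table,
    closeness,
    expected_influence,
    shortest_path_lengths,
    strength,
)


def net_from(w: np.ndarray) -> WeightedNetwork:
    return WeightedNetwork(w, tuple(f"N{i}" for i in range(w.shape[0])))


@pytest.fixture
def path_3():
    """A--B (0.5), B--C (0.5)."""
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = 0.5
    w[1, 2] = w[2, 1] = 0.5
    return net_from(w)


@pytest.fixture
def random_small_nets():
    """50 random weighted graphs with p <= 7, mixed signs and densities."""
    rng = np.random.default_rng(123)
    nets = []
    for _ in range(50):
        p = int(rng.integers(3, 8))
        w = np.zeros((p, p))
        iu, ju = np.triu_indices(p, k=1)
        mask = rng.random(iu.size) < rng.uniform(0.3, 0.9)
        vals = rng.uniform(0.1, 0.9, iu.size) * rng.choice([-1, 1], iu.size)
        w[iu[mask], ju[mask]] = vals[mask]
        w[ju[mask], iu[mask]] = vals[mask]
        nets.append(net_from(w))
    return nets


class TestHandExamples:
    def test_strength_on_path(self, path_3):
        assert np.allclose(strength(path_3), [0.5, 1.0, 0.5])

    def test_strength_and_influence_with_mixed_signs(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.3
        w[0, 2] = w[2, 0] = -0.4
        net = net_from(w)
        assert strength(net)[0] == pytest.approx(0.7)
        assert expected_influence(net)[0] == pytest.approx(-0.1)

    def test_influence_equals_strength_when_all_positive(self, path_3):
        assert np.allclose(expected_influence(path_3), strength(path_3))

    def test_single_negative_edge_influence(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = -0.2
        assert np.allclose(expected_influence(net_from(w)), [-0.2, -0.2])

    def test_distances_on_path(self, path_3):
        d = shortest_path_lengths(path_3)
        assert d[0, 1] == pytest.approx(2.0)
        assert d[0, 2] == pytest.approx(4.0)

    def test_disconnected_pair_infinite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        d = shortest_path_lengths(net_from(w))
        assert np.isinf(d[0, 2])

    def test_closeness_on_path(self, path_3):
        c = closeness(path_3)
        assert c[1] == pytest.approx(1 / 4)
        assert c[0] == pytest.approx(1 / 6)

    def test_closeness_two_nodes(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.5
        assert np.allclose(closeness(net_from(w)), [0.5, 0.5])

    def test_isolated_node_closeness_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        assert closeness(net_from(w))[2] == 0.0

    def test_betweenness_path_middle(self, path_3):
        assert np.allclose(betweenness(path_3), [0.0, 1.0, 0.0])

    def test_betweenness_complete_triangle_zero(self):
        w = np.full((3, 3), 0.5)
        np.fill_diagonal(w, 0.0)
        assert np.allclose(betweenness(net_from(w)), 0.0)

    def test_betweenness_star_center(self):
        w = np.zeros((4, 4))
        for leaf in (1, 2, 3):
            w[0, leaf] = w[leaf, 0] = 0.5
        assert np.allclose(betweenness(net_from(w)), [3.0, 0, 0, 0])

    def test_ordered_pairs_flag_doubles(self, path_3):
        assert np.allclose(betweenness(path_3, ordered_pairs=True),
                           2 * betweenness(path_3))

    def test_empty_network_all_zero(self):
        net = net_from(np.zeros((4, 4)))
        assert np.allclose(strength(net), 0.0)
        assert np.allclose(closeness(net), 0.0)
        assert np.allclose(betweenness(net), 0.0)


class TestEnumerationOracle:
    def test_distances_closeness_betweenness_match(self, random_small_nets):
        for i, net in enumerate(random_small_nets):
            w = net.weights
            assert np.allclose(shortest_path_lengths(net), brute_distances(w),
                               atol=1e-9), f"distances, graph {i}"
            assert np.allclose(closeness(net), brute_closeness(w),
                               atol=1e-9), f"closeness, graph {i}"
            assert np.allclose(betweenness(net), brute_betweenness(w),
                               atol=1e-9), f"betweenness, graph {i}"


class TestProperties:
    def test_scale_invariance_of_ranks(self, random_small_nets):
        # shrink (weights must stay below 1): distances scale by 1/c,
        # closeness by c, betweenness not at all
        c = 0.37
        for net in random_small_nets[:10]:
            scaled = net_from(net.weights * c)
            assert np.allclose(closeness(scaled), closeness(net) * c)
            assert np.allclose(betweenness(scaled), betweenness(net))

    def test_strength_linear_on_shared_support(self):
        rng = np.random.default_rng(7)
        p = 6
        iu, ju = np.triu_indices(p, k=1)
        mask = rng.random(iu.size) < 0.5
        signs = rng.choice([-1, 1], iu.size)  # shared per-edge signs

        def rand_net():
            w = np.zeros((p, p))
            vals = rng.uniform(0.05, 0.45, iu.size) * signs
            w[iu[mask], ju[mask]] = vals[mask]
            w[ju[mask], iu[mask]] = vals[mask]
            return w

        w1, w2 = rand_net(), rand_net()
        assert np.abs(w1 + w2).max() < 1
        total = net_from(w1 + w2)
        assert np.allclose(strength(total), strength(net_from(w1)) + strength(net_from(w2)))
        assert np.allclose(expected_influence(total),
                           expected_influence(net_from(w1)) + expected_influence(net_from(w2)))


class TestCentralityTable:
    def test_invariants(self, random_small_nets):
        net = random_small_nets[0]
        df = centrality_table(net)
        assert (df["strength"] >= 0).all()
        assert (df["closeness"] >= 0).all()
        assert (df["betweenness"] >= 0).all()
        assert (df["expected_influence"].abs() <= df["strength"] + 1e-12).all()
        for col in ("strength_z", "closeness_z", "betweenness_z"):
            if df[col].std(ddof=1) > 0:
                assert df[col].mean() == pytest.approx(0.0, abs=1e-12)
                assert df[col].std(ddof=1) == pytest.approx(1.0)
        assert (df["strength"].diff().dropna() <= 1e-12).all()  # sorted descending
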