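"""Bootstrap CIs, difference tests, and case-dropping stability."""

import numpy as np
import pytest

from symptomnet import (
    MarginalSpec,
    StabilityResult,
    SymptomDataset,
    TrueNetwork,
    WeightedNetwork,
    bootstrap_network,
    case_dropping,
    cs_coefficient,
    edge_difference_test,
    generate_dataset,
    make_true_network,
    node_difference_test,
)
from symptomnet.stability import BootstrapResult, _pairwise_difference

pytestmark = pytest.mark.filterwarnings("ignore:fewer than 1000")

FAST = {"n_lambda": 20}


def _flat_marginals(p):
    return MarginalSpec(np.full(p, 0.8), np.full(p, 3.0),
                        tuple(f"S{i+1}" for i in range(p)))


@pytest.fixture(scope="module")
def small_strong_dataset():
    truth = make_true_network(6, 0.4, (0.3, 0.45), seed=5)
    return generate_dataset(truth, _flat_marginals(6), 300, seed=6)


class TestBootstrapNetwork:
    def test_deterministic_given_seed(self, small_strong_dataset):
        a = bootstrap_network(small_strong_dataset, B=100, seed=3, estimator_kwargs=FAST)
        b = bootstrap_network(small_strong_dataset, B=100, seed=3, estimator_kwargs=FAST)
        assert np.array_equal(a.replicate_edges, b.replicate_edges)
        assert a.edge_ci().equals(b.edge_ci())

    def test_degenerate_estimator_gives_zero_width_cis(self, small_strong_dataset):
        w = np.zeros((6, 6))
        w[0, 1] = w[1, 0] = 0.3
        fixed = WeightedNetwork(w, small_strong_dataset.labels)

        def constant_estimator(data, **kwargs):
            return fixed

        boot = bootstrap_network(small_strong_dataset, B=100, seed=0,
                                 estimator=constant_estimator)
        ci = boot.edge_ci()
        assert np.allclose(ci["lower"], ci["upper"])
        assert np.allclose(ci["lower"], ci["estimate"])

    def test_strong_edge_ci_excludes_zero(self):
        omega = np.eye(6)
        omega[0, 1] = omega[1, 0] = -0.4
        truth = TrueNetwork.from_precision(omega)
        marg = _flat_marginals(6)
        hits = 0
        for seed in range(5):
            data = generate_dataset(truth, marg, 1000, seed=40 + seed)
            boot = bootstrap_network(data, B=200, seed=seed, estimator_kwargs=FAST)
            ci = boot.edge_ci().set_index("edge").loc["S1--S2"]
            hits += ci["lower"] > 0
        assert hits >= 4

    def test_replicates_obey_network_invariants(self, small_strong_dataset):
        boot = bootstrap_network(small_strong_dataset, B=100, seed=1,
                                 estimator_kwargs=FAST)
        assert np.abs(boot.replicate_edges).max() < 1
        assert (boot.replicate_strength >= 0).all()
        ci = boot.edge_ci()
        assert (ci["lower"] <= ci["upper"]).all()

    def test_too_few_replicates_rejected(self, small_strong_dataset):
        with pytest.raises(ValueError):
            bootstrap_network(small_strong_dataset, B=50)


class TestDifferenceTests:
    def _boot_from_replicates(self, reps: np.ndarray) -> BootstrapResult:
        """Assemble a minimal BootstrapResult around hand-built edge replicates."""
        m = reps.shape[1]
        p = 3
        w = np.zeros((p, p))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.1
        net = WeightedNetwork(w, ("A", "B", "C"))
        pairs = ((0, 1), (0, 2), (1, 2))[:m]
        return BootstrapResult(net, reps, np.zeros((reps.shape[0], p)),
                               np.zeros((reps.shape[0], p)), reps.shape[0], 0, pairs)

    def test_hand_built_percentile_arithmetic(self):
        reps = np.array([[0.5, 0.1], [0.6, 0.2], [0.55, 0.15], [0.52, 0.12], [0.58, 0.18]])
        boot = self._boot_from_replicates(reps)
        dm = edge_difference_test(boot, alpha=0.05)
        diff = reps[:, 0] - reps[:, 1]
        lo, hi = np.quantile(diff, [0.025, 0.975])
        expected = (lo > 0) or (hi < 0)
        assert dm.significant[0, 1] == expected
        assert not dm.significant.diagonal().any()
        assert np.array_equal(dm.significant, dm.significant.T)

    def test_disjoint_ranges_significant(self):
        rng = np.random.default_rng(0)
        reps = np.column_stack([rng.uniform(0.4, 0.5, 200), rng.uniform(0.1, 0.2, 200)])
        boot = self._boot_from_replicates(reps)
        assert edge_difference_test(boot, alpha=0.05).significant[0, 1]

    def test_identical_edges_never_differ(self):
        reps = np.column_stack([np.linspace(0.1, 0.5, 50)] * 2)
        boot = self._boot_from_replicates(reps)
        assert not edge_difference_test(boot).significant[0, 1]

    def test_node_dominance_significant(self):
        rng = np.random.default_rng(1)
        s = np.column_stack([
            rng.uniform(2.0, 2.5, 100),
            rng.uniform(1.0, 1.4, 100),
            rng.uniform(1.0, 2.6, 100),
        ])
        p = 3
        w = np.zeros((p, p)); w[0, 1] = w[1, 0] = 0.3
        net = WeightedNetwork(w, ("A", "B", "C"))
        boot = BootstrapResult(net, np.zeros((100, 3)), s, s, 100, 0,
                               ((0, 1), (0, 2), (1, 2)))
        dm = node_difference_test(boot, "strength")
        assert dm.significant[0, 1]
        assert not dm.significant.diagonal().any()

    def test_bonferroni_is_no_more_liberal(self):
        rng = np.random.default_rng(2)
        reps = rng.normal(0.3, 0.05, size=(200, 3)) + np.array([0.0, 0.02, 0.2])
        boot = self._boot_from_replicates(reps)
        plain = edge_difference_test(boot, alpha=0.05)
        corrected = edge_difference_test(boot, alpha=0.05, bonferroni=True)
        assert (corrected.significant <= plain.significant).all()

    def test_pairwise_matrix_shape_and_symmetry(self):
        reps = np.random.default_rng(3).normal(size=(60, 4))
        sig = _pairwise_difference(reps, 0.05, False)
        assert sig.shape == (4, 4)
        assert np.array_equal(sig, sig.T)
        assert not sig.diagonal().any()


class TestCaseDropping:
    def test_duplicated_blocks_keep_centrality_stable(self):
        truth = make_true_network(5, 0.5, (0.3, 0.45), seed=9)
        block = generate_dataset(truth, _flat_marginals(5), 150, seed=10)
        doubled = SymptomDataset(np.vstack([block.scores, block.scores]),
                                 block.labels)
        res = case_dropping(doubled, "strength", drop_grid=(0.5,), B=50, seed=1,
                            estimator_kwargs=FAST)
        assert float(np.mean(res.correlations[0.5])) > 0.85

    def test_subsample_smaller_than_p_plus_one_skipped(self, small_strong_dataset):
        with pytest.warns(UserWarning, match="skipped"):
            res = case_dropping(small_strong_dataset, "strength",
                                drop_grid=(0.2, 0.99), B=50, seed=0,
                                estimator_kwargs=FAST)
        assert res.drop_proportions == (0.2,)

    def test_multiple_indices_share_subsamples(self, small_strong_dataset):
        res = case_dropping(small_strong_dataset, ("strength", "expected_influence"),
                            drop_grid=(0.3,), B=50, seed=2, estimator_kwargs=FAST)
        assert set(res) == {"strength", "expected_influence"}
        assert res["strength"].drop_proportions == (0.3,)

    def test_deterministic_given_seed(self, small_strong_dataset):
        a = case_dropping(small_strong_dataset, "strength", drop_grid=(0.3,),
                          B=50, seed=4, estimator_kwargs=FAST)
        b = case_dropping(small_strong_dataset, "strength", drop_grid=(0.3,),
                          B=50, seed=4, estimator_kwargs=FAST)
        assert np.array_equal(a.correlations[0.3], b.correlations[0.3])


class TestCsCoefficient:
    def _result(self, corr_by_q):
        return StabilityResult(
            "strength",
            tuple(corr_by_q),
            {q: np.asarray(v, dtype=float) for q, v in corr_by_q.items()},
        )

    def test_all_perfect_gives_max_grid(self):
        res = self._result({q: np.ones(20) for q in (0.1, 0.3, 0.5, 0.7)})
        assert cs_coefficient(res) == 0.7

    def test_all_zero_gives_zero(self):
        res = self._result({q: np.zeros(20) for q in (0.1, 0.3)})
        assert cs_coefficient(res) == 0.0

    def test_grid_scan_stops_at_first_failure(self):
        good = np.full(20, 0.9)
        bad = np.full(20, 0.2)
        res = self._result({0.1: good, 0.2: good, 0.3: good, 0.4: good, 0.5: bad,
                            0.6: good})
        assert cs_coefficient(res) == 0.4

    def test_95_percent_rule(self):
        # exactly 94 of 100 above 0.7 fails; 95 passes
        fail = np.concatenate([np.full(94, 0.9), np.full(6, 0.1)])
        ok = np.concatenate([np.full(95, 0.9), np.full(5, 0.1)])
        assert cs_coefficient(self._result({0.1: fail})) == 0.0
        assert cs_coefficient(self._result({0.1: ok})) == 0.1
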