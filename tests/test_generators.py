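"""Tree, niche-web, random-flow and null-model generators."""

import numpy as np
import pytest

from enaflow import (
    NicheParams,
    TreeSpec,
    assign_random_flows,
    balance,
    banavar_flow,
    chain_tree,
    check_balance,
    impact,
    niche_web,
    null_model,
    star_tree,
    subtree_impact,
    throughflow,
)
from enaflow.generators import NULL_MODES, _all_reachable


class TestTreeSpecs:
    def test_chain(self):
        np.testing.assert_array_equal(chain_tree(2).parent, [-1, 0])
        assert chain_tree(1).n == 1

    def test_star(self):
        np.testing.assert_array_equal(star_tree(3).parent, [-1, 0, 0, 0])

    def test_rejects_cycle(self):
        with pytest.raises(ValueError, match="cycle|root"):
            TreeSpec(np.array([1, 0]))

    def test_rejects_two_roots(self):
        with pytest.raises(ValueError, match="root"):
            TreeSpec(np.array([-1, -1]))


class TestBanavarFlow:
    def test_chain_three_nodes(self):
        net = banavar_flow(chain_tree(3))
        np.testing.assert_allclose(throughflow(net), [3, 2, 1])
        np.testing.assert_allclose(impact(net), [6, 3, 1])

    def test_star_two_leaves(self):
        net = banavar_flow(star_tree(2))
        np.testing.assert_allclose(throughflow(net), [3, 1, 1])
        np.testing.assert_allclose(impact(net), [5, 1, 1])

    def test_single_node(self):
        net = banavar_flow(chain_tree(1))
        np.testing.assert_allclose(throughflow(net), [1])
        np.testing.assert_allclose(impact(net), [1])

    def test_exactly_balanced_and_matches_subtree_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            tree = TreeSpec(
                np.concatenate([[-1], [rng.integers(0, i) for i in range(1, 15)]]),
                consumption=rng.uniform(0.5, 3.0, 15),
            )
            net = banavar_flow(tree)
            assert check_balance(net, rel_tol=1e-12).balanced
            np.testing.assert_allclose(impact(net), subtree_impact(tree), atol=1e-9)


class TestNicheWeb:
    def test_deterministic_under_seed(self):
        p = NicheParams(30, 0.12, seed=5)
        np.testing.assert_array_equal(niche_web(p), niche_web(p))

    def test_source_and_sink_attachment(self):
        adj = niche_web(NicheParams(30, 0.12, seed=5))
        S = 30
        assert adj[0, 1 : S + 1].any()  # basal species fed by the source
        assert adj[1 : S + 1, S + 1].all()  # everyone dissipates
        assert _all_reachable(adj, S)

    def test_realized_connectance(self):
        target, S, reps = 0.1, 50, 200
        vals = np.array(
            [
                np.count_nonzero(niche_web(NicheParams(S, target, seed=k))[1 : S + 1, 1 : S + 1])
                / S**2
                for k in range(reps)
            ]
        )
        se = vals.std(ddof=1) / np.sqrt(reps)
        assert abs(vals.mean() - target) < 3 * se

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            NicheParams(1, 0.1)
        with pytest.raises(ValueError):
            NicheParams(10, 0.6)


class TestAssignRandomFlows:
    def test_fluxes_in_half_open_interval(self):
        adj = niche_web(NicheParams(40, 0.15, seed=2))
        net = assign_random_flows(adj, f_max=3.0, seed=7)
        w = net.flux[net.flux > 0]
        assert np.all(w > 0) and np.all(w <= 3.0)
        # edge set identical to the adjacency
        np.testing.assert_array_equal(net.flux > 0, adj)

    def test_uniform_mean(self):
        adj = np.zeros((102, 102), dtype=bool)
        adj[0, 1:101] = True  # 100 source edges
        adj[1:101, 101] = True  # 100 sink edges
        adj[1:101, 1:101] = ~np.eye(100, dtype=bool)  # 9900 living edges
        net = assign_random_flows(adj, f_max=2.0, seed=0)
        w = net.flux[net.flux > 0]
        se = 2.0 / np.sqrt(12) / np.sqrt(w.size)
        assert abs(w.mean() - 1.0) < 3 * se

    def test_seed_reproducibility(self):
        adj = niche_web(NicheParams(20, 0.15, seed=1))
        a = assign_random_flows(adj, seed=9).flux
        b = assign_random_flows(adj, seed=9).flux
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def source_web():
    adj = niche_web(NicheParams(40, 0.12, seed=21))
    return assign_random_flows(adj, f_max=5.0, seed=22)


class TestNullModels:
    def test_shuffle_preserves_weight_multiset(self, source_web):
        nul = null_model(source_web, "shuffle_weights", seed=3)
        np.testing.assert_allclose(
            np.sort(nul.flux[nul.flux > 0]), np.sort(source_web.flux[source_web.flux > 0])
        )
        np.testing.assert_array_equal(nul.flux > 0, source_web.flux > 0)

    def test_topology_mode_preserves_zero_pattern(self, source_web):
        nul = null_model(source_web, "topology_random_weights", seed=3)
        np.testing.assert_array_equal(nul.flux > 0, source_web.flux > 0)
        assert not np.allclose(nul.flux, source_web.flux)

    def test_rewire_preserves_counts(self, source_web):
        nul = null_model(source_web, "rewire_random_weights", seed=3)
        assert nul.n_living == source_web.n_living
        liv = source_web.living
        assert np.count_nonzero(nul.flux[liv, liv]) == np.count_nonzero(
            source_web.flux[liv, liv]
        )
        # boundary attachments survive as edges
        np.testing.assert_array_equal(
            nul.flux[0] > 0, source_web.flux[0] > 0
        )

    def test_weights_bounded_by_original_max(self, source_web):
        f_max = source_web.flux.max()
        for mode in NULL_MODES:
            nul = null_model(source_web, mode, seed=5)
            assert nul.flux.max() <= f_max

    def test_rewire_degrades_allometric_fit(self):
        """Randomizing structure+weights destroys the allometric regression."""
        from enaflow import FAAConfig, allometry_exponent, faa_adjust

        adj = niche_web(NicheParams(50, 0.1, seed=7))
        raw = assign_random_flows(adj, seed=8)
        res = faa_adjust(balance(raw, "average"), FAAConfig(beta=0.9))
        assert res.converged
        src_r2 = allometry_exponent(res.network).r_squared
        r2s = [
            allometry_exponent(
                balance(null_model(res.network, "rewire_random_weights", seed=k), "naive")
            ).r_squared
            for k in range(50)
        ]
        assert np.median(r2s) < src_r2
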