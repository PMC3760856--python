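"""Throughflow, Markov system, impact variants and the random-walk oracle."""

import numpy as np
import pytest

from enaflow import (
    FlowNetwork,
    banavar_flow,
    dissipation,
    impact,
    markov_system,
    mc_fundamental,
    node_table,
    random_tree,
    subtree_impact,
    throughflow,
)
from conftest import random_balanced_web


class TestThroughflow:
    def test_tree(self, tree_net):
        np.testing.assert_allclose(throughflow(tree_net), [10, 6])

    def test_cycle(self, cycle_net):
        np.testing.assert_allclose(throughflow(cycle_net), [10, 6])

    def test_self_loop_counts_on_both_sides(self):
        net = FlowNetwork(
            ["a"], np.array([[0, 10, 0], [0, 2, 10], [0, 0, 0]], dtype=float)
        )
        np.testing.assert_allclose(throughflow(net), [12])

    def test_rejects_unbalanced(self):
        net = FlowNetwork(
            ["a"], np.array([[0, 10, 0], [0, 0, 7], [0, 0, 0]], dtype=float)
        )
        with pytest.raises(ValueError, match="not balanced"):
            throughflow(net)

    def test_rejects_unreachable_node(self):
        # b exchanges nothing: zero throughflow must name it
        net = FlowNetwork(
            ["a", "b"],
            np.array(
                [[0, 3, 0, 0], [0, 0, 0, 3], [0, 0, 0, 0], [0, 0, 0, 0]], dtype=float
            ),
        )
        with pytest.raises(ValueError, match="b"):
            throughflow(net)


class TestMarkovSystem:
    def test_tree_fundamental_matrix(self, tree_net):
        sys = markov_system(tree_net)
        np.testing.assert_allclose(sys.M, [[0, 0.6], [0, 0]])
        np.testing.assert_allclose(sys.N, [[1, 0.6], [0, 1]])

    def test_cycle_fundamental_matrix(self, cycle_net):
        sys = markov_system(cycle_net)
        np.testing.assert_allclose(sys.M, [[0, 0.6], [1 / 3, 0]])
        np.testing.assert_allclose(
            sys.N, [[1.25, 0.75], [1 / 3 / 0.8, 1.25]], atol=1e-12
        )

    def test_all_direct_to_sink_gives_identity(self):
        net = FlowNetwork(
            ["a", "b"],
            np.array(
                [[0, 2, 3, 0], [0, 0, 0, 2], [0, 0, 0, 3], [0, 0, 0, 0]], dtype=float
            ),
        )
        np.testing.assert_array_equal(markov_system(net).N, np.eye(2))

    def test_non_dissipative_component_rejected(self):
        # b<->c recirculate forever and never reach the sink
        net = FlowNetwork(
            ["a", "b", "c"],
            np.array(
                [
                    [0, 1, 0, 0, 0],
                    [0, 0, 0, 0, 1],
                    [0, 0, 0, 5, 0],
                    [0, 0, 5, 0, 0],
                    [0, 0, 0, 0, 0],
                ],
                dtype=float,
            ),
        )
        with pytest.raises(ValueError, match="non-dissipative"):
            markov_system(net)


class TestImpact:
    def test_tree_equals_subtree_sums(self, tree_net):
        np.testing.assert_allclose(impact(tree_net), [16, 6])
        np.testing.assert_allclose(impact(tree_net, "labeled_particles"), [16, 6])

    def test_cycle_expected_flux(self, cycle_net):
        np.testing.assert_allclose(impact(cycle_net), [20, 10])

    def test_cycle_labeled_particles(self, cycle_net):
        np.testing.assert_allclose(impact(cycle_net, "labeled_particles"), [16, 8])

    def test_unknown_variant(self, tree_net):
        with pytest.raises(ValueError, match="variant"):
            impact(tree_net, "bogus")

    @pytest.mark.parametrize("seed", range(5))
    def test_impact_dominates_throughflow(self, seed):
        net = random_balanced_web(seed=seed)
        A = throughflow(net)
        for variant in ("expected_flux", "labeled_particles"):
            C = impact(net, variant)
            assert np.all(C >= A - 1e-9 * A)

    @pytest.mark.parametrize("seed", range(5))
    def test_variants_agree_on_trees_and_match_oracle(self, seed):
        tree = random_tree(30, seed=seed)
        net = banavar_flow(tree)
        expected = subtree_impact(tree)
        np.testing.assert_allclose(impact(net, "expected_flux"), expected, atol=1e-9)
        np.testing.assert_allclose(
            impact(net, "labeled_particles"), expected, atol=1e-9
        )

    def test_conservation(self):
        net = random_balanced_web(seed=11)
        assert net.total_input() == pytest.approx(net.total_output(), rel=1e-9)


class TestDissipation:
    def test_reads_sink_column(self, tree_net):
        np.testing.assert_allclose(dissipation(tree_net), [4, 6])

    def test_zero_for_missing_sink_edge(self):
        net = FlowNetwork(
            ["a", "b"],
            np.array(
                [[0, 5, 0, 0], [0, 0, 5, 0], [0, 0, 0, 5], [0, 0, 0, 0]], dtype=float
            ),
        )
        np.testing.assert_array_equal(dissipation(net), [0, 5])


class TestMonteCarloOracle:
    def test_identity_chain_is_exact(self):
        net = FlowNetwork(
            ["a", "b"],
            np.array(
                [[0, 2, 3, 0], [0, 0, 0, 2], [0, 0, 0, 3], [0, 0, 0, 0]], dtype=float
            ),
        )
        np.testing.assert_array_equal(mc_fundamental(net, n_walkers=100), np.eye(2))

    def test_cycle_matches_closed_form(self, cycle_net):
        nhat, se = mc_fundamental(cycle_net, n_walkers=50_000, seed=5, return_se=True)
        N = markov_system(cycle_net).N
        assert np.all(np.abs(nhat - N) <= 4 * se + 1e-12)

    def test_tree_offdiagonal_is_binomial(self, tree_net):
        n = 50_000
        nhat = mc_fundamental(tree_net, n_walkers=n, seed=6)
        se = np.sqrt(0.6 * 0.4 / n)
        assert abs(nhat[0, 1] - 0.6) < 4 * se

    def test_seed_reproducibility(self, cycle_net):
        a = mc_fundamental(cycle_net, n_walkers=1000, seed=42)
        b = mc_fundamental(cycle_net, n_walkers=1000, seed=42)
        np.testing.assert_array_equal(a, b)


def test_node_table(tree_net):
    df = node_table(tree_net)
    assert list(df["node"]) == ["a", "b"]
    np.testing.assert_allclose(df["A"], [10, 6])
    np.testing.assert_allclose(df["C"], [16, 6])
    np.testing.assert_allclose(df["d"], [4, 6])
    assert df.attrs["variant"] == "expected_flux"
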