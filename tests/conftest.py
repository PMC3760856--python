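import numpy as np
import pytest

from enaflow import FlowNetwork


@pytest.fixture
def tree_net() -> FlowNetwork:
    """Acyclic 2-compartment web: in->a:10, a->b:6, a->sink:4, b->sink:6."""
    return FlowNetwork(
        ["a", "b"],
        np.array(
            [
                [0, 10, 0, 0],
                [0, 0, 6, 4],
                [0, 0, 0, 6],
                [0, 0, 0, 0],
            ],
            dtype=float,
        ),
    )


@pytest.fixture
def cycle_net() -> FlowNetwork:
    """Cycle-bearing web: in->a:8, b->a:2, a->b:6, a->sink:4, b->sink:4."""
    return FlowNetwork(
        ["a", "b"],
        np.array(
            [
                [0, 8, 0, 0],
                [0, 0, 6, 4],
                [0, 2, 0, 4],
                [0, 0, 0, 0],
            ],
            dtype=float,
        ),
    )


def random_balanced_web(S: int = 20, connectance: float = 0.15, seed: int = 0):
    """A balanced random-flow niche web, for property tests."""
    from enaflow import NicheParams, assign_random_flows, balance, niche_web

    adj = niche_web(NicheParams(S, connectance, seed=seed))
    return balance(assign_random_flows(adj, seed=seed + 1), "average")
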