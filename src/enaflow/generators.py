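"""Synthetic flow-network generators.

Everything the analysis pipeline consumes can be generated here without any
external data: Banavar-style spanning-tree flow networks (each node draws a
fixed consumption from a root-fed supply), niche-model food webs with random
flow assignment, and the null models (edge rewiring, weight randomization,
weight shuffling) used to test the significance of the scaling laws.

Energy-flow orientation is resource -> consumer throughout: the source feeds
basal species and every compartment loses flux to the sink.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network import FlowNetwork

__all__ = [
    "TreeSpec",
    "chain_tree",
    "star_tree",
    "random_tree",
    "banavar_flow",
    "subtree_impact",
    "NicheParams",
    "niche_web",
    "assign_random_flows",
    "null_model",
    "NULL_MODES",
]

NULL_MODES = ("rewire_random_weights", "topology_random_weights", "shuffle_weights")


@dataclass
class TreeSpec:
    """A rooted tree: ``parent[i]`` is the parent index, -1 marks the root."""

    parent: np.ndarray
    consumption: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        n = self.parent.size
        if self.consumption is None:
            self.consumption = np.ones(n)
        self.consumption = np.asarray(self.consumption, dtype=float)
        if self.consumption.shape != (n,):
            raise ValueError("consumption must match the number of nodes")
        if np.any(self.consumption <= 0):
            raise ValueError("consumption must be positive")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise ValueError("tree must have exactly one root")
        # Walking parent pointers must terminate at the root (acyclicity).
        for i in range(n):
            j, hops = i, 0
            while self.parent[j] >= 0:
                j = self.parent[j]
                hops += 1
                if hops > n:
                    raise ValueError("parent vector contains a cycle")

    @property
    def n(self) -> int:
        return self.parent.size

    def subtree_sums(self, values: np.ndarray) -> np.ndarray:
        """Sum ``values`` over the subtree rooted at each node."""
        values = np.asarray(values, dtype=float)
        order = _topological_order(self.parent)
        total = values.copy()
        for i in reversed(order):  # children before parents
            p = self.parent[i]
            if p >= 0:
                total[p] += total[i]
        return total


def _topological_order(parent: np.ndarray) -> list[int]:
    """Nodes ordered root-first (every parent before its children)."""
    n = parent.size
    children: list[list[int]] = [[] for _ in range(n)]
    root = -1
    for i, p in enumerate(parent):
        if p < 0:
            root = i
        else:
            children[p].append(i)
    order, stack = [], [root]
    while stack:
        i = stack.pop()
        order.append(i)
        stack.extend(children[i])
    return order


def chain_tree(n: int) -> TreeSpec:
    """A path of ``n`` nodes rooted at one end (the least efficient tree)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return TreeSpec(np.arange(-1, n - 1))


def star_tree(k: int) -> TreeSpec:
    """A root with ``k`` leaves (the most efficient tree)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return TreeSpec(np.concatenate([[-1], np.zeros(k, dtype=int)]))


def random_tree(n: int, seed: int = 0) -> TreeSpec:
    """A uniform random recursive tree on ``n`` nodes (node 0 is the root)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    parent = np.full(n, -1, dtype=int)
    for i in range(1, n):
        parent[i] = rng.integers(0, i)
    return TreeSpec(parent)


def banavar_flow(tree: TreeSpec) -> FlowNetwork:
    """Turn a rooted tree into an exactly balanced supply network.

    Each node consumes its ``consumption`` (default one unit) per time step:
    the edge into a node carries the total consumption of its subtree, every
    node dissipates its own consumption to the sink, and the source feeds the
    root with the grand total.  Node throughflow then equals the subtree
    consumption sum, the weighted analogue of the spanning-tree node count.
    """
    n = tree.n
    subtotal = tree.subtree_sums(tree.consumption)
    flux = np.zeros((n + 2, n + 2))
    for i, p in enumerate(tree.parent):
        if p < 0:
            flux[0, i + 1] = subtotal[i]  # source -> root
        else:
            flux[p + 1, i + 1] = subtotal[i]
        flux[i + 1, n + 1] = tree.consumption[i]  # dissipation
    labels = [f"n{i}" for i in range(n)]
    return FlowNetwork(labels, flux, {"generator": "banavar_flow"})


def subtree_impact(tree: TreeSpec) -> np.ndarray:
    """Spanning-tree impact oracle: sum of subtree throughflows.

    The tree-analysis value of C — for each node, the sum of the throughflow
    (subtree consumption total) over every node of its subtree.  The Markov
    impact of :func:`banavar_flow` must reproduce this exactly.
    """
    return tree.subtree_sums(tree.subtree_sums(tree.consumption))


@dataclass
class NicheParams:
    """Niche-model food-web parameters (S species, target connectance E/S^2)."""

    S: int
    connectance: float
    seed: int = 0
    max_retries: int = 1000

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("S must be >= 2")
        if not (0 < self.connectance < 0.5):
            raise ValueError("connectance must be in (0, 0.5)")


def niche_web(params: NicheParams) -> np.ndarray:
    """Generate a niche-model food web as a boolean flow adjacency.

    Each species draws a niche value ``n_i ~ U(0,1)``, a diet-range fraction
    ``x ~ Beta(1, 1/(2C) - 1)`` giving ``r_i = x * n_i``, and a diet centre
    ``~ U(r_i/2, n_i)``; it consumes every species whose niche value falls in
    the diet interval.  The species with the smallest niche value is forced
    basal, duplicate niche values and webs with species unreachable from the
    source are redrawn (bounded retries).

    Returns an ``(S+2, S+2)`` boolean adjacency in FlowNetwork layout: edges
    are oriented prey -> predator, basal species hang off the source, and
    every species is attached to the sink.  Feed it to
    :func:`assign_random_flows` to obtain a weighted network.
    """
    rng = np.random.default_rng(params.seed)
    S, C = params.S, params.connectance
    b = 1.0 / (2.0 * C) - 1.0
    for _ in range(params.max_retries):
        nv = np.sort(rng.uniform(0.0, 1.0, S))
        if np.unique(nv).size < S:
            continue
        x = rng.beta(1.0, b, S)
        r = x * nv
        r[0] = 0.0  # smallest-niche species is basal
        centre = rng.uniform(r / 2.0, np.maximum(nv, r / 2.0 + 1e-12))
        lo, hi = centre - r / 2.0, centre + r / 2.0
        eats = (nv[None, :] >= lo[:, None]) & (nv[None, :] <= hi[:, None])
        eats &= r[:, None] > 0
        # prey j -> predator i
        adj = np.zeros((S + 2, S + 2), dtype=bool)
        adj[1 : S + 1, 1 : S + 1] = eats.T
        basal = ~eats.any(axis=1)
        adj[0, 1 : S + 1] = basal
        adj[1 : S + 1, S + 1] = True
        # every species must take part in the web and be fed from the source
        connected = adj[1 : S + 1, 1 : S + 1].any(axis=0) | basal
        if not connected.all():
            continue
        if _all_reachable(adj, S):
            return adj
    raise RuntimeError(
        f"niche web generation failed after {params.max_retries} retries "
        f"(S={S}, connectance={C}, seed={params.seed})"
    )


def _all_reachable(adj: np.ndarray, S: int) -> bool:
    seen = adj[0, 1 : S + 1].copy()
    frontier = seen.copy()
    inner = adj[1 : S + 1, 1 : S + 1]
    while frontier.any():
        nxt = inner[frontier].any(axis=0) & ~seen
        seen |= nxt
        frontier = nxt
    return bool(seen.all())


def assign_random_flows(adjacency: np.ndarray, f_max: float = 1.0, seed: int = 0) -> FlowNetwork:
    """Draw an independent ``U(0, f_max]`` flux for every edge of ``adjacency``.

    The result is generally *unbalanced*; balance it (or run the flow
    adjusting algorithm) before Markov analysis.
    """
    adjacency = np.asarray(adjacency, dtype=bool)
    if f_max <= 0:
        raise ValueError("f_max must be positive")
    S = adjacency.shape[0] - 2
    rng = np.random.default_rng(seed)
    flux = np.zeros(adjacency.shape)
    ij = np.nonzero(adjacency)
    # 1 - U(0,1) lies in (0, 1]: zero flux would delete the edge.
    flux[ij] = f_max * (1.0 - rng.random(ij[0].size))
    labels = [f"s{i}" for i in range(S)]
    return FlowNetwork(labels, flux, {"generator": "assign_random_flows", "f_max": str(f_max)})


def null_model(net: FlowNetwork, mode: str, seed: int = 0) -> FlowNetwork:
    """Randomized counterpart of ``net`` for significance testing.

    ``rewire_random_weights``
        Keep S and the number of living-living edges; redirect those edges
        uniformly at random (self-loops allowed, multi-edges collapse
        forbidden) and draw all weights ``U(0, f_max]``.
    ``topology_random_weights``
        Keep every edge; redraw all weights ``U(0, f_max]``.
    ``shuffle_weights``
        Keep every edge; permute the existing weights among the edges.

    ``f_max`` is the maximum flux of the original network.  Source/sink
    attachments survive as edges in every mode.  The output is left
    unbalanced on purpose: compute dissipation from it raw, and balance a
    copy before the Markov analysis.
    """
    if mode not in NULL_MODES:
        raise ValueError(f"unknown null mode {mode!r}; use one of {NULL_MODES}")
    rng = np.random.default_rng(seed)
    S = net.n_living
    f_max = float(net.flux.max())
    flux = np.zeros_like(net.flux)
    if mode == "shuffle_weights":
        ij = np.nonzero(net.flux)
        weights = net.flux[ij]
        flux[ij] = rng.permutation(weights)
    elif mode == "topology_random_weights":
        ij = np.nonzero(net.flux)
        flux[ij] = f_max * (1.0 - rng.random(ij[0].size))
    else:  # rewire_random_weights
        inner = net.flux[net.living, net.living]
        n_edges = int(np.count_nonzero(inner))
        if n_edges > S * S:
            raise ValueError("more living edges than slots")
        # sample distinct (i, j) slots uniformly
        slots = rng.choice(S * S, size=n_edges, replace=False)
        new_inner = np.zeros((S, S), dtype=bool)
        new_inner[np.unravel_index(slots, (S, S))] = True
        flux[net.living, net.living] = new_inner * (f_max * (1.0 - rng.random((S, S))))
        src = net.flux[net.source, net.living] > 0
        snk = net.flux[net.living, net.sink] > 0
        flux[net.source, net.living] = src * (f_max * (1.0 - rng.random(S)))
        flux[net.living, net.sink] = snk * (f_max * (1.0 - rng.random(S)))
    meta = dict(net.meta)
    meta.update(null_mode=mode, null_seed=str(seed))
    return FlowNetwork(list(net.labels), flux, meta)
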