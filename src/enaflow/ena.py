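"""Ecological network analysis core: throughflow, impact and dissipation.

A balanced flow network induces an absorbing Markov chain: a particle at
compartment ``i`` moves to compartment ``j`` with probability
``m_ij = f_ij / A_i`` (donor-normalized) and is absorbed by the sink with the
row-sum deficit ``f_i,sink / A_i``.  The fundamental matrix
``N = (I - M)^{-1}`` gives the expected number of visits ``n_ij`` to ``j`` of
a particle currently at ``i`` before absorption; from it the *impact*
``C_i`` — the total direct plus indirect flux influence of compartment ``i``
on the whole network — follows in closed form.  A brute-force random-walk
simulator of the same chain is provided as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .network import FlowNetwork, check_balance

__all__ = [
    "throughflow",
    "markov_system",
    "MarkovSystem",
    "impact",
    "dissipation",
    "mc_fundamental",
    "node_table",
    "IMPACT_VARIANTS",
]

IMPACT_VARIANTS = ("expected_flux", "labeled_particles")


def throughflow(net: FlowNetwork, rel_tol: float = 1e-6) -> np.ndarray:
    """Per-compartment throughflow ``A_i``: total inflow, source included.

    On a balanced network this equals the total outflow.  Raises if the
    network is not balanced at ``rel_tol`` or if any compartment has zero
    throughflow (it would be unreachable and the Markov normalization would
    divide by zero).
    """
    report = check_balance(net, rel_tol=rel_tol)
    if not report.balanced:
        raise ValueError(
            f"network is not balanced (max relative residual "
            f"{report.max_rel_residual:.3e} > {rel_tol:g}); balance it first"
        )
    A = net.inflows()
    if np.any(A <= 0):
        dead = [net.labels[i] for i in np.flatnonzero(A <= 0)]
        raise ValueError(f"zero throughflow (unreachable compartments): {dead}")
    return A


@dataclass
class MarkovSystem:
    """Absorbing-chain view of a balanced flow network."""

    M: np.ndarray  #: living-to-living transition probabilities (substochastic)
    N: np.ndarray  #: fundamental matrix (I - M)^{-1}
    absorbing_ok: bool  #: every compartment can reach the sink

    @property
    def sink_probability(self) -> np.ndarray:
        """Per-compartment one-step absorption probability (row-sum deficit)."""
        return 1.0 - self.M.sum(axis=1)


def markov_system(net: FlowNetwork, rel_tol: float = 1e-6) -> MarkovSystem:
    """Build the substochastic matrix ``M`` and fundamental matrix ``N``.

    ``m_ij = f_ij / A_i`` for living ``i, j`` (self-loops kept); ``N`` solves
    ``(I - M) N = I``.  Raises on a non-dissipative component (spectral radius
    of ``M`` at or above 1: some compartment cannot reach the sink) and on an
    ill-conditioned ``I - M``.
    """
    A = throughflow(net, rel_tol=rel_tol)
    F = net.flux[net.living, net.living]
    M = F / A[:, None]
    rho = float(np.max(np.abs(np.linalg.eigvals(M)))) if M.size else 0.0
    if rho >= 1.0 - 1e-12:
        raise ValueError(
            f"non-dissipative component: spectral radius of M is {rho:.6f}; "
            "some compartment cannot reach the sink"
        )
    I = np.eye(M.shape[0])
    cond = np.linalg.cond(I - M)
    if not np.isfinite(cond) or cond > 1.0 / np.finfo(float).eps:
        raise ValueError(f"(I - M) is ill-conditioned (cond={cond:.3e})")
    N = scipy.linalg.solve(I - M, I)
    return MarkovSystem(M=M, N=N, absorbing_ok=True)


def impact(
    net: FlowNetwork, variant: str = "expected_flux", rel_tol: float = 1e-6
) -> np.ndarray:
    """Total direct + indirect impact ``C_i`` of each compartment.

    ``expected_flux`` (default)
        ``C_i = A_i * sum_j n_ij`` — the expected flux, over all pathways,
        reaching any compartment downstream of ``i`` (multiple passes through
        a cycle all count).  On trees this is exactly the subtree throughflow
        sum of the spanning-tree analysis.
    ``labeled_particles``
        ``C_i = (A_i / n_ii) * sum_j n_ij`` — counts each particle that ever
        passed ``i`` once, correcting by the expected number of returns
        ``n_ii``; differs from ``expected_flux`` only on cycle-bearing
        networks (``n_ii > 1``).
    """
    if variant not in IMPACT_VARIANTS:
        raise ValueError(f"unknown impact variant {variant!r}; use one of {IMPACT_VARIANTS}")
    A = throughflow(net, rel_tol=rel_tol)
    N = markov_system(net, rel_tol=rel_tol).N
    C = A * N.sum(axis=1)
    if variant == "labeled_particles":
        C = C / np.diag(N)
    return C


def dissipation(net_original: FlowNetwork) -> np.ndarray:
    """Dissipative flux ``d_i``: the flow from ``i`` to the sink.

    Must be read from the *original* (pre-balancing) matrix — artificial
    balancing rewrites sink edges.  Zeros are allowed; the scaling fit
    excludes them.
    """
    return net_original.flux[net_original.living, net_original.sink].copy()


def mc_fundamental(
    net: FlowNetwork,
    n_walkers: int = 10_000,
    seed: int = 0,
    max_steps: int = 1_000_000,
    return_se: bool = False,
):
    """Monte-Carlo estimate of the fundamental matrix by random walks.

    For each living compartment ``i``, ``n_walkers`` particles start at ``i``
    and hop under ``M`` until absorbed by the sink; ``nhat[i, j]`` is the mean
    number of visits to ``j`` per walk (the start counts as a visit, so
    ``nhat[i, i] >= 1``).  With ``return_se=True`` also returns the matrix of
    standard errors of those means.  This is a brute-force oracle for
    ``N = (I - M)^{-1}``, deterministic under a fixed ``seed``.
    """
    sys = markov_system(net)
    M = sys.M
    S = M.shape[0]
    rng = np.random.default_rng(seed)
    # Cumulative transition table; last column accumulates absorption.
    cum = np.cumsum(np.hstack([M, sys.sink_probability[:, None]]), axis=1)
    cum[:, -1] = 1.0
    nhat = np.empty((S, S))
    se = np.empty((S, S))
    for start in range(S):
        visits = np.zeros((n_walkers, S), dtype=np.int64)
        visits[:, start] = 1
        state = np.full(n_walkers, start, dtype=np.intp)
        alive = np.arange(n_walkers)
        steps = 0
        while alive.size:
            steps += 1
            if steps > max_steps:
                raise RuntimeError(
                    "walk length exceeded cap: suspected non-absorbing chain"
                )
            u = rng.random(alive.size)
            nxt = (u[:, None] > cum[state]).sum(axis=1)
            absorbed = nxt == S
            survivors = ~absorbed
            alive = alive[survivors]
            state = nxt[survivors]
            np.add.at(visits, (alive, state), 1)
        nhat[start] = visits.mean(axis=0)
        se[start] = visits.std(axis=0, ddof=1) / np.sqrt(n_walkers)
    return (nhat, se) if return_se else nhat


def node_table(
    net_balanced: FlowNetwork,
    net_original: FlowNetwork | None = None,
    variant: str = "expected_flux",
    rel_tol: float = 1e-6,
):
    """Per-node results table (pandas DataFrame): node, A, C, d.

    ``d`` is read from ``net_original`` when given (the pre-balancing matrix),
    otherwise from ``net_balanced``.  Use ``to_csv(sep='\\t')`` for the TSV
    report; variant and tolerance are stored in ``df.attrs``.
    """
    import pandas as pd

    A = throughflow(net_balanced, rel_tol=rel_tol)
    C = impact(net_balanced, variant=variant, rel_tol=rel_tol)
    d = dissipation(net_original if net_original is not None else net_balanced)
    df = pd.DataFrame({"node": net_balanced.labels, "A": A, "C": C, "d": d})
    df.attrs["variant"] = variant
    df.attrs["rel_tol"] = rel_tol
    return df
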