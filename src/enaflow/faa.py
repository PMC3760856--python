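"""Flow Adjusting Algorithm (FAA).

Given a balanced flow network, the FAA perturbs edge fluxes — keeping the
topology and every node's *influx ratios* fixed — until each living node
obeys a prescribed dissipation law ``d_i = c * A_i^beta`` while restoring the
per-node flow balance.  Each worklist step solves the scalar fixed-point
equation

    x = (outflow to living nodes) + c * x**beta

for the node's new total influx ``x``, rescales the node's incoming edges
proportionally, and writes the implied sink flux ``c * x**beta``; changed
nodes push their upstream neighbours back onto the worklist.  The sweep
stops when a fresh global fit of the dissipation law on the adjusted matrix
reaches the target exponent and goodness of fit, or when the worklist goes
quiet.  On some topologies (notably random webs) the iteration can
oscillate; a damping factor and an oscillation detector are provided, and a
non-converged run returns diagnostics instead of raising.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .network import FlowNetwork, check_balance
from .scaling import ScalingFit, dissipation_exponent

__all__ = ["FAAConfig", "FAAResult", "node_influx_solve", "faa_adjust", "fit_prefactor"]


@dataclass
class FAAConfig:
    """Tuning knobs of the Flow Adjusting Algorithm.

    ``beta`` is the target dissipation exponent; ``c`` the dissipation
    prefactor, or ``"fit-from-original"`` to use the least-squares intercept
    at fixed slope ``beta`` (keeps the adjusted network near the original
    scale).  ``damping`` < 1 mixes the old influx into each update to break
    oscillations; ``seed`` enables shuffling of the worklist order between
    sweeps.
    """

    beta: float
    c: float | str = "fit-from-original"
    max_sweeps: int = 500
    beta_tol: float = 0.01
    r2_min: float = 0.99
    root_tol: float = 1e-10
    damping: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.beta_tol <= 0 or self.root_tol <= 0:
            raise ValueError("beta_tol and root_tol must be positive")
        if not (0 < self.r2_min <= 1):
            raise ValueError("r2_min must be in (0, 1]")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must be in (0, 1]")
        if not isinstance(self.c, str) and self.c <= 0:
            raise ValueError("c must be positive")


@dataclass
class FAAResult:
    """Adjusted network plus convergence diagnostics."""

    network: FlowNetwork
    converged: bool
    sweeps: int
    achieved_beta: float
    achieved_r2: float
    max_balance_residual: float
    c: float = float("nan")
    history: list = field(default_factory=list, repr=False)


def node_influx_solve(out_to_living: float, c: float, beta: float,
                      root_tol: float = 1e-12) -> float:
    """Solve ``x = out_to_living + c * x**beta`` for the new node influx.

    For ``beta < 1`` the positive root is unique.  For ``beta > 1`` there may
    be zero, one or two positive roots; the smallest is returned, and a
    missing root raises (the dissipation target is infeasible for that node).
    ``beta = 1`` degenerates to a linear equation.
    """
    if out_to_living < 0:
        raise ValueError("out_to_living must be nonnegative")
    if c < 0:
        raise ValueError("c must be nonnegative")
    out = float(out_to_living)
    if c == 0.0:
        if out <= 0:
            raise ValueError("no dissipation and no living outflow: influx is zero")
        return out
    if beta == 0.0:
        return out + c
    if beta == 1.0:
        if c >= 1.0:
            raise ValueError("dissipation target infeasible: beta=1 with c >= 1")
        if out <= 0:
            raise ValueError(
                "terminal node unsolvable at beta=1: only x=0 satisfies the law; "
                "use beta != 1 or add a living outflow"
            )
        return out / (1.0 - c)

    def g(x: float) -> float:
        return x - c * x**beta - out

    if beta < 1.0:
        # g is eventually increasing and g(0+) <= 0: unique positive root.
        if out <= 0:
            return c ** (1.0 / (1.0 - beta))
        lo = out  # g(out) = -c*out**beta < 0
        hi = max(out, 1.0)
        while g(hi) < 0:
            hi *= 2.0
    else:
        # beta > 1: h(x) = c x^beta + out - x has a single interior minimum.
        x_star = (1.0 / (c * beta)) ** (1.0 / (beta - 1.0))
        if out <= 0:
            return c ** (1.0 / (1.0 - beta))
        if g(x_star) < 0:
            raise ValueError(
                "dissipation target infeasible: no positive root for "
                f"beta={beta}, c={c}, out={out}"
            )
        lo, hi = out, x_star  # g(out) < 0 <= g(x_star); smallest root in between
        if g(lo) > 0:  # numerically already past the root
            return lo
    root = optimize.brentq(g, lo, hi, xtol=1e-12 * max(1.0, hi), rtol=8.9e-16)
    # Newton polish to machine precision so the restored balance is exact.
    for _ in range(3):
        slope = 1.0 - c * beta * root ** (beta - 1.0)
        if slope == 0.0:
            break
        step = g(root) / slope
        if not np.isfinite(step):
            break
        nxt = root - step
        if nxt <= 0:
            break
        root = nxt
    return float(root)


def fit_prefactor(net: FlowNetwork, beta: float) -> float:
    """Least-squares dissipation prefactor at fixed slope ``beta``.

    ``c = 10**mean(log10 d_i - beta*log10 A_i)`` over nodes with ``d_i > 0``:
    the log-intercept that best matches the original network's scale.
    """
    A = net.inflows()
    d = net.flux[net.living, net.sink]
    keep = (d > 0) & (A > 0)
    if not np.any(keep):
        raise ValueError("cannot fit prefactor: no positive dissipation values")
    return float(10.0 ** np.mean(np.log10(d[keep]) - beta * np.log10(A[keep])))


def _reachable_from_source(net: FlowNetwork) -> np.ndarray:
    S = net.n_living
    adj = net.flux[: S + 1, 1 : S + 1] > 0
    seen = np.zeros(S, dtype=bool)
    frontier = np.flatnonzero(adj[0])
    seen[frontier] = True
    while frontier.size:
        nxt = np.flatnonzero(adj[1:][frontier].any(axis=0) & ~seen)
        seen[nxt] = True
        frontier = nxt
    return seen


def faa_adjust(net: FlowNetwork, config: FAAConfig) -> FAAResult:
    """Impose the dissipation law ``d_i = c * A_i^beta`` on a balanced network.

    Returns an :class:`FAAResult`; ``converged`` requires the freshly fitted
    dissipation exponent within ``beta_tol`` of ``beta``, its r-squared at
    least ``r2_min``, and a maximum relative balance residual below 1e-6.
    Oscillating runs return ``converged=False`` with the sweep history rather
    than raising.
    """
    report = check_balance(net, rel_tol=1e-6)
    if not report.balanced:
        raise ValueError("FAA requires a balanced input network; call balance() first")
    reachable = _reachable_from_source(net)
    if not reachable.all():
        bad = [net.labels[i] for i in np.flatnonzero(~reachable)]
        raise ValueError(f"FAA requires source-connectivity; unreachable: {bad}")

    c = fit_prefactor(net, config.beta) if isinstance(config.c, str) else float(config.c)
    S = net.n_living
    F = net.flux.copy()
    sink = S + 1
    rng = np.random.default_rng(config.seed) if config.seed is not None else None

    # Backward initialization: the law's inputs are immediately meaningful only
    # at nodes feeding the sink; updates then propagate upstream.
    worklist = deque(i for i in range(1, S + 1) if F[i, sink] > 0)
    in_list = set(worklist)
    upstream = [np.flatnonzero(net.flux[1 : S + 1, i] > 0) + 1 for i in range(1, S + 1)]

    history: list[tuple[float, float, float]] = []
    sweeps = 0
    while sweeps < config.max_sweeps and worklist:
        sweeps += 1
        if rng is not None and len(worklist) > 1:
            order = list(worklist)
            rng.shuffle(order)
            worklist = deque(order)
        for _ in range(len(worklist)):
            i = worklist.popleft()
            in_list.discard(i)
            out_living = float(F[i, 1 : S + 1].sum())
            inflow = float(F[: S + 1, i].sum())
            x = node_influx_solve(out_living, c, config.beta, root_tol=config.root_tol)
            if config.damping < 1.0:
                x = (1.0 - config.damping) * inflow + config.damping * x
            if inflow <= 0:
                raise RuntimeError(f"node {net.labels[i - 1]} lost all inflow")
            scale = x / inflow
            F[: S + 1, i] *= scale  # preserves influx ratios exactly
            F[i, sink] = c * x**config.beta
            if abs(scale - 1.0) > config.root_tol:
                for j in upstream[i - 1]:
                    if j not in in_list:
                        worklist.append(j)
                        in_list.add(j)
        adjusted = FlowNetwork(list(net.labels), F.copy(), dict(net.meta))
        fit = dissipation_exponent(adjusted)
        residual = check_balance(adjusted, rel_tol=1e-6)
        history.append((fit.exponent, fit.r_squared, residual.max_rel_residual))
        ok = (
            abs(fit.exponent - config.beta) <= config.beta_tol
            and fit.r_squared >= config.r2_min
            and residual.max_rel_residual <= 1e-6
        )
        if ok and not worklist:
            break
        if _oscillating(history):
            break

    adjusted = FlowNetwork(list(net.labels), F, dict(net.meta))
    adjusted.meta.update(faa_beta=f"{config.beta:g}", faa_c=f"{c:.17g}")
    fit = dissipation_exponent(adjusted)
    residual = check_balance(adjusted, rel_tol=1e-6)
    converged = (
        abs(fit.exponent - config.beta) <= config.beta_tol
        and fit.r_squared >= config.r2_min
        and residual.max_rel_residual <= 1e-6
    )
    return FAAResult(
        network=adjusted,
        converged=converged,
        sweeps=sweeps,
        achieved_beta=fit.exponent,
        achieved_r2=fit.r_squared,
        max_balance_residual=residual.max_rel_residual,
        c=c,
        history=history,
    )


def _oscillating(history: list, window: int = 20) -> bool:
    """Residuals cycling without improvement over two consecutive windows."""
    if len(history) < 2 * window:
        return False
    res = np.asarray([h[2] for h in history])
    recent = res[-window:].min()
    previous = res[-2 * window : -window].min()
    return recent >= previous * (1 - 1e-9)
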