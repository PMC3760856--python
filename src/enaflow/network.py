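"""Weighted directed flow networks with explicit source and sink compartments.

A flow network here is a steady-state energy (or nutrient) budget: living and
non-living compartments exchange flux, a fictitious *source* compartment feeds
the system (environmental input) and a fictitious *sink* compartment absorbs
all losses (respiration plus export).  The container stores the full
``(S+2) x (S+2)`` flux matrix with the source at index 0 and the sink at index
``S+1``; all analysis routines in :mod:`enaflow` operate on this object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FlowNetwork",
    "BalanceReport",
    "check_balance",
    "balance",
    "BALANCE_METHODS",
]

#: Methods accepted by :func:`balance`.
BALANCE_METHODS = ("naive", "input", "output", "average")


@dataclass
class FlowNetwork:
    """A weighted directed flow network with boundary compartments.

    Parameters
    ----------
    labels :
        Names of the ``S`` living (or non-living, e.g. detritus) compartments,
        in matrix order.  Source and sink are implicit.
    flux :
        ``(S+2, S+2)`` nonnegative matrix; ``flux[i, j]`` is the flow from
        compartment ``i`` to ``j`` in the network's (arbitrary but internally
        consistent) energy-flow units.  Row/column 0 is the source, row/column
        ``S+1`` the sink.  Diagonal entries on living compartments
        (cannibalism / self-loops) are permitted.
    meta :
        Free-form provenance map (habitat, units, balancing method used, ...).
    """

    labels: list[str]
    flux: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flux = np.asarray(self.flux, dtype=float)
        self.labels = list(self.labels)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_living(self) -> int:
        """Number of living/non-living compartments S (boundary excluded)."""
        return len(self.labels)

    @property
    def source(self) -> int:
        return 0

    @property
    def sink(self) -> int:
        return self.n_living + 1

    @property
    def living(self) -> slice:
        """Index slice selecting the living compartments."""
        return slice(1, self.n_living + 1)

    def validate(self) -> None:
        S = self.n_living
        if S < 1:
            raise ValueError("flow network needs at least one living compartment")
        if len(set(self.labels)) != S:
            raise ValueError("compartment labels must be unique")
        if self.flux.shape != (S + 2, S + 2):
            raise ValueError(
                f"flux matrix must be {(S + 2, S + 2)} for {S} compartments, "
                f"got {self.flux.shape}"
            )
        if not np.all(np.isfinite(self.flux)):
            raise ValueError("flux matrix contains non-finite entries")
        if np.any(self.flux < 0):
            raise ValueError("flux entries must be nonnegative")
        if np.any(self.flux[self.sink, :] > 0):
            raise ValueError("sink is absorbing: flux out of the sink is forbidden")
        if np.any(self.flux[:, self.source] > 0):
            raise ValueError("source only emits: flux into the source is forbidden")
        if not np.any(self.flux[self.source, self.living] > 0):
            raise ValueError("network has no input: some source flux must be positive")

    # -- per-node budgets --------------------------------------------------

    def inflows(self) -> np.ndarray:
        """Total inflow of each living compartment (source included)."""
        return self.flux[: self.sink, self.living].sum(axis=0)

    def outflows(self) -> np.ndarray:
        """Total outflow of each living compartment (sink included)."""
        return self.flux[self.living, 1:].sum(axis=1)

    def total_input(self) -> float:
        """Total boundary input (source outflow)."""
        return float(self.flux[self.source, :].sum())

    def total_output(self) -> float:
        """Total boundary loss (sink inflow)."""
        return float(self.flux[:, self.sink].sum())

    def n_edges(self) -> int:
        """Number of positive-flux edges, boundary attachments included."""
        return int(np.count_nonzero(self.flux > 0))

    def copy(self) -> "FlowNetwork":
        return FlowNetwork(list(self.labels), self.flux.copy(), dict(self.meta))

    def index_of(self, label: str) -> int:
        """Matrix index of a living compartment by name."""
        try:
            return self.labels.index(label) + 1
        except ValueError:
            raise KeyError(f"unknown compartment {label!r}") from None


@dataclass
class BalanceReport:
    """Steady-state check: inflow minus outflow per living compartment."""

    residual: np.ndarray
    max_rel_residual: float
    balanced: bool
    rel_tol: float


def check_balance(net: FlowNetwork, rel_tol: float = 1e-6) -> BalanceReport:
    """Check the steady-state (flow balance) condition.

    For every living compartment the inflow must equal the outflow.  The
    residual is ``inflow_i - outflow_i``; relative residuals are taken against
    the compartment throughflow (its inflow) so that networks whose fluxes
    span orders of magnitude are judged fairly.
    """
    inflow = net.inflows()
    outflow = net.outflows()
    residual = inflow - outflow
    denom = np.maximum(np.maximum(inflow, outflow), 1e-30)
    max_rel = float(np.max(np.abs(residual) / denom)) if len(residual) else 0.0
    return BalanceReport(residual, max_rel, max_rel <= rel_tol, rel_tol)


def _balance_naive(net: FlowNetwork) -> FlowNetwork:
    # Surplus inflow is dumped to the sink; deficit is drawn from the source.
    out = net.copy()
    residual = out.inflows() - out.outflows()
    liv = np.arange(1, out.sink)
    surplus = residual > 0
    out.flux[liv[surplus], out.sink] += residual[surplus]
    out.flux[out.source, liv[~surplus]] += -residual[~surplus]
    return out


def _living_proportions(flux: np.ndarray, axis_sums: np.ndarray, S: int, rows: bool):
    if rows:
        return flux[1 : S + 1, 1:] / axis_sums[:, None]
    return flux[: S + 1, 1 : S + 1] / axis_sums[None, :]


def _balance_input(net: FlowNetwork) -> FlowNetwork:
    # Keep source inputs and each node's outflow *proportions* fixed; solve the
    # unique throughflow vector A with A = s + P^T A, then rescale outflow rows.
    S = net.n_living
    outflow = net.outflows()
    inflow = net.inflows()
    bad = (outflow <= 0) & (inflow > 0)
    if np.any(bad):
        names = [net.labels[i] for i in np.flatnonzero(bad)]
        raise ValueError(
            f"input balancing impossible: zero outflow with positive inflow at {names}"
        )
    safe_out = np.where(outflow > 0, outflow, 1.0)
    P = _living_proportions(net.flux, safe_out, S, rows=True)  # (S, S+1): living+sink
    P_ll = P[:, :S]  # living -> living shares
    s = net.flux[net.source, net.living]
    A = np.linalg.solve(np.eye(S) - P_ll.T, s)
    out = net.copy()
    out.flux[net.living, 1:] = A[:, None] * P
    return out


def _balance_output(net: FlowNetwork) -> FlowNetwork:
    # Keep sink losses and each node's inflow *proportions* fixed; solve the
    # throughflow vector B with B = d + Q B, then rescale inflow columns.
    S = net.n_living
    inflow = net.inflows()
    outflow = net.outflows()
    bad = (inflow <= 0) & (outflow > 0)
    if np.any(bad):
        names = [net.labels[i] for i in np.flatnonzero(bad)]
        raise ValueError(
            f"output balancing impossible: zero inflow with positive outflow at {names}"
        )
    safe_in = np.where(inflow > 0, inflow, 1.0)
    Q = _living_proportions(net.flux, safe_in, S, rows=False)  # (S+1, S): source+living
    Q_ll = Q[1:, :]  # living -> living shares of the receiver's inflow
    d = net.flux[net.living, net.sink]
    B = np.linalg.solve(np.eye(S) - Q_ll, d)
    out = net.copy()
    out.flux[: S + 1, net.living] = Q * B[None, :]
    return out


def _balance_average(
    net: FlowNetwork, rel_tol: float = 1e-11, max_iter: int = 100_000
) -> FlowNetwork:
    # Two-sided multiplicative rescaling toward the mean of inflow and outflow.
    # Each iteration scales living rows by sqrt(target/outflow) and living
    # columns by sqrt(target/inflow) (Sinkhorn-style), which leaves balanced
    # networks fixed and converges linearly on dissipative networks.
    out = net.copy()
    S = net.n_living
    for _ in range(max_iter):
        inflow = out.inflows()
        outflow = out.outflows()
        denom = np.maximum(np.maximum(inflow, outflow), 1e-30)
        if np.max(np.abs(inflow - outflow) / denom) <= rel_tol:
            return out
        target = 0.5 * (inflow + outflow)
        rf = np.sqrt(np.where(outflow > 0, target / np.maximum(outflow, 1e-300), 1.0))
        cf = np.sqrt(np.where(inflow > 0, target / np.maximum(inflow, 1e-300), 1.0))
        out.flux[1 : S + 1, :] *= rf[:, None]
        out.flux[:, 1 : S + 1] *= cf[None, :]
    raise RuntimeError("average balancing did not converge")


def balance(net: FlowNetwork, method: str = "average") -> FlowNetwork:
    """Return an artificially balanced copy of ``net``.

    Strategies (per-node steady state enforced at relative tolerance 1e-9):

    ``naive``
        Dump any surplus inflow to the sink and draw any deficit from the
        source; all internal flows untouched.
    ``input``
        Inputs are authoritative: each node's outflows are rescaled to match
        its inflow, with outflow proportions preserved (exact linear solve).
    ``output``
        Losses are authoritative: each node's inflows are rescaled to match
        its outflow, with inflow proportions preserved (exact linear solve).
    ``average``
        Symmetric compromise: node throughflow is pulled to the mean of inflow
        and outflow by iterated two-sided rescaling.

    The original network is never modified (dissipation for the scaling
    analysis must be read from the *pre-balancing* matrix).  Total boundary
    input before/after is recorded in ``meta``.
    """
    if method not in BALANCE_METHODS:
        raise ValueError(f"unknown balancing method {method!r}; use one of {BALANCE_METHODS}")
    before = net.total_input()
    if method == "naive":
        out = _balance_naive(net)
    elif method == "input":
        out = _balance_input(net)
    elif method == "output":
        out = _balance_output(net)
    else:
        out = _balance_average(net)
    report = check_balance(out, rel_tol=1e-9)
    if not report.balanced:
        raise RuntimeError(
            f"balancing method {method!r} failed: max relative residual "
            f"{report.max_rel_residual:.3e}"
        )
    out.meta.update(
        balance_method=method,
        source_input_before=f"{before:.17g}",
        source_input_after=f"{out.total_input():.17g}",
    )
    return out
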