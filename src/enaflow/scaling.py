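"""Power-law (allometric and dissipation) scaling fits.

Both laws are fitted by ordinary least squares on log10-transformed pairs:
the allometric law ``C ~ A^eta`` over all living compartments, and the
dissipation law ``d ~ A^gamma`` over compartments with positive dissipation
(zeros vanish on log axes and are excluded, not imputed).  Source and sink
never enter a regression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ena import dissipation, impact, throughflow
from .network import FlowNetwork

__all__ = ["ScalingFit", "loglog_fit", "allometry_exponent", "dissipation_exponent"]


@dataclass
class ScalingFit:
    """Result of a log-log OLS power-law fit ``y ~ 10^b * x^k``."""

    exponent: float  #: fitted slope k (eta or gamma)
    log10_prefactor: float  #: intercept b on the log10 scale
    r_squared: float  #: squared Pearson correlation of the log pairs
    n_points: int  #: pairs entering the regression
    excluded: int  #: nonpositive pairs dropped before the fit

    def predict(self, x: np.ndarray) -> np.ndarray:
        return 10.0**self.log10_prefactor * np.asarray(x, float) ** self.exponent


def loglog_fit(x: np.ndarray, y: np.ndarray, min_points: int = 2) -> ScalingFit:
    """OLS of ``log10 y`` on ``log10 x``; pairs with a nonpositive value drop.

    Two points already determine a slope (with a trivially perfect fit);
    ``ScalingFit.n_points`` lets callers impose a stricter reportability
    threshold.  Raises on fewer than ``min_points`` surviving pairs or on
    zero variance in ``log10 x``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d vectors of equal length")
    keep = (x > 0) & (y > 0)
    excluded = int(np.sum(~keep))
    lx, ly = np.log10(x[keep]), np.log10(y[keep])
    if lx.size < max(min_points, 2):
        raise ValueError(
            f"degenerate fit: only {lx.size} positive pairs (need >= {max(min_points, 2)})"
        )
    if np.ptp(lx) == 0:
        raise ValueError("degenerate fit: zero variance in log10 x")
    if np.ptp(ly) == 0:
        # exact horizontal law: zero residual variance, slope 0
        return ScalingFit(0.0, float(ly[0]), 1.0, int(lx.size), excluded)
    res = stats.linregress(lx, ly)
    return ScalingFit(
        exponent=float(res.slope),
        log10_prefactor=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=int(lx.size),
        excluded=excluded,
    )


def allometry_exponent(
    net_balanced: FlowNetwork, variant: str = "expected_flux", rel_tol: float = 1e-6
) -> ScalingFit:
    """Fit the allometric law ``C ~ A^eta`` on a balanced network.

    The exponent eta measures centralization: how fast the total direct plus
    indirect influence of a compartment grows with its throughflow.
    """
    A = throughflow(net_balanced, rel_tol=rel_tol)
    C = impact(net_balanced, variant=variant, rel_tol=rel_tol)
    return loglog_fit(A, C)


def dissipation_exponent(net_original: FlowNetwork) -> ScalingFit:
    """Fit the dissipation law ``d ~ A^gamma`` on the original network.

    ``A`` is the inflow-sum throughflow of the *pre-balancing* matrix (no
    balance precondition: the law is an empirical property of the raw data)
    and ``d`` the raw sink flux; compartments with ``d_i = 0`` are excluded.
    """
    A = net_original.inflows()
    d = dissipation(net_original)
    return loglog_fit(A, d)
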