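"""Evolutionary-game emulation fit and emulative powers.

Network activity, normalized to the open unit interval, is modelled as
two-strategy replicator dynamics on a directed graph:

    dx_i/dt = x_i (1 - x_i) * sum_{j != i} a_ij (2 x_j - 1)

where ``a_ij`` is the weight with which network ``i`` emulates
(``a_ij > 0``) or anti-emulates (``a_ij < 0``) network ``j``.  The coupling
acts through each network's rate of change of activity rather than the
signal itself.  The emulation matrix ``A`` is recovered from data by
ridge-regularized least squares of the central-difference derivatives on
the replicator regressors, row by row.

The emulative powers summarize ``A`` per network: ``OutEP_i = sum_j a_ij``
(row sum — the total weight with which network i emulates the others),
``InEP_j = sum_i a_ij`` (column sum — how much network j is emulated), and
``NetEP = OutEP - InEP``, which sums to zero over networks by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DirectedConnectivity, NetworkTimeSeries

__all__ = [
    "EmulativeProfile",
    "normalize_unit_interval",
    "fit_egn",
    "emulative_powers",
    "ep_features",
]

DEFAULT_MARGIN = 0.05
DEFAULT_RIDGE = 1e-3


@dataclass(frozen=True)
class EmulativeProfile:
    """In-, out- and net-emulative power per network (net = out - in)."""

    in_ep: np.ndarray
    out_ep: np.ndarray
    net_ep: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if not np.allclose(self.net_ep, self.out_ep - self.in_ep, atol=1e-12):
            raise ValueError("net_ep must equal out_ep - in_ep")


def normalize_unit_interval(ts: NetworkTimeSeries, margin: float = DEFAULT_MARGIN) -> NetworkTimeSeries:
    """Affine-map each column onto [margin, 1 - margin].

    Replicator states must live strictly inside (0, 1); ``margin = 0`` is
    refused because the dynamics are degenerate on the boundary.
    """
    if not 0 < margin < 0.5:
        raise ValueError(f"margin must lie in (0, 0.5), got {margin}")
    vals = ts.values
    lo = vals.min(axis=0)
    hi = vals.max(axis=0)
    span = hi - lo
    constant = np.flatnonzero(span == 0)
    if constant.size:
        names = [ts.network_labels[i] for i in constant]
        raise ValueError(f"constant signal for network(s) {names}: cannot normalize")
    unit = (vals - lo) / span
    return ts.with_values(margin + (1.0 - 2.0 * margin) * unit)


def fit_egn(
    ts: NetworkTimeSeries,
    ridge_lambda: float = DEFAULT_RIDGE,
    *,
    gate_min: float = 0.05,
) -> DirectedConnectivity:
    """Fit the emulation matrix A to a session of unit-interval states.

    Derivatives are estimated by central differences (endpoints dropped);
    each row ``a_i.`` solves a ridge-regularized least-squares problem with
    regressors ``r_j(t) = x_i(t)(1 - x_i(t))(2 x_j(t) - 1)``, ``j != i``.
    The ridge penalty is scaled by the mean regressor energy so
    ``ridge_lambda`` is dimensionless.  Diagonal of A is zero.

    Samples where the target's replicator gate ``x_i (1 - x_i)`` falls below
    ``gate_min`` are excluded from that row's regression: near the boundary
    the gate annihilates the deterministic signal, so such samples carry
    noise only and dilute the fit (a saturated trajectory can dominate a
    record).  The row falls back to all samples when too few survive.
    """
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be nonnegative")
    x = ts.values
    T, N = x.shape
    if T < N + 10:
        raise ValueError(f"record too short to fit {N} networks: T={T} < N+10")
    if np.any(x <= 0.0) or np.any(x >= 1.0):
        raise ValueError("states must lie strictly inside (0, 1); normalize first")
    xdot = (x[2:] - x[:-2]) / (2.0 * ts.dt)
    mid = x[1:-1]
    strategy = 2.0 * mid - 1.0
    A = np.zeros((N, N))
    for i in range(N):
        gate = mid[:, i] * (1.0 - mid[:, i])
        keep = gate >= gate_min
        if keep.sum() < N + 10:
            keep = np.ones(len(gate), dtype=bool)
        others = [j for j in range(N) if j != i]
        R = gate[keep, None] * strategy[np.ix_(keep, others)]
        gram = R.T @ R
        scale = float(np.trace(gram)) / len(others)
        if scale == 0.0:
            continue  # gate identically saturated: no identifiable coupling
        penalty = ridge_lambda * scale if ridge_lambda > 0 else 0.0
        lhs = gram + penalty * np.eye(len(others))
        rhs = R.T @ xdot[keep, i]
        try:
            coef = np.linalg.solve(lhs, rhs)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"rank-deficient replicator regressors for network {ts.network_labels[i]!r}"
            ) from exc
        A[i, others] = coef
    return DirectedConnectivity(A, ts.network_labels)


def emulative_powers(A: DirectedConnectivity) -> EmulativeProfile:
    """In-/out-/net-emulative powers of an emulation matrix."""
    vals = A.values
    out_ep = vals.sum(axis=1)
    in_ep = vals.sum(axis=0)
    return EmulativeProfile(in_ep=in_ep, out_ep=out_ep, net_ep=out_ep - in_ep, labels=A.labels)


def ep_features(
    ts: NetworkTimeSeries,
    *,
    margin: float = DEFAULT_MARGIN,
    ridge_lambda: float = DEFAULT_RIDGE,
) -> pd.Series:
    """Named emulative-power features of one session: 3N values.

    Normalizes the session, fits A, and reports ``In-EP_<X>``,
    ``Out-EP_<X>`` and ``Net-EP_<X>`` per network (42 features for N = 14).
    """
    profile = emulative_powers(fit_egn(normalize_unit_interval(ts, margin), ridge_lambda))
    names: list[str] = []
    vals: list[float] = []
    for prefix, vec in (("In-EP", profile.in_ep), ("Out-EP", profile.out_ep), ("Net-EP", profile.net_ep)):
        for lab, v in zip(profile.labels, vec):
            names.append(f"{prefix}_{lab}")
            vals.append(float(v))
    return pd.Series(vals, index=names, dtype=float)
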