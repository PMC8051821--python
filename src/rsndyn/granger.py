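"""Conditional Granger causality between network time series.

For each ordered pair (target ``i``, source ``j``) the causality
``g_ij = F_{j->i|rest}`` is the log ratio of residual variances of target
``i``'s equation in two VAR(p) models over all ``N`` series: the reduced
model omits source ``j``'s lags from that equation, the full model keeps
them.  The matrix ``G = {g_ij}`` (entry = influence of source ``j`` on
target ``i``) is summarized into the net pairwise causality
``netgc = g_ij - g_ji``, and per-network in-/out-/net-degrees
(``DegIn`` = row sums = total inflow, ``DegOut`` = column sums = total
outflow, ``NetDeg = DegOut - DegIn``).

Estimation is ordinary least squares on per-column demeaned series, with
the reduced models refit independently; negative log ratios (possible
under separate estimation) are clamped to zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DirectedConnectivity, NetworkTimeSeries

__all__ = [
    "GcSummaries",
    "select_var_order",
    "conditional_gc",
    "gc_summaries",
    "gc_features",
]


@dataclass(frozen=True)
class GcSummaries:
    """Net pairwise causality and degree summaries of a GC matrix.

    ``net_gc[k]`` is the net causal flow for the k-th unordered pair (A, B)
    in row-major label order: ``F_{A->B} - F_{B->A}``.  ``net_deg`` sums to
    zero by the telescoping identity (both degree vectors sum to the grand
    total of G).
    """

    net_gc: np.ndarray
    deg_in: np.ndarray
    deg_out: np.ndarray
    net_deg: np.ndarray
    labels: tuple[str, ...]

    @property
    def pairs(self) -> list[tuple[str, str]]:
        labels = self.labels
        return [(labels[a], labels[b]) for a in range(len(labels)) for b in range(a + 1, len(labels))]


def _lag_design(X: np.ndarray, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Response (T-p, N) and lag regressor matrix (T-p, N*p), lag-major columns."""
    T, N = X.shape
    Y = X[p:]
    cols = [X[p - l : T - l] for l in range(1, p + 1)]
    Z = np.concatenate(cols, axis=1)
    return Y, Z


def select_var_order(
    ts: NetworkTimeSeries, max_order: int = 10, criterion: str = "BIC"
) -> int:
    """Common VAR order for all series, minimizing AIC or BIC on the full fit.

    Delegates to the standard VAR order-selection machinery; may return 0
    for serially unstructured data (white noise).  Raises when ``max_order``
    is infeasible for the record length.
    """
    criterion = criterion.upper()
    if criterion not in ("AIC", "BIC"):
        raise ValueError(f"criterion must be AIC or BIC, got {criterion!r}")
    T, N = ts.values.shape
    if T <= N * max_order + 10:
        raise ValueError(
            f"max_order {max_order} infeasible for T={T}, N={N}: need T > N*max_order + 10"
        )
    from statsmodels.tsa.api import VAR

    X = ts.values - ts.values.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = VAR(X).select_order(maxlags=max_order, trend="n")
    return int(sel.selected_orders[criterion.lower()])


def conditional_gc(ts: NetworkTimeSeries, order: int) -> DirectedConnectivity:
    """Conditional pairwise Granger causality matrix at the given VAR order.

    Returns ``G`` with ``G[i, j] = max(0, ln(rss_reduced / rss_full))`` for
    target ``i``, source ``j``; diagonal is zero.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    T, N = ts.values.shape
    n_regressors = N * order
    if T - order <= n_regressors + 1:
        raise ValueError(f"VAR({order}) infeasible: {T - order} rows for {n_regressors} regressors")
    if order > 3 and T < 40 * order:
        warnings.warn(
            f"VAR({order}) on T={T}, N={N} leaves few degrees of freedom per equation",
            stacklevel=2,
        )
    X = ts.values - ts.values.mean(axis=0)
    Y, Z = _lag_design(X, order)
    B, res, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    if rank < Z.shape[1]:
        raise np.linalg.LinAlgError(
            f"ill-conditioned regressor matrix (rank {rank} < {Z.shape[1]}); try a lower order"
        )
    rss_full = np.sum((Y - Z @ B) ** 2, axis=0)
    if np.any(rss_full <= 0):
        raise np.linalg.LinAlgError("singular full-model fit: zero residual variance")
    G = np.zeros((N, N))
    for j in range(N):
        keep = np.ones(Z.shape[1], dtype=bool)
        keep[[j + N * l for l in range(order)]] = False
        Zr = Z[:, keep]
        Br, _, rank_r, _ = np.linalg.lstsq(Zr, Y, rcond=None)
        if rank_r < Zr.shape[1]:
            raise np.linalg.LinAlgError("ill-conditioned reduced-model regressors")
        rss_red = np.sum((Y - Zr @ Br) ** 2, axis=0)
        for i in range(N):
            if i == j:
                continue
            G[i, j] = max(0.0, float(np.log(rss_red[i] / rss_full[i])))
    return DirectedConnectivity(G, ts.network_labels)


def gc_summaries(G: DirectedConnectivity) -> GcSummaries:
    """Net pairwise causality and in-/out-/net-degrees of a GC matrix."""
    vals = G.values
    n = G.n
    deg_in = vals.sum(axis=1)
    deg_out = vals.sum(axis=0)
    net_deg = deg_out - deg_in
    net_gc = np.array([vals[b, a] - vals[a, b] for a in range(n) for b in range(a + 1, n)])
    return GcSummaries(net_gc=net_gc, deg_in=deg_in, deg_out=deg_out, net_deg=net_deg, labels=G.labels)


def gc_features(
    ts: NetworkTimeSeries,
    order: int | None = None,
    *,
    max_order: int = 10,
    criterion: str = "BIC",
) -> pd.Series:
    """Named GC features for one session: 3*N(N-1)/2 + 3*N values.

    For each unordered pair A < B (label order): ``A->B`` is the causality
    of A on B, ``A<-B`` that of B on A, and ``netgc_A->B`` their difference;
    then per-network ``GC_DegIn_<X>``, ``GC_DegOut_<X>`` and
    ``GC_NetDeg_<X>``.  When ``order`` is None it is selected by the given
    criterion (floored at 1).
    """
    if order is None:
        order = max(1, select_var_order(ts, max_order=max_order, criterion=criterion))
    G = conditional_gc(ts, order)
    summ = gc_summaries(G)
    labels = G.labels
    n = G.n
    names: list[str] = []
    vals: list[float] = []
    pairs = [(a, b) for a in range(n) for b in range(a + 1, n)]
    for a, b in pairs:
        names.append(f"{labels[a]}->{labels[b]}")
        vals.append(G.values[b, a])
    for a, b in pairs:
        names.append(f"{labels[a]}<-{labels[b]}")
        vals.append(G.values[a, b])
    for k, (a, b) in enumerate(pairs):
        names.append(f"netgc_{labels[a]}->{labels[b]}")
        vals.append(summ.net_gc[k])
    for prefix, vec in (("GC_DegIn", summ.deg_in), ("GC_DegOut", summ.deg_out), ("GC_NetDeg", summ.net_deg)):
        for lab, v in zip(labels, vec):
            names.append(f"{prefix}_{lab}")
            vals.append(float(v))
    return pd.Series(vals, index=names, dtype=float)
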