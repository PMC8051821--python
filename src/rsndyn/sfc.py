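"""Static functional connectivity: whole-record Pearson correlation.

The sFC matrix of a session is the ``N x N`` Pearson correlation of all
network pairs; its ``N(N-1)/2`` unique upper-triangle entries become the
named features ``sFC-<A>-<B>`` (A before B in network-label order), 91 for
the study's 14 networks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NetworkTimeSeries

__all__ = ["SymmetricConnectivity", "correlation_matrix", "sfc_features", "matrix_from_features"]


@dataclass(frozen=True)
class SymmetricConnectivity:
    """Symmetric correlation matrix with unit diagonal and entries in [-1, 1]."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("connectivity must be square")
        if len(self.labels) != values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(values), 1.0, atol=1e-12):
            raise ValueError("diagonal must be 1")
        if np.any(np.abs(values) > 1 + 1e-12):
            raise ValueError("entries must lie in [-1, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def correlation_matrix(ts: NetworkTimeSeries) -> SymmetricConnectivity:
    """Pearson correlation of all network pairs over the whole record."""
    values = ts.values
    stds = values.std(axis=0)
    constant = np.flatnonzero(stds == 0)
    if constant.size:
        names = [ts.network_labels[i] for i in constant]
        raise ValueError(f"constant signal for network(s) {names}: correlation undefined")
    corr = np.corrcoef(values, rowvar=False)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return SymmetricConnectivity(corr, ts.network_labels)


def _pair_indices(n: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle pair ordering (the fixed vectorization order)."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def sfc_features(ts: NetworkTimeSeries) -> pd.Series:
    """Vectorized sFC features, named ``sFC-<A>-<B>``; length N(N-1)/2."""
    conn = correlation_matrix(ts)
    labels = conn.labels
    pairs = _pair_indices(conn.n)
    names = [f"sFC-{labels[i]}-{labels[j]}" for i, j in pairs]
    vals = [conn.values[i, j] for i, j in pairs]
    return pd.Series(vals, index=names, dtype=float)


def matrix_from_features(features: pd.Series, labels: tuple[str, ...]) -> SymmetricConnectivity:
    """Reassemble the sFC matrix from its vectorization (inverse of sfc_features)."""
    n = len(labels)
    values = np.eye(n)
    for (i, j) in _pair_indices(n):
        values[i, j] = values[j, i] = features[f"sFC-{labels[i]}-{labels[j]}"]
    return SymmetricConnectivity(values, labels)
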