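"""Core domain objects and I/O for resting-state network time-series cohorts.

The package operates on per-session matrices of network activity: ``T`` time
points by ``N`` large-scale resting-state networks (RSNs), sampled every
``dt`` seconds.  A :class:`Cohort` bundles the sessions of a two-group,
two-session study design (patients vs. controls, sessions RS1/RS2), and a
:class:`FeatureTable` carries named per-observation features between the
extraction, selection and classification stages.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SESSIONS",
    "GROUPS",
    "DEFAULT_NETWORKS",
    "NetworkTimeSeries",
    "Cohort",
    "FeatureTable",
    "DirectedConnectivity",
    "load_cohort",
    "write_cohort",
    "read_feature_table",
    "write_feature_table",
    "load_mat_session",
    "derive_seed",
]

#: The two resting-state sessions of the study design.
SESSIONS = ("RS1", "RS2")

#: Group labels; "ACA" (accelerated cognitive ageing) is the positive class.
GROUPS = ("ACA", "CONTROL")

#: The 14 large-scale resting-state networks used throughout: lateral visual,
#: medial visual, default mode, auditory, ventral attention, lateral
#: sensorimotor, dorsal attention, occipital visual, superior sensorimotor,
#: cerebellar, left/right fronto-parietal, salience and cingulate networks.
DEFAULT_NETWORKS = (
    "LVISU", "MVISU", "DMN", "AUDI", "VAN", "LSM", "DAN",
    "OVIS", "SSM", "CB", "FPL", "FPR", "SN", "CING",
)

#: Key columns reserved in every feature-table CSV.
KEY_COLUMNS = ("subject_id", "session_id", "group")

MIN_SAMPLES = 32


def derive_seed(master_seed: int, *keys: object) -> int:
    """Derive a stable stream seed below 2**31 from a master seed and keys.

    Uses SHA-256 of the textual keys so the derivation is independent of the
    process hash seed; adding new subjects or stages never perturbs the
    streams of existing ones.
    """
    text = "\x1f".join(str(k) for k in keys)
    digest = hashlib.sha256(text.encode("utf-8")).digest()
    offset = int.from_bytes(digest[:4], "little")
    return int((int(master_seed) + offset) % (2**31 - 1))


@dataclass(frozen=True)
class NetworkTimeSeries:
    """One session's ``T x N`` network signal matrix.

    Parameters
    ----------
    values
        Real matrix, rows are time points, columns are networks.
    dt
        Sampling interval in seconds.
    network_labels
        One unique label per column (e.g. ``"DMN"``, ``"DAN"``).
    subject_id, session_id, group
        Observation keys; ``session_id`` is ``"RS1"`` or ``"RS2"``,
        ``group`` is ``"ACA"`` or ``"CONTROL"``.
    """

    values: np.ndarray
    dt: float
    network_labels: tuple[str, ...]
    subject_id: str = "S0"
    session_id: str = "RS1"
    group: str = "CONTROL"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "network_labels", tuple(self.network_labels))
        if values.ndim != 2:
            raise ValueError(f"values must be a 2-D T x N matrix, got ndim={values.ndim}")
        T, N = values.shape
        if T < MIN_SAMPLES:
            raise ValueError(f"need at least {MIN_SAMPLES} time points, got {T}")
        if N < 2:
            raise ValueError(f"need at least 2 networks, got {N}")
        if len(self.network_labels) != N:
            raise ValueError(
                f"{len(self.network_labels)} labels for {N} columns"
            )
        if len(set(self.network_labels)) != N:
            raise ValueError("network labels must be unique")
        if not np.all(np.isfinite(values)):
            raise ValueError("time series contains non-finite values")
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.session_id not in SESSIONS:
            raise ValueError(f"session_id must be one of {SESSIONS}, got {self.session_id!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_networks(self) -> int:
        return self.values.shape[1]

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples * self.dt

    @property
    def key(self) -> tuple[str, str]:
        return (self.subject_id, self.session_id)

    def column(self, label: str) -> np.ndarray:
        """Return the signal of one network by label."""
        try:
            idx = self.network_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown network label {label!r}") from None
        return self.values[:, idx]

    def with_values(self, values: np.ndarray) -> "NetworkTimeSeries":
        return replace(self, values=values)


@dataclass(frozen=True)
class DirectedConnectivity:
    """Zero-diagonal ``N x N`` directed weight matrix.

    For Granger causality the entry ``values[i, j]`` is the causal influence
    of source network ``j`` on target network ``i`` (``F_{j->i}``).  For the
    evolutionary-game emulation matrix the entry ``a_ij`` is the weight with
    which network ``i`` emulates network ``j``.
    """

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", tuple(self.labels))
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("connectivity must be a square matrix")
        if len(self.labels) != values.shape[0]:
            raise ValueError("label count does not match matrix size")
        if not np.all(np.isfinite(values)):
            raise ValueError("connectivity contains non-finite values")
        if np.any(np.abs(np.diag(values)) > 0):
            raise ValueError("diagonal must be exactly zero")

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Cohort:
    """A collection of sessions sharing networks, labels and sampling."""

    sessions: list[NetworkTimeSeries]

    def __post_init__(self) -> None:
        if not self.sessions:
            raise ValueError("cohort has no sessions")
        ref = self.sessions[0]
        seen: dict[tuple[str, str], str] = {}
        groups: dict[str, str] = {}
        for ts in self.sessions:
            if ts.network_labels != ref.network_labels:
                raise ValueError(
                    f"session {ts.key} has labels {ts.network_labels}, "
                    f"expected {ref.network_labels}"
                )
            if ts.dt != ref.dt:
                raise ValueError(f"session {ts.key} has dt={ts.dt}, expected {ref.dt}")
            if ts.key in seen:
                raise ValueError(f"duplicate (subject, session) pair {ts.key}")
            seen[ts.key] = ts.group
            prior = groups.setdefault(ts.subject_id, ts.group)
            if prior != ts.group:
                raise ValueError(
                    f"subject {ts.subject_id!r} has conflicting group labels "
                    f"{prior!r} and {ts.group!r}"
                )

    @property
    def network_labels(self) -> tuple[str, ...]:
        return self.sessions[0].network_labels

    @property
    def dt(self) -> float:
        return self.sessions[0].dt

    @property
    def subjects(self) -> tuple[str, ...]:
        out: list[str] = []
        for ts in self.sessions:
            if ts.subject_id not in out:
                out.append(ts.subject_id)
        return tuple(out)

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self):
        return iter(self.sessions)

    def session(self, subject_id: str, session_id: str) -> NetworkTimeSeries:
        for ts in self.sessions:
            if ts.key == (subject_id, session_id):
                return ts
        raise KeyError(f"no session {(subject_id, session_id)} in cohort")

    def filter_session(self, session_id: str) -> "Cohort":
        kept = [ts for ts in self.sessions if ts.session_id == session_id]
        if not kept:
            raise KeyError(f"no sessions with session_id={session_id!r}")
        return Cohort(kept)

    def require_both_groups(self) -> None:
        present = {ts.group for ts in self.sessions}
        missing = set(GROUPS) - present
        if missing:
            raise ValueError(f"group analysis requires both groups; missing {sorted(missing)}")


class FeatureTable:
    """Observations x named features, keyed by (subject, session, group).

    ``values`` is a ``pandas.DataFrame`` whose columns are the feature names;
    ``keys`` is a frame with the reserved columns ``subject_id``,
    ``session_id`` and ``group``, aligned row-for-row with ``values``.
    """

    def __init__(self, keys: pd.DataFrame, values: pd.DataFrame) -> None:
        keys = keys.reset_index(drop=True)
        values = values.reset_index(drop=True)
        if list(keys.columns) != list(KEY_COLUMNS):
            raise ValueError(f"key columns must be {KEY_COLUMNS}, got {tuple(keys.columns)}")
        if len(keys) != len(values):
            raise ValueError("keys and values have different numbers of rows")
        names = list(values.columns)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate feature names: {dupes}")
        clash = set(names) & set(KEY_COLUMNS)
        if clash:
            raise ValueError(f"feature names clash with key columns: {sorted(clash)}")
        if len(values.columns) and not np.all(np.isfinite(values.to_numpy(dtype=float))):
            raise ValueError("feature table contains missing or non-finite values")
        bad_groups = set(keys["group"]) - set(GROUPS)
        if bad_groups:
            raise ValueError(f"unknown group labels: {sorted(bad_groups)}")
        dup = keys.duplicated(subset=["subject_id", "session_id"])
        if dup.any():
            raise ValueError("duplicate (subject_id, session_id) observations")
        self.keys = keys
        self.values = values.astype(float) if len(values.columns) else values

    # -- construction -----------------------------------------------------
    @classmethod
    def from_rows(cls, rows: Sequence[tuple[NetworkTimeSeries, pd.Series]]) -> "FeatureTable":
        """Build a table from (session, feature-row) pairs."""
        keys = pd.DataFrame(
            [(ts.subject_id, ts.session_id, ts.group) for ts, _ in rows],
            columns=list(KEY_COLUMNS),
        )
        values = pd.DataFrame([row for _, row in rows]).reset_index(drop=True)
        return cls(keys, values)

    @classmethod
    def concat_features(cls, tables: Sequence["FeatureTable"]) -> "FeatureTable":
        """Horizontally join tables that share identical observation keys."""
        if not tables:
            raise ValueError("no tables to concatenate")
        first = tables[0]
        for other in tables[1:]:
            if not first.keys.equals(other.keys):
                raise ValueError("feature tables have mismatching observation keys")
        values = pd.concat([t.values for t in tables], axis=1)
        return cls(first.keys.copy(), values)

    # -- views ------------------------------------------------------------
    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_observations(self) -> int:
        return len(self.keys)

    @property
    def groups(self) -> np.ndarray:
        return self.keys["group"].to_numpy()

    def matrix(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def subset(self, features: Sequence[str]) -> "FeatureTable":
        missing = [f for f in features if f not in self.values.columns]
        if missing:
            raise KeyError(f"unknown features: {missing[:5]}")
        return FeatureTable(self.keys.copy(), self.values.loc[:, list(features)].copy())

    def session_table(self, session_id: str) -> "FeatureTable":
        mask = (self.keys["session_id"] == session_id).to_numpy()
        if not mask.any():
            raise KeyError(f"no observations for session {session_id!r}")
        return FeatureTable(self.keys.loc[mask].copy(), self.values.loc[mask].copy())

    def sort_by_subject(self) -> "FeatureTable":
        order = self.keys.sort_values(["subject_id", "session_id"]).index
        return FeatureTable(self.keys.loc[order].copy(), self.values.loc[order].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([self.keys, self.values], axis=1)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"FeatureTable({self.n_observations} observations x {len(self.values.columns)} features)"


# ---------------------------------------------------------------------------
# Cohort I/O: CSV manifest + one delimited text matrix per session.
# ---------------------------------------------------------------------------

def _read_matrix(path: Path) -> tuple[np.ndarray, tuple[str, ...]]:
    frame = pd.read_csv(path)
    labels = tuple(str(c) for c in frame.columns)
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric entries in time-series matrix") from exc
    if np.isnan(values).any():
        raise ValueError(f"{path}: ragged or missing entries in time-series matrix")
    return values, labels


def load_cohort(manifest_path: str | Path, dt: float | None = None) -> Cohort:
    """Load a cohort described by a CSV manifest.

    The manifest has columns ``subject_id``, ``session_id``, ``group`` and
    ``file`` (paths resolved relative to the manifest), plus an optional
    ``dt`` column (seconds; default 2.0).  Each referenced file is a
    delimited text matrix with a header row of network labels, one row per
    time point.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    manifest = pd.read_csv(manifest_path)
    required = {"subject_id", "session_id", "group", "file"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    sessions = []
    for _, row in manifest.iterrows():
        path = manifest_path.parent / str(row["file"])
        if not path.exists():
            raise FileNotFoundError(f"time-series file not found: {path}")
        values, labels = _read_matrix(path)
        row_dt = dt if dt is not None else float(row.get("dt", 2.0) or 2.0)
        sessions.append(
            NetworkTimeSeries(
                values=values,
                dt=row_dt,
                network_labels=labels,
                subject_id=str(row["subject_id"]),
                session_id=str(row["session_id"]),
                group=str(row["group"]),
            )
        )
    return Cohort(sessions)


def write_cohort(cohort: Cohort, directory: str | Path, float_format: str = "%.10g") -> Path:
    """Write a cohort as a manifest plus one CSV matrix per session.

    Returns the manifest path; ``load_cohort`` round-trips the result.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in cohort:
        fname = f"{ts.subject_id}_{ts.session_id}.csv"
        frame = pd.DataFrame(ts.values, columns=list(ts.network_labels))
        frame.to_csv(directory / fname, index=False, float_format=float_format)
        rows.append((ts.subject_id, ts.session_id, ts.group, fname, ts.dt))
    manifest = pd.DataFrame(rows, columns=["subject_id", "session_id", "group", "file", "dt"])
    manifest_path = directory / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def write_feature_table(table: FeatureTable, path: str | Path) -> Path:
    """Write a feature table to CSV (keys first, then feature columns)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_feature_table(path: str | Path) -> FeatureTable:
    """Read a feature table written by :func:`write_feature_table`."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
    names = header[len(KEY_COLUMNS):]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"{path}: duplicate feature names {dupes}")
    frame = pd.read_csv(path)
    if list(frame.columns[: len(KEY_COLUMNS)]) != list(KEY_COLUMNS):
        raise ValueError(f"{path}: expected leading key columns {KEY_COLUMNS}")
    keys = frame.loc[:, list(KEY_COLUMNS)].astype(str)
    values = frame.drop(columns=list(KEY_COLUMNS))
    return FeatureTable(keys, values)


def load_mat_session(
    path: str | Path,
    variable: str,
    *,
    dt: float = 2.0,
    network_labels: Sequence[str] = DEFAULT_NETWORKS,
    subject_id: str = "S0",
    session_id: str = "RS1",
    group: str = "CONTROL",
    transpose: bool = False,
) -> NetworkTimeSeries:
    """Read one session from a MATLAB file (schema-configurable convenience).

    ``variable`` names the stored array; set ``transpose=True`` when the file
    stores networks x time.  Classic MAT files are read with
    :mod:`scipy.io`; v7.3 (HDF5) files with :mod:`h5py` when available.
    """
    path = Path(path)
    try:
        from scipy.io import loadmat

        data = loadmat(path)
        if variable not in data:
            raise KeyError(f"{path}: no variable {variable!r} in MAT file")
        values = np.asarray(data[variable], dtype=float)
    except NotImplementedError:  # MAT v7.3 is an HDF5 container
        import h5py

        with h5py.File(path, "r") as fh:
            if variable not in fh:
                raise KeyError(f"{path}: no variable {variable!r} in MAT file")
            # h5py yields the MATLAB array transposed
            values = np.asarray(fh[variable], dtype=float).T
    if transpose:
        values = values.T
    return NetworkTimeSeries(
        values=values,
        dt=dt,
        network_labels=tuple(network_labels),
        subject_id=subject_id,
        session_id=session_id,
        group=group,
    )
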