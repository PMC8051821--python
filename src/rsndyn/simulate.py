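"""Synthetic cohorts with planted, known structure.

Every downstream metric is validated against data generated here: stable
VAR processes with planted lagged coupling (ground truth for Granger
causality), band-limited phase-locked oscillations (ground truth for
wavelet time-of-coherence), replicator-dynamics trajectories (ground truth
for the evolutionary-game emulation fit), and a two-session benchmark
cohort that mirrors the study design of 10 patients vs. 14 controls, 14
networks, 208 samples at a 2 s sampling interval.

Determinism: one master seed is spawned into per-subject/per-session
streams by hashing the textual keys (:func:`rsndyn.core.derive_seed`), so
adding subjects never perturbs the streams of existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_NETWORKS,
    Cohort,
    DirectedConnectivity,
    FeatureTable,
    NetworkTimeSeries,
    derive_seed,
)

__all__ = [
    "SimulationConfig",
    "PlantedEffect",
    "gen_ar1_noise",
    "gen_var_session",
    "gen_var_cohort",
    "gen_phase_locked_pair",
    "gen_egn_trajectory",
    "gen_benchmark_dataset",
    "gen_feature_table",
    "companion_spectral_radius",
]

#: Default AR(1) coefficient emulating BOLD autocorrelation at a 2 s TR.
DEFAULT_AR1 = 0.3

_BURN_IN = 100


@dataclass(frozen=True)
class PlantedEffect:
    """One group-difference descriptor.

    ``kind`` is one of ``var_coupling`` (lagged directed coupling in the VAR
    base process), ``phase_lock`` (a shared band-limited oscillation in a
    network pair), ``egn_matrix`` (a replicator-coupled component embedded
    in a network pair) or ``mean_shift_feature`` (a shifted feature column,
    realized at the feature-table level by :func:`gen_feature_table`).
    ``params`` hold the kind-specific values documented on the generator
    functions.
    """

    kind: str
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        allowed = {"var_coupling", "phase_lock", "egn_matrix", "mean_shift_feature"}
        if self.kind not in allowed:
            raise ValueError(f"unknown effect kind {self.kind!r}; expected one of {sorted(allowed)}")


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic benchmark cohort."""

    n_controls: int = 14
    n_patients: int = 10
    n_networks: int = 14
    n_samples: int = 208
    dt: float = 2.0
    seed: int = 0
    noise_sd: float = 1.0
    ar1_coef: float = DEFAULT_AR1
    network_labels: tuple[str, ...] = DEFAULT_NETWORKS
    effects: tuple[PlantedEffect, ...] = ()

    def __post_init__(self) -> None:
        if self.n_samples < 64:
            raise ValueError("n_samples must be at least 64")
        if not 0 <= self.ar1_coef < 1:
            raise ValueError("ar1_coef must lie in [0, 1)")
        if len(self.network_labels) != self.n_networks:
            raise ValueError("network_labels length must equal n_networks")
        for eff in self.effects:
            for key in ("source", "target", "pair"):
                val = eff.params.get(key)
                labels = val if isinstance(val, (tuple, list)) else [val]
                for lab in labels:
                    if lab is not None and lab not in self.network_labels:
                        raise ValueError(f"effect references unknown network {lab!r}")


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the VAR companion matrix.

    ``coeffs`` has shape ``(p, N, N)``; the process is stable iff the radius
    is strictly below 1.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None]
    p, N, _ = coeffs.shape
    companion = np.zeros((N * p, N * p))
    companion[:N] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        companion[N:, : N * (p - 1)] = np.eye(N * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def gen_ar1_noise(rng: np.random.Generator, T: int, n: int, coef: float, sd: float) -> np.ndarray:
    """Stationary AR(1) noise, ``T x n``, with marginal standard deviation ``sd``."""
    if sd == 0:
        return np.zeros((T, n))
    innov_sd = sd * np.sqrt(1.0 - coef**2)
    x = np.empty((T + _BURN_IN, n))
    x[0] = rng.normal(0.0, sd, size=n)
    eps = rng.normal(0.0, innov_sd, size=(T + _BURN_IN - 1, n))
    for t in range(1, T + _BURN_IN):
        x[t] = coef * x[t - 1] + eps[t - 1]
    return x[_BURN_IN:]


def gen_var_session(
    coeffs: np.ndarray,
    T: int,
    *,
    dt: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    network_labels: Sequence[str] | None = None,
    subject_id: str = "S0",
    session_id: str = "RS1",
    group: str = "CONTROL",
) -> NetworkTimeSeries:
    """One realization of a VAR(p) process with Gaussian innovations.

    ``coeffs`` is ``(p, N, N)`` (or ``(N, N)`` for p=1) with entry
    ``coeffs[l, i, j]`` the weight of ``x_j[t-l-1]`` in ``x_i[t]``.  Raises
    if the process is unstable, reporting the companion spectral radius.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.ndim == 2:
        coeffs = coeffs[None]
    radius = companion_spectral_radius(coeffs)
    if radius >= 1.0:
        raise ValueError(f"unstable VAR coefficients: companion spectral radius {radius:.4f} >= 1")
    p, N, _ = coeffs.shape
    labels = tuple(network_labels) if network_labels is not None else tuple(f"NET{i+1}" for i in range(N))
    rng = np.random.default_rng(seed)
    total = T + _BURN_IN
    x = np.zeros((total, N))
    eps = rng.normal(0.0, noise_sd, size=(total, N))
    for t in range(total):
        acc = eps[t].copy()
        for l in range(1, p + 1):
            if t - l >= 0:
                acc += coeffs[l - 1] @ x[t - l]
        x[t] = acc
    return NetworkTimeSeries(
        values=x[_BURN_IN:],
        dt=dt,
        network_labels=labels,
        subject_id=subject_id,
        session_id=session_id,
        group=group,
    )


def gen_var_cohort(
    config: SimulationConfig,
    coeffs_control: np.ndarray,
    coeffs_patient: np.ndarray | None = None,
    *,
    sessions: Sequence[str] = ("RS1",),
) -> Cohort:
    """Cohort of VAR realizations with group-dependent coupling.

    Controls follow ``coeffs_control``; patients follow ``coeffs_patient``
    (default: same as controls).  Per-session seeds derive from
    ``config.seed`` and the subject/session keys.
    """
    if coeffs_patient is None:
        coeffs_patient = coeffs_control
    out = []
    roster = [(f"ctrl{i+1:02d}", "CONTROL") for i in range(config.n_controls)]
    roster += [(f"aca{i+1:02d}", "ACA") for i in range(config.n_patients)]
    for subject, group in roster:
        coeffs = coeffs_control if group == "CONTROL" else coeffs_patient
        for session in sessions:
            out.append(
                gen_var_session(
                    coeffs,
                    config.n_samples,
                    dt=config.dt,
                    noise_sd=config.noise_sd,
                    seed=derive_seed(config.seed, "var", subject, session),
                    network_labels=config.network_labels,
                    subject_id=subject,
                    session_id=session,
                    group=group,
                )
            )
    return Cohort(out)


def _oscillation_window(T: int, coherent_fraction: float) -> np.ndarray:
    """Contiguous centred indicator window covering the requested fraction."""
    width = int(round(coherent_fraction * T))
    start = (T - width) // 2
    window = np.zeros(T)
    window[start : start + width] = 1.0
    return window


def gen_phase_locked_pair(
    period_s: float,
    coherent_fraction: float,
    phase_offset_rad: float,
    T: int = 208,
    dt: float = 2.0,
    noise_sd: float = 0.5,
    seed: int = 0,
    *,
    amplitude: float = 1.0,
    ar1_coef: float = DEFAULT_AR1,
    network_labels: Sequence[str] = ("NET1", "NET2"),
    subject_id: str = "S0",
    session_id: str = "RS1",
    group: str = "CONTROL",
) -> NetworkTimeSeries:
    """Two channels sharing a sinusoid over a contiguous centred window.

    Channel 2 is shifted by ``phase_offset_rad`` (positive offset = channel 1
    leads).  Independent AR(1) noise of standard deviation ``noise_sd`` is
    added throughout.  The window is centred so that, for moderate periods,
    it lies inside the cone of influence and the planted fraction maps
    directly onto the time-of-coherence.
    """
    if not (2 * dt < period_s < T * dt / 2):
        raise ValueError(
            f"period {period_s} s not resolvable: need 2*dt={2*dt} < period < T*dt/2={T*dt/2}"
        )
    if not 0 <= coherent_fraction <= 1:
        raise ValueError("coherent_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(T) * dt
    window = _oscillation_window(T, coherent_fraction)
    carrier = 2 * np.pi * t / period_s
    x = amplitude * np.cos(carrier) * window
    y = amplitude * np.cos(carrier - phase_offset_rad) * window
    noise = gen_ar1_noise(rng, T, 2, ar1_coef, noise_sd)
    values = np.column_stack([x, y]) + noise
    return NetworkTimeSeries(
        values=values,
        dt=dt,
        network_labels=tuple(network_labels),
        subject_id=subject_id,
        session_id=session_id,
        group=group,
    )


def replicator_rhs(x: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Right-hand side of the two-strategy replicator dynamics on a network.

    ``dx_i/dt = x_i (1 - x_i) * sum_{j != i} a_ij (2 x_j - 1)``: network ``i``
    moves toward the active strategy (x -> 1) when the networks it emulates
    with positive weight are active (x_j > 1/2), and away when the weights
    are negative (anti-emulation).
    """
    return x * (1.0 - x) * (A @ (2.0 * x - 1.0))


def gen_egn_trajectory(
    A: DirectedConnectivity | np.ndarray,
    x0: np.ndarray,
    T: int = 208,
    dt: float = 2.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    *,
    clip_margin: float = 0.01,
    network_labels: Sequence[str] | None = None,
    subject_id: str = "S0",
    session_id: str = "RS1",
    group: str = "CONTROL",
) -> NetworkTimeSeries:
    """Integrate the replicator dynamics by explicit Euler stepping.

    States are perturbed by additive Gaussian noise of size ``noise_sd`` per
    step and clipped to ``[clip_margin, 1 - clip_margin]``.  ``x0`` must be
    strictly interior to (0, 1): the dynamics are degenerate on the boundary
    (``x_i(1 - x_i) = 0`` freezes the state).
    """
    if isinstance(A, DirectedConnectivity):
        labels = A.labels if network_labels is None else tuple(network_labels)
        A = A.values
    else:
        A = np.asarray(A, dtype=float)
        labels = (
            tuple(network_labels)
            if network_labels is not None
            else tuple(f"NET{i+1}" for i in range(A.shape[0]))
        )
    if np.any(np.abs(np.diag(A)) > 0):
        raise ValueError("emulation matrix must have a zero diagonal")
    x0 = np.asarray(x0, dtype=float)
    if np.any(x0 <= 0.0) or np.any(x0 >= 1.0):
        raise ValueError("x0 must lie strictly inside (0, 1); replicator dynamics are degenerate on the boundary")
    rng = np.random.default_rng(seed)
    n = A.shape[0]
    x = np.empty((T, n))
    x[0] = x0
    lo, hi = clip_margin, 1.0 - clip_margin
    for t in range(1, T):
        step = x[t - 1] + dt * replicator_rhs(x[t - 1], A)
        if noise_sd > 0:
            step = step + rng.normal(0.0, noise_sd, size=n)
        x[t] = np.clip(step, lo, hi)
    return NetworkTimeSeries(
        values=x,
        dt=dt,
        network_labels=labels,
        subject_id=subject_id,
        session_id=session_id,
        group=group,
    )


# ---------------------------------------------------------------------------
# Benchmark cohort
# ---------------------------------------------------------------------------

def default_benchmark_effects() -> tuple[PlantedEffect, ...]:
    """Planted group differences for the benchmark cohort.

    Patients (ACA) differ from controls by: (a) a lagged directed coupling
    DMN -> AUDI in the VAR base process (Granger-causality ground truth);
    (b) a 20 s in-phase oscillation shared by DMN and MVISU over 60% of the
    record (time-of-coherence ground truth, band [16, 32) s); (c) a
    replicator-coupled component in DMN/DAN whose emulation weight
    a[DAN, DMN] flips sign between groups (emulative-power ground truth:
    patients' DMN is anti-emulated, mirroring a negative In-EP).
    """
    return (
        PlantedEffect("var_coupling", {"source": "DMN", "target": "AUDI", "coeff": 0.5, "lag": 1, "control_coeff": 0.0}),
        PlantedEffect(
            "phase_lock",
            {
                "pair": ("MVISU", "DMN"),
                "period_s": 20.0,
                "fraction": 0.6,
                "control_fraction": 0.0,
                "amplitude": 1.2,
                "phase_offset_rad": 0.0,
            },
        ),
        PlantedEffect(
            "egn_matrix",
            {"pair": ("DMN", "DAN"), "weight": -0.12, "control_weight": 0.12, "amplitude": 1.0, "state_noise": 0.04},
        ),
    )


def default_benchmark_config(seed: int = 0) -> SimulationConfig:
    return SimulationConfig(seed=seed, effects=default_benchmark_effects())


def _benchmark_session(config: SimulationConfig, subject: str, session: str, group: str) -> NetworkTimeSeries:
    labels = list(config.network_labels)
    N, T, dt = config.n_networks, config.n_samples, config.dt
    patient = group == "ACA"

    # Base process: diagonal AR(1) plus any planted lagged couplings.
    max_lag = 1
    for eff in config.effects:
        if eff.kind == "var_coupling":
            max_lag = max(max_lag, int(eff.params.get("lag", 1)))
    coeffs = np.zeros((max_lag, N, N))
    coeffs[0] += np.eye(N) * config.ar1_coef
    for eff in config.effects:
        if eff.kind != "var_coupling":
            continue
        coeff = float(eff.params["coeff"] if patient else eff.params.get("control_coeff", 0.0))
        if coeff == 0.0:
            continue
        lag = int(eff.params.get("lag", 1))
        src = labels.index(eff.params["source"])
        tgt = labels.index(eff.params["target"])
        coeffs[lag - 1, tgt, src] += coeff
    base = gen_var_session(
        coeffs,
        T,
        dt=dt,
        noise_sd=config.noise_sd,
        seed=derive_seed(config.seed, "bench-var", subject, session),
        network_labels=labels,
        subject_id=subject,
        session_id=session,
        group=group,
    )
    values = base.values.copy()

    t_axis = np.arange(T) * dt
    for k, eff in enumerate(config.effects):
        if eff.kind == "phase_lock":
            fraction = float(eff.params["fraction"] if patient else eff.params.get("control_fraction", 0.0))
            if fraction <= 0:
                continue
            a_lab, b_lab = eff.params["pair"]
            amp = float(eff.params.get("amplitude", 1.0))
            period = float(eff.params["period_s"])
            offset = float(eff.params.get("phase_offset_rad", 0.0))
            window = _oscillation_window(T, fraction)
            rng = np.random.default_rng(derive_seed(config.seed, "bench-phase", k, subject, session))
            phase0 = rng.uniform(0, 2 * np.pi)  # random carrier phase per session
            carrier = 2 * np.pi * t_axis / period + phase0
            values[:, labels.index(a_lab)] += amp * np.cos(carrier) * window
            values[:, labels.index(b_lab)] += amp * np.cos(carrier - offset) * window
        elif eff.kind == "egn_matrix":
            a_lab, b_lab = eff.params["pair"]
            weight = float(eff.params["weight"] if patient else eff.params.get("control_weight", 0.0))
            amp = float(eff.params.get("amplitude", 1.0))
            state_noise = float(eff.params.get("state_noise", 0.04))
            A2 = np.array([[0.0, 0.0], [weight, 0.0]])  # b emulates a with the given sign
            traj = gen_egn_trajectory(
                A2,
                x0=np.array([0.5, 0.5]),
                T=T,
                dt=dt,
                noise_sd=state_noise,
                seed=derive_seed(config.seed, "bench-egn", k, subject, session),
                clip_margin=0.05,
                network_labels=("a", "b"),
            ).values
            z = (traj - traj.mean(axis=0)) / np.maximum(traj.std(axis=0), 1e-12)
            values[:, labels.index(a_lab)] += amp * z[:, 0]
            values[:, labels.index(b_lab)] += amp * z[:, 1]
    return base.with_values(values)


def gen_benchmark_dataset(
    seed: int = 0, config: SimulationConfig | None = None
) -> tuple[Cohort, Cohort]:
    """Two-session benchmark cohort mirroring the study design.

    Returns ``(cohort_rs1, cohort_rs2)`` with 14 controls and 10 patients,
    two sessions each, 208 x 14 matrices at dt = 2 s, and the planted group
    differences of :func:`default_benchmark_effects` (disable by passing a
    config with ``effects=()``).
    """
    if config is None:
        config = default_benchmark_config(seed)
    roster = [(f"ctrl{i+1:02d}", "CONTROL") for i in range(config.n_controls)]
    roster += [(f"aca{i+1:02d}", "ACA") for i in range(config.n_patients)]
    cohorts = []
    for session in ("RS1", "RS2"):
        cohorts.append(
            Cohort([_benchmark_session(config, subj, session, grp) for subj, grp in roster])
        )
    return cohorts[0], cohorts[1]


def gen_feature_table(
    n_controls: int = 14,
    n_patients: int = 10,
    n_features: int = 100,
    *,
    effect_sizes: Mapping[str, float] | None = None,
    sessions: Sequence[str] = ("RS1",),
    seed: int = 0,
) -> FeatureTable:
    """Gaussian feature table with optional planted group mean shifts.

    ``effect_sizes`` maps feature name -> shift (in pooled-SD units) added to
    the patient group; unnamed features are exchangeable between groups
    (standard normal).  Realizes the ``mean_shift_feature`` effect kind for
    selection and classification calibration studies.
    """
    rng = np.random.default_rng(seed)
    names = [f"f{i:04d}" for i in range(n_features)]
    rows = []
    keys = []
    for session in sessions:
        for subject, group in [(f"ctrl{i+1:02d}", "CONTROL") for i in range(n_controls)] + [
            (f"aca{i+1:02d}", "ACA") for i in range(n_patients)
        ]:
            vals = rng.normal(0.0, 1.0, size=n_features)
            if group == "ACA" and effect_sizes:
                for name, shift in effect_sizes.items():
                    vals[names.index(name)] += shift
            keys.append((subject, session, group))
            rows.append(vals)
    return FeatureTable(
        pd.DataFrame(keys, columns=["subject_id", "session_id", "group"]),
        pd.DataFrame(np.array(rows), columns=names),
    )
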