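"""Morlet wavelet coherence, phase classification and time-of-coherence.

The continuous wavelet transform uses the analytic Morlet wavelet
(omega0 = 6) evaluated in the frequency domain over log2-spaced scales, the
standard construction for geophysical and neuroimaging coherence analysis.
Squared coherence between two signals is the smoothed cross-wavelet power
normalized by the smoothed auto-powers, with scale-dependent Gaussian
smoothing in time and a boxcar over 0.6 octave in scale.  Pointwise
significance is calibrated against AR(1) surrogate pairs matched to each
input's lag-1 autocorrelation.

The relative phase angle ``theta = arg(W_x W_y*)`` is positive when signal
1 leads, and is classified into four quadrants: in-phase
(theta in [-pi/4, pi/4)), signal 1 leading ([pi/4, 3pi/4)), anti-phase
([3pi/4, pi] and [-pi, -3pi/4)), signal 1 lagging ([-3pi/4, -pi/4)).
The time-of-coherence of a pair is, per period band and phase class, the
percentage of the record during which some in-band scale is significantly
coherent inside the cone of influence with that phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .core import NetworkTimeSeries, derive_seed

__all__ = [
    "PhaseClass",
    "CoherenceScalogram",
    "PERIOD_BANDS",
    "PHASE_PREFIX",
    "morlet_cwt",
    "coherence_pair",
    "surrogate_threshold",
    "significance_mask",
    "classify_phase",
    "time_of_coherence",
    "wcoh_features",
    "ThresholdCache",
]

#: Morlet nondimensional frequency; 6 makes scale ~ Fourier period.
OMEGA0 = 6.0

#: Sub-octave resolution: 12 scales per octave.
DJ = 1.0 / 12.0

#: Fourier factor: period = FOURIER_FACTOR * scale for the Morlet wavelet.
FOURIER_FACTOR = 4.0 * np.pi / (OMEGA0 + np.sqrt(2.0 + OMEGA0**2))

#: The five period bands (seconds); the last band is closed at 128 s.
PERIOD_BANDS = ((4.0, 8.0), (8.0, 16.0), (16.0, 32.0), (32.0, 64.0), (64.0, 128.0))

MIN_SAMPLES = 64


class PhaseClass(str, Enum):
    """Phase-quadrant categories partitioning (-pi, pi]."""

    IN_PHASE = "ip"
    ANTI_PHASE = "ap"
    LEADING = "lead"
    LAGGING = "lag"


#: Feature-name prefixes in their fixed output order.
PHASE_PREFIX = (PhaseClass.IN_PHASE, PhaseClass.ANTI_PHASE, PhaseClass.LEADING, PhaseClass.LAGGING)


def classify_phase(theta):
    """Classify phase angles in (-pi, pi] into the four quadrant classes.

    Returns a :class:`PhaseClass` for scalar input or an integer array of
    indices into :data:`PHASE_PREFIX` for array input.  Boundaries are
    half-open on the lower side so the classes partition (-pi, pi].
    """
    arr = np.asarray(theta, dtype=float)
    if np.any(arr <= -np.pi - 1e-12) or np.any(arr > np.pi + 1e-12):
        raise ValueError("phase angle outside (-pi, pi]")
    idx = _phase_index(arr)
    if np.isscalar(theta) or arr.ndim == 0:
        return PHASE_PREFIX[int(idx)]
    return idx


def _phase_index(theta: np.ndarray) -> np.ndarray:
    """Vectorized class index: 0=ip, 1=ap, 2=lead, 3=lag."""
    q = np.pi / 4.0
    idx = np.empty(np.shape(theta), dtype=np.int8)
    idx[...] = 1  # anti-phase covers [3pi/4, pi] and [-pi, -3pi/4)
    inp = (theta >= -q) & (theta < q)
    lead = (theta >= q) & (theta < 3 * q)
    lag = (theta >= -3 * q) & (theta < -q)
    idx[inp] = 0
    idx[lead] = 2
    idx[lag] = 3
    return idx


@dataclass
class CoherenceScalogram:
    """Time x scale coherence of one signal pair.

    ``coherence`` and ``phase`` are (n_scales, n_times); ``coi_mask`` is
    True inside the cone of influence (reliable, away from edge effects);
    ``sig_mask`` is True where coherence exceeds the surrogate threshold
    (filled by :func:`significance_mask`, None until then).
    """

    times: np.ndarray
    periods: np.ndarray
    coherence: np.ndarray
    phase: np.ndarray
    coi_mask: np.ndarray
    sig_mask: np.ndarray | None = None
    dt: float = 2.0

    def __post_init__(self) -> None:
        shape = (len(self.periods), len(self.times))
        for name in ("coherence", "phase", "coi_mask"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} has shape {getattr(self, name).shape}, expected {shape}")
        if self.sig_mask is not None and self.sig_mask.shape != shape:
            raise ValueError("sig_mask shape mismatch")
        if np.any(self.coherence < -1e-9) or np.any(self.coherence > 1 + 1e-9):
            raise ValueError("coherence outside [0, 1]")


def _scales(dt: float, T: int, min_period: float, max_period: float) -> np.ndarray:
    if T < MIN_SAMPLES:
        raise ValueError(f"record too short for wavelet analysis: T={T} < {MIN_SAMPLES}")
    resolvable = T * dt / 2.0
    if max_period > resolvable:
        warnings.warn(
            f"record of {T * dt:.0f} s cannot resolve periods above {resolvable:.0f} s; "
            f"truncating the scale range (requested {max_period:.0f} s)",
            stacklevel=3,
        )
        max_period = resolvable
    s0 = min_period / FOURIER_FACTOR
    n_octaves = np.log2(max_period / min_period)
    J = int(np.floor(n_octaves / DJ))
    return s0 * 2.0 ** (DJ * np.arange(J + 1))


def morlet_cwt(
    x: np.ndarray,
    dt: float,
    *,
    min_period: float = 4.0,
    max_period: float = 128.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Continuous Morlet (omega0=6) wavelet transform of one series.

    Returns ``(coeffs, periods, coi)``: complex coefficients of shape
    (n_scales, T) over log2-spaced scales spanning the requested period
    range, the Fourier periods (seconds), and the cone-of-influence curve
    ``coi[t]`` — the largest reliable period at each time, set by the
    wavelet's e-folding time ``sqrt(2) * scale``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("morlet_cwt expects a 1-D series")
    T = x.size
    scales = _scales(dt, T, min_period, max_period)
    x = x - x.mean()
    n_fft = next_fast_len(2 * T)
    xhat = fft(x, n_fft)
    omega = 2.0 * np.pi * np.fft.fftfreq(n_fft, d=dt)
    pos = omega > 0
    # Analytic Morlet in the frequency domain, L2-normalized per scale.
    arg = scales[:, None] * omega[None, :]
    psi_hat = np.zeros_like(arg)
    psi_hat[:, pos] = (
        np.pi**-0.25
        * np.sqrt(2.0 * np.pi * scales[:, None] / dt)
        * np.exp(-0.5 * (arg[:, pos] - OMEGA0) ** 2)
    )
    W = ifft(xhat[None, :] * psi_hat, axis=1)[:, :T]
    periods = FOURIER_FACTOR * scales
    edge = dt * np.minimum(np.arange(T), np.arange(T)[::-1])
    coi = FOURIER_FACTOR / np.sqrt(2.0) * edge
    return W, periods, coi


def _smooth(field: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Scale-dependent Gaussian smoothing in time, boxcar smoothing in scale.

    Time smoothing (std = one scale) runs in the frequency domain for all
    scales at once, with zero padding; the resulting amplitude droop near
    the record edges multiplies the cross- and auto-spectra identically and
    cancels in the coherence ratio.
    """
    S, T = field.shape
    n = next_fast_len(2 * T)
    omega = 2.0 * np.pi * np.fft.fftfreq(n)
    ghat = np.exp(-0.5 * (scales[:, None] / dt) ** 2 * omega[None, :] ** 2)
    out = ifft(fft(field, n, axis=1) * ghat, axis=1)[:, :T]
    if not np.iscomplexobj(field):
        out = out.real
    width = max(1, int(round(0.6 / DJ)))
    if np.iscomplexobj(out):
        out = uniform_filter1d(out.real, width, axis=0, mode="nearest") + 1j * uniform_filter1d(
            out.imag, width, axis=0, mode="nearest"
        )
    else:
        out = uniform_filter1d(out, width, axis=0, mode="nearest")
    return out


def coherence_pair(
    x: np.ndarray,
    y: np.ndarray,
    dt: float,
    *,
    min_period: float = 4.0,
    max_period: float = 128.0,
) -> CoherenceScalogram:
    """Squared wavelet coherence and relative phase of two equal-length series.

    ``coherence = |S(Wxy/s)|^2 / (S(|Wx|^2/s) S(|Wy|^2/s))`` with the
    smoothing operator ``S`` of :func:`_smooth`; ``phase = arg`` of the
    smoothed cross-spectrum, positive when ``x`` leads ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    Wx, periods, coi = morlet_cwt(x, dt, min_period=min_period, max_period=max_period)
    Wy, _, _ = morlet_cwt(y, dt, min_period=min_period, max_period=max_period)
    scales = periods / FOURIER_FACTOR
    inv_s = 1.0 / scales[:, None]
    cross = _smooth(Wx * np.conj(Wy) * inv_s, scales, dt)
    sxx = _smooth(np.abs(Wx) ** 2 * inv_s, scales, dt)
    syy = _smooth(np.abs(Wy) ** 2 * inv_s, scales, dt)
    denom = np.maximum(sxx * syy, 1e-300)
    coherence = np.clip(np.abs(cross) ** 2 / denom, 0.0, 1.0)
    phase = np.angle(cross)
    times = np.arange(x.size) * dt
    coi_mask = periods[:, None] <= coi[None, :]
    return CoherenceScalogram(
        times=times,
        periods=periods,
        coherence=coherence,
        phase=phase,
        coi_mask=coi_mask,
        dt=dt,
    )


def _lag1_autocorr(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom == 0:
        return 0.0
    r1 = float(np.dot(x[:-1], x[1:]) / denom)
    return float(np.clip(r1, -0.95, 0.95))


def _ar1_batch(rng: np.random.Generator, r1: float, T: int, n: int) -> np.ndarray:
    """n stationary AR(1) series of length T, unit variance, coefficient r1."""
    innov = rng.normal(0.0, np.sqrt(max(1.0 - r1**2, 1e-6)), size=(n, T))
    x = np.empty((n, T))
    x[:, 0] = rng.normal(0.0, 1.0, size=n)
    for t in range(1, T):
        x[:, t] = r1 * x[:, t - 1] + innov[:, t]
    return x


def surrogate_threshold(
    r1x: float,
    r1y: float,
    T: int,
    dt: float,
    *,
    n_surrogates: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
    min_period: float = 4.0,
    max_period: float = 128.0,
) -> np.ndarray:
    """Per-scale (1-alpha) coherence quantile over AR(1) surrogate pairs.

    The null distribution is pooled over inside-COI time points of all
    surrogate pairs for each scale (falling back to all time points for
    scales whose COI is empty).  Coherence is invariant to signal variance,
    so the threshold depends only on (r1x, r1y, T, dt, scale grid).
    """
    if n_surrogates < 50:
        raise ValueError("need at least 50 surrogates for a stable quantile")
    rng = np.random.default_rng(seed)
    xs = _ar1_batch(rng, r1x, T, n_surrogates)
    ys = _ar1_batch(rng, r1y, T, n_surrogates)
    pooled: list[np.ndarray] = []
    coi_mask = None
    for k in range(n_surrogates):
        scal = coherence_pair(xs[k], ys[k], dt, min_period=min_period, max_period=max_period)
        if coi_mask is None:
            coi_mask = scal.coi_mask
            pooled = [[] for _ in range(len(scal.periods))]
        for s in range(len(scal.periods)):
            inside = coi_mask[s]
            vals = scal.coherence[s, inside] if inside.any() else scal.coherence[s]
            pooled[s].append(vals)
    thr = np.array([np.quantile(np.concatenate(v), 1.0 - alpha) for v in pooled])
    return thr


def significance_mask(
    x: np.ndarray,
    y: np.ndarray,
    scalogram: CoherenceScalogram,
    n_surrogates: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
    *,
    threshold: np.ndarray | None = None,
) -> np.ndarray:
    """Pointwise significance of a coherence scalogram vs. AR(1) surrogates.

    Surrogates are matched to each input's lag-1 autocorrelation (coherence
    is variance-invariant, so no amplitude matching is needed).  A
    precomputed per-scale ``threshold`` may be supplied to share surrogate
    ensembles across pairs.
    """
    if threshold is None:
        threshold = surrogate_threshold(
            _lag1_autocorr(x),
            _lag1_autocorr(y),
            T=len(scalogram.times),
            dt=scalogram.dt,
            n_surrogates=n_surrogates,
            alpha=alpha,
            seed=seed,
            min_period=float(scalogram.periods[0]),
            max_period=float(scalogram.periods[-1]) * (1 + 1e-9),
        )
    if len(threshold) != len(scalogram.periods):
        raise ValueError("threshold length does not match scale count")
    mask = scalogram.coherence > threshold[:, None]
    scalogram.sig_mask = mask
    return mask


def time_of_coherence(
    scalogram: CoherenceScalogram,
    *,
    bands: Sequence[tuple[float, float]] = PERIOD_BANDS,
    per_cell: bool = False,
) -> pd.DataFrame:
    """Percentage of the record coherent per (period band, phase class).

    For each band and time point, the point counts toward the phase class of
    the maximal-coherence cell among in-band scales that are significant and
    inside the cone of influence.  With ``per_cell=True`` the percentage is
    instead computed over (scale, time) cells of the band.  Rows are bands
    (s1..s5), columns the four phase classes; per band the four values sum
    to the total significant-time percentage.
    """
    if scalogram.sig_mask is None:
        raise ValueError("significance mask not computed; call significance_mask first")
    T = len(scalogram.times)
    periods = scalogram.periods
    usable = scalogram.sig_mask & scalogram.coi_mask
    phase_idx = _phase_index(scalogram.phase)
    out = np.zeros((len(bands), 4))
    for b, (lo, hi) in enumerate(bands):
        closed = hi >= bands[-1][1]  # last band closed at its upper edge
        in_band = (periods >= lo) & ((periods <= hi * (1 + 1e-9)) if closed else (periods < hi))
        if not in_band.any():
            continue
        band_use = usable[in_band]
        band_coh = np.where(band_use, scalogram.coherence[in_band], -1.0)
        band_phase = phase_idx[in_band]
        if per_cell:
            n_cells = band_use.size
            for c in range(4):
                out[b, c] = 100.0 * np.sum(band_use & (band_phase == c)) / n_cells
            continue
        any_sig = band_use.any(axis=0)
        best_scale = np.argmax(band_coh, axis=0)
        t_idx = np.flatnonzero(any_sig)
        classes = band_phase[best_scale[t_idx], t_idx]
        for c in range(4):
            out[b, c] = 100.0 * np.sum(classes == c) / T
    return pd.DataFrame(
        out,
        index=[f"s{k+1}" for k in range(len(bands))],
        columns=[p.value for p in PHASE_PREFIX],
    )


class ThresholdCache:
    """Shares surrogate significance thresholds across signal pairs.

    The null coherence distribution depends only on the record geometry and
    the two lag-1 autocorrelations, so thresholds are memoized on the AR(1)
    coefficients quantized to ``resolution`` (order-free).  Each cache entry
    draws its own surrogate ensemble with a seed derived from the base seed
    and the key, making results independent of evaluation order.
    """

    def __init__(
        self,
        T: int,
        dt: float,
        *,
        n_surrogates: int = 300,
        alpha: float = 0.05,
        seed: int = 0,
        resolution: float = 0.05,
        min_period: float = 4.0,
        max_period: float = 128.0,
    ) -> None:
        self.T, self.dt = T, dt
        self.n_surrogates, self.alpha, self.seed = n_surrogates, alpha, seed
        self.resolution = resolution
        self.min_period, self.max_period = min_period, max_period
        self._store: dict[tuple[int, int], np.ndarray] = {}

    def _key(self, r1x: float, r1y: float) -> tuple[int, int]:
        q = lambda r: int(round(r / self.resolution))
        return tuple(sorted((q(r1x), q(r1y))))  # type: ignore[return-value]

    def threshold(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        key = self._key(_lag1_autocorr(x), _lag1_autocorr(y))
        if key not in self._store:
            self._store[key] = surrogate_threshold(
                key[0] * self.resolution,
                key[1] * self.resolution,
                self.T,
                self.dt,
                n_surrogates=self.n_surrogates,
                alpha=self.alpha,
                seed=derive_seed(self.seed, "wcoh-thr", key[0], key[1]),
                min_period=self.min_period,
                max_period=self.max_period,
            )
        return self._store[key]


def wcoh_features(
    ts: NetworkTimeSeries,
    n_surrogates: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
    *,
    cache: ThresholdCache | None = None,
    per_cell: bool = False,
) -> pd.Series:
    """Time-of-coherence features for all network pairs of one session.

    Names follow ``<prefix>_<A>-<B>_s<k>`` with prefix in {ip, ap, lead,
    lag}, A before B in label order, and k = 1..5 indexing the period bands
    [4,8), [8,16), [16,32), [32,64), [64,128] s; 4*5*N(N-1)/2 features
    (1820 for N = 14).
    """
    labels = ts.network_labels
    n = ts.n_networks
    max_period = min(128.0, ts.duration / 2.0)
    if cache is None:
        cache = ThresholdCache(
            ts.n_samples,
            ts.dt,
            n_surrogates=n_surrogates,
            alpha=alpha,
            seed=seed,
            max_period=max_period,
        )
    names: list[str] = []
    vals: list[float] = []
    for a in range(n):
        for b in range(a + 1, n):
            x, y = ts.values[:, a], ts.values[:, b]
            scal = coherence_pair(x, y, ts.dt, max_period=max_period)
            significance_mask(x, y, scal, threshold=cache.threshold(x, y))
            toc = time_of_coherence(scal, per_cell=per_cell)
            for prefix in PHASE_PREFIX:
                for k in range(len(PERIOD_BANDS)):
                    names.append(f"{prefix.value}_{labels[a]}-{labels[b]}_s{k+1}")
                    vals.append(float(toc.iloc[k][prefix.value]))
    return pd.Series(vals, index=names, dtype=float)


def export_scalogram(scalogram: CoherenceScalogram, path) -> None:
    """Write a scalogram (coherence, phase, masks) as delimited text for plotting."""
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    np.savetxt(path / "times_s.csv", scalogram.times, delimiter=",")
    np.savetxt(path / "periods_s.csv", scalogram.periods, delimiter=",")
    np.savetxt(path / "coherence.csv", scalogram.coherence, delimiter=",")
    np.savetxt(path / "phase.csv", scalogram.phase, delimiter=",")
    np.savetxt(path / "coi_mask.csv", scalogram.coi_mask.astype(int), fmt="%d", delimiter=",")
    if scalogram.sig_mask is not None:
        np.savetxt(path / "sig_mask.csv", scalogram.sig_mask.astype(int), fmt="%d", delimiter=",")
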