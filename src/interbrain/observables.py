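"""From phase trajectories to EEG-like signals and phase-locking measures.

The measurement chain mirrors a standard hyperscanning analysis:
synthesise a sinusoidal signal from each oscillator's phase, add
Gaussian observation noise, band-pass filter, extract the instantaneous
phase with the Hilbert transform, and quantify phase locking between
two channels with the phase-locking value

    PLV = (1/T) | sum_{t=1..T} exp(i (theta_a(t) - theta_b(t))) |,

which is 0 for unrelated phases and 1 for a constant relative phase.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .model_core import OSCILLATOR_ORDER, PhaseTrajectory

__all__ = [
    "GAMMA_BAND",
    "THETA_BAND",
    "TimeSeries",
    "AnalyticPhase",
    "PLVValue",
    "synthesize_signal",
    "add_observation_noise",
    "rms",
    "snr_db",
    "snr_from_timeseries",
    "bandpass_filter",
    "instantaneous_phase",
    "plv",
]

#: Default analysis bands (Hz): gamma for the A2-B2 coupling measure.
GAMMA_BAND: tuple[float, float] = (35.0, 45.0)
THETA_BAND: tuple[float, float] = (4.0, 8.0)


@dataclass
class TimeSeries:
    """Real-valued signals, one row per channel, at a fixed sampling rate."""

    values: np.ndarray  # (n_channels, T)
    sampling_rate_hz: float
    labels: tuple[str, ...] = OSCILLATOR_ORDER

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels must match the number of channels")

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz

    def channel(self, label: str) -> np.ndarray:
        return self.values[self.labels.index(label)]


@dataclass
class AnalyticPhase:
    """Instantaneous (wrapped) phases from the analytic signal.

    ``band`` records the band-pass applied beforehand ("none" for the
    bypass path); ``edge_trim`` is the number of samples dropped at
    each end to suppress Hilbert edge effects.
    """

    phases: np.ndarray  # (n_channels, T'), radians in (-pi, pi]
    sampling_rate_hz: float
    labels: tuple[str, ...] = OSCILLATOR_ORDER
    band: str = "none"
    edge_trim: int = 0

    def channel(self, label: str) -> np.ndarray:
        return self.phases[self.labels.index(label)]


@dataclass(frozen=True)
class PLVValue:
    """A single phase-locking value in [0, 1] for one channel pair."""

    value: float
    pair: tuple[str, str] = ("A2", "B2")
    n_timepoints: int = 0

    def __float__(self) -> float:
        return self.value


def synthesize_signal(trajectory: PhaseTrajectory, amplitude: float = 1.0) -> TimeSeries:
    """Map phases to signals, x_i(t) = amplitude * sin(theta_i(t))."""
    if not np.all(np.isfinite(trajectory.phases)):
        raise ValueError("trajectory contains non-finite phases")
    return TimeSeries(
        values=amplitude * np.sin(trajectory.phases),
        sampling_rate_hz=1.0 / trajectory.step_s,
        labels=trajectory.labels,
    )


def add_observation_noise(
    signal: TimeSeries, mu: float, sigma: float, rng: np.random.Generator
) -> TimeSeries:
    """Add iid Gaussian(mu, sigma) noise to every sample of every channel.

    Pure function: the input series is left unmodified.
    """
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    if sigma == 0 and mu == 0:
        noisy = signal.values.copy()
    else:
        noisy = signal.values + rng.normal(mu, sigma, size=signal.values.shape)
    return replace(signal, values=noisy)


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude of an array."""
    x = np.asarray(x, dtype=float)
    return float(np.sqrt(np.mean(np.square(x))))


def snr_db(signal_level: float, noise_level: float) -> float:
    """Signal-to-noise ratio in decibels, 20*log10(signal/noise)."""
    if signal_level <= 0 or noise_level <= 0:
        raise ValueError("signal and noise levels must be strictly positive")
    return 20.0 * np.log10(signal_level / noise_level)


def snr_from_timeseries(
    clean: TimeSeries, noise: TimeSeries, convention: str = "rms"
) -> float:
    """SNR (dB) of a clean/noise series pair under a stated convention.

    Only the RMS/RMS convention is implemented: amplitude of each series
    is its root-mean-square.  The convention is recorded in run
    manifests because published absolute SNR figures are sensitive to it.
    """
    if convention != "rms":
        raise ValueError(f"unknown SNR convention {convention!r}")
    return snr_db(rms(clean.values), rms(noise.values))


def bandpass_filter(
    signal: TimeSeries,
    low_hz: float | None,
    high_hz: float | None = None,
    order: int = 4,
) -> TimeSeries:
    """Zero-phase (forward-backward Butterworth) band-pass filter.

    Pass ``low_hz=None`` (or the string ``"none"``) for the identity
    bypass.  The band must lie strictly inside (0, Nyquist).
    """
    if low_hz is None or (isinstance(low_hz, str) and low_hz == "none"):
        return replace(signal, values=signal.values.copy())
    nyq = signal.sampling_rate_hz / 2.0
    if high_hz is None:
        raise ValueError("high_hz is required unless bypassing")
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
        )
    sos = butter(order, [low_hz, high_hz], btype="band", fs=signal.sampling_rate_hz, output="sos")
    return replace(signal, values=sosfiltfilt(sos, signal.values, axis=-1))


def instantaneous_phase(signal: TimeSeries, edge_trim_s: float = 0.5) -> AnalyticPhase:
    """Instantaneous phase of each channel via the Hilbert transform.

    The first and last ``edge_trim_s`` seconds are discarded to
    suppress the transform's edge effects (default 0.5 s).
    """
    if edge_trim_s < 0:
        raise ValueError("edge_trim_s must be nonnegative")
    n_trim = int(round(edge_trim_s * signal.sampling_rate_hz))
    if signal.n_samples - 2 * n_trim < 2:
        raise ValueError("signal too short after edge trimming")
    analytic = hilbert(signal.values, axis=-1)
    phases = np.angle(analytic)
    if n_trim:
        phases = phases[:, n_trim:-n_trim]
    return AnalyticPhase(
        phases=phases,
        sampling_rate_hz=signal.sampling_rate_hz,
        labels=signal.labels,
        edge_trim=n_trim,
    )


def plv(
    phase_a: np.ndarray | Sequence[float],
    phase_b: np.ndarray | Sequence[float],
    pair: tuple[str, str] = ("A2", "B2"),
) -> PLVValue:
    """Phase-locking value between two equal-length phase series.

    PLV = (1/T)|sum_t exp(i(theta_a - theta_b))|; symmetric in its
    arguments, invariant under a common additive constant, in [0, 1].
    """
    a = np.asarray(phase_a, dtype=float)
    b = np.asarray(phase_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("phase series must be 1-D and of equal length")
    if a.size < 1:
        raise ValueError("phase series must contain at least one sample")
    value = float(np.abs(np.mean(np.exp(1j * (a - b)))))
    return PLVValue(value=min(value, 1.0), pair=pair, n_timepoints=a.size)


def _plv_batch(dphi: np.ndarray) -> np.ndarray:
    """Row-wise PLV of a (R, T) array of phase differences."""
    return np.abs(np.mean(np.exp(1j * dphi), axis=-1))
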