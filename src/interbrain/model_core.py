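"""Two-brain Kuramoto phase dynamics.

The system is four phase oscillators split into two "brain" units: each
unit holds one theta oscillator (A1, B1; 6 Hz mean) and one gamma
oscillator (A2, B2; 40 Hz mean).  Phases evolve under instantaneous
sine coupling,

    dtheta_i/dt = omega_i(t) + sum_j K_ij sin(theta_j - theta_i),

where ``K`` is a symmetric coupling matrix carrying theta-gamma
cross-frequency coupling (CFC) inside each unit (A1-A2 and B1-B2) and
inter-brain theta coupling (theta-IBC) across units (A1-B1).  The gamma
oscillators A2 and B2 are never directly connected: any phase locking
between them must be relayed through the theta chain
A2 <- A1 <-> B1 -> B2.

Integration is forward Euler with a 10 ms output step by default; an
optional ``substeps`` refinement integrates on a finer internal grid
while recording on the same output grid.  All phases are in radians
(stored unwrapped), frequencies in rad/s, time in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "OSCILLATOR_ORDER",
    "OscillatorSpec",
    "CouplingMatrix",
    "SimulationConfig",
    "PhaseTrajectory",
    "IntegrationError",
    "default_oscillators",
    "build_two_brain_coupling_matrix",
    "sample_natural_frequencies",
    "sample_initial_phases",
    "integrate_kuramoto",
]

#: Fixed oscillator ordering used everywhere (rows of matrices, channel order).
OSCILLATOR_ORDER: tuple[str, ...] = ("A1", "A2", "B1", "B2")

_UNITS = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
_BANDS = {"A1": "theta", "A2": "gamma", "B1": "theta", "B2": "gamma"}

TWO_PI = 2.0 * np.pi


class IntegrationError(RuntimeError):
    """Raised when the Euler integration produces a non-finite phase."""


@dataclass(frozen=True)
class OscillatorSpec:
    """One phase oscillator: its label, unit, band and natural frequency.

    ``mean_frequency_hz`` and ``frequency_spread_hz`` parameterise the
    distribution the per-replicate (or per-step) natural frequency is
    drawn from; the spread is the SD of a normal law (or the half-width
    of a uniform law, see :func:`sample_natural_frequencies`).
    """

    label: str
    mean_frequency_hz: float
    frequency_spread_hz: float = 1.0
    unit: str | None = None
    band: str | None = None

    def __post_init__(self) -> None:
        if self.label not in _UNITS:
            raise ValueError(f"unknown oscillator label {self.label!r}; expected one of {OSCILLATOR_ORDER}")
        if self.mean_frequency_hz <= 0:
            raise ValueError("mean_frequency_hz must be positive")
        if self.frequency_spread_hz < 0:
            raise ValueError("frequency_spread_hz must be nonnegative")
        if self.unit is None:
            object.__setattr__(self, "unit", _UNITS[self.label])
        if self.band is None:
            object.__setattr__(self, "band", _BANDS[self.label])

    @property
    def mean_omega(self) -> float:
        """Mean natural frequency in rad/s (2*pi*f)."""
        return TWO_PI * self.mean_frequency_hz


def default_oscillators(
    theta_hz: float = 6.0,
    gamma_hz: float = 40.0,
    spread_hz: float = 1.0,
) -> tuple[OscillatorSpec, ...]:
    """The canonical four oscillators: theta at 6 (+/-1) Hz, gamma at 40 (+/-1) Hz."""
    freq = {"A1": theta_hz, "A2": gamma_hz, "B1": theta_hz, "B2": gamma_hz}
    return tuple(
        OscillatorSpec(label, mean_frequency_hz=freq[label], frequency_spread_hz=spread_hz)
        for label in OSCILLATOR_ORDER
    )


@dataclass(frozen=True)
class CouplingMatrix:
    """Nonnegative n x n coupling strengths K_ij with a zero diagonal.

    For the two-brain topology the oscillator order is fixed as
    (A1, A2, B1, B2) and nonzero entries occur only on the pairs
    {A1,A2}, {B1,B2} (cross-frequency coupling) and {A1,B1}
    (inter-brain theta coupling).
    """

    strengths: np.ndarray
    labels: tuple[str, ...] = OSCILLATOR_ORDER

    def __post_init__(self) -> None:
        K = np.asarray(self.strengths, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("coupling matrix must be square")
        if len(self.labels) != K.shape[0]:
            raise ValueError("labels must match matrix size")
        if np.any(K < 0):
            raise ValueError("coupling strengths must be nonnegative")
        if np.any(np.diag(K) != 0):
            raise ValueError("coupling matrix must have a zero diagonal")
        object.__setattr__(self, "strengths", K)
        self.strengths.setflags(write=False)

    @property
    def n(self) -> int:
        return self.strengths.shape[0]

    @property
    def is_symmetric(self) -> bool:
        return bool(np.array_equal(self.strengths, self.strengths.T))

    def to_csv(self, path: str | Path) -> None:
        """Write as plain CSV: header row of labels, then n numeric rows."""
        with open(path, "w") as fh:
            fh.write("," + ",".join(self.labels) + "\n")
            for lab, row in zip(self.labels, self.strengths):
                fh.write(lab + "," + ",".join(format(v, ".17g") for v in row) + "\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CouplingMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(df.to_numpy(dtype=float), labels=tuple(df.columns))


def build_two_brain_coupling_matrix(theta_ibc: float, cfc: float) -> CouplingMatrix:
    """Coupling matrix of the two-brain model.

    Parameters
    ----------
    theta_ibc
        Inter-brain theta coupling strength (edge A1-B1), >= 0.
    cfc
        Within-unit theta-gamma cross-frequency coupling strength
        (edges A1-A2 and B1-B2), >= 0.

    Returns
    -------
    CouplingMatrix
        Symmetric 4x4 matrix in the (A1, A2, B1, B2) order; the six
        remaining off-diagonal entries ({A2,B2}, {A1,B2}, {A2,B1}) are
        structural zeros.
    """
    if theta_ibc < 0 or cfc < 0:
        raise ValueError("coupling strengths must be nonnegative")
    K = np.zeros((4, 4))
    K[0, 1] = K[1, 0] = cfc  # A1 - A2
    K[2, 3] = K[3, 2] = cfc  # B1 - B2
    K[0, 2] = K[2, 0] = theta_ibc  # A1 - B1
    return CouplingMatrix(K)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration and observation-noise settings for one replicate.

    Defaults reproduce the reference protocol: 40 s of dynamics on a
    10 ms Euler grid (4,000 steps, 4,001 recorded samples including
    t=0), additive Gaussian observation noise with sigma = 0.6, and
    natural frequencies drawn once per replicate
    (``frequency_mode="per_run_constant"``).  ``per_step_jitter``
    instead redraws the frequency of every oscillator at every output
    step.  ``substeps`` refines the internal Euler step to
    ``step_s/substeps`` while keeping the output grid unchanged.
    Couplings act instantaneously: time delays are not supported.

    ``coupling_timescale`` fixes the unit of the coupling strengths:

    ``"per_second"``
        K_ij is a rate in rad/s and the Euler update scales it by the
        integration step (the literal ODE reading).  Couplings of
        order one are then weak relative to the band frequencies.
    ``"per_step"``
        K_ij is the phase kick applied per *output* step — the
        discrete-time Kuramoto map, theta += dt*omega + K*sin(...) —
        equivalent to an ODE coupling of K/step_s rad/s.  This is the
        reading under which couplings of order one visibly entrain
        oscillators across a 34 Hz band gap, and it is the default of
        the sweep protocol (see :mod:`interbrain.experiment`).
    """

    duration_s: float = 40.0
    step_s: float = 0.01
    substeps: int = 1
    noise_sigma: float = 0.6
    noise_mu: float = 0.0
    frequency_mode: str = "per_run_constant"
    frequency_distribution: str = "normal"
    coupling_timescale: str = "per_second"
    master_seed: int = 0
    time_delays: float | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.step_s <= 0:
            raise ValueError("duration_s and step_s must be positive")
        n = self.duration_s / self.step_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s must be an integer multiple of step_s")
        if self.substeps < 1 or int(self.substeps) != self.substeps:
            raise ValueError("substeps must be a positive integer")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")
        if self.frequency_mode not in ("per_run_constant", "per_step_jitter"):
            raise ValueError(f"unknown frequency_mode {self.frequency_mode!r}")
        if self.frequency_distribution not in ("normal", "uniform"):
            raise ValueError(f"unknown frequency_distribution {self.frequency_distribution!r}")
        if self.coupling_timescale not in ("per_second", "per_step"):
            raise ValueError(f"unknown coupling_timescale {self.coupling_timescale!r}")
        if self.time_delays not in (None, 0, 0.0):
            raise ValueError("time delays are not supported; couplings act instantaneously")

    @property
    def n_steps(self) -> int:
        """Number of Euler output steps (4,000 at defaults)."""
        return int(round(self.duration_s / self.step_s))

    @property
    def n_samples(self) -> int:
        """Recorded samples including t=0 (4,001 at defaults)."""
        return self.n_steps + 1

    @property
    def sampling_rate_hz(self) -> float:
        return 1.0 / self.step_s

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class PhaseTrajectory:
    """Unwrapped phases (n oscillators x T samples) on a uniform time grid."""

    phases: np.ndarray
    times: np.ndarray
    omega: np.ndarray  # (n,) rad/s, or (n, n_steps) in jitter mode
    labels: tuple[str, ...] = OSCILLATOR_ORDER

    @property
    def n_oscillators(self) -> int:
        return self.phases.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phases.shape[1]

    @property
    def step_s(self) -> float:
        return float(self.times[1] - self.times[0])


def sample_natural_frequencies(
    specs: Sequence[OscillatorSpec],
    mode: str,
    rng: np.random.Generator,
    n_steps: int | None = None,
    distribution: str = "normal",
) -> np.ndarray:
    """Draw natural frequencies omega_i (rad/s) for one replicate.

    In ``per_run_constant`` mode each oscillator gets a single draw
    held for the whole run; in ``per_step_jitter`` mode each oscillator
    is redrawn at every output step (shape ``(n, n_steps)``), which is
    the alternative reading of a time-dependent omega_i(t).  The draw
    order is fixed as the canonical order (A1, A2, B1, B2), per step in
    jitter mode, so results are reproducible from the generator state.

    ``distribution="normal"`` treats the spread as an SD;
    ``"uniform"`` treats it as the half-width of a uniform interval.
    """
    means = np.array([s.mean_frequency_hz for s in specs])
    spreads = np.array([s.frequency_spread_hz for s in specs])
    if mode == "per_run_constant":
        size: tuple[int, ...] = (len(specs),)
    elif mode == "per_step_jitter":
        if n_steps is None:
            raise ValueError("n_steps is required in per_step_jitter mode")
        size = (n_steps, len(specs))
    else:
        raise ValueError(f"unknown frequency mode {mode!r}")

    if distribution == "normal":
        f_hz = rng.normal(means, spreads, size=size)
    elif distribution == "uniform":
        f_hz = rng.uniform(means - spreads, means + spreads, size=size)
    else:
        raise ValueError(f"unknown frequency distribution {distribution!r}")
    omega = TWO_PI * f_hz
    return omega.T if omega.ndim == 2 else omega


def sample_initial_phases(n: int, rng: np.random.Generator) -> np.ndarray:
    """n independent initial phases, uniform on [0, 2*pi)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.uniform(0.0, TWO_PI, size=n)


def _effective_coupling(K: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Coupling matrix in rad/s under the config's coupling timescale."""
    if config.coupling_timescale == "per_step":
        return K / config.step_s
    return K


def _euler_phases(
    theta0: np.ndarray,
    omega: np.ndarray,
    K: np.ndarray,
    n_steps: int,
    step_s: float,
    substeps: int,
    record: np.ndarray | None = None,
) -> np.ndarray:
    """Batched forward-Euler core.

    ``theta0``: (R, n); ``omega``: (R, n) or (R, n, n_steps);
    ``record``: indices of oscillators whose full trajectory is kept
    (default: all).  Returns phases of shape (R, len(record), n_steps+1).

    The coupling term sum_j K_ij sin(theta_j - theta_i) is expanded as
    cos(theta_i)*(K sin theta)_i - sin(theta_i)*(K cos theta)_i so only
    2n transcendentals per replicate per substep are needed; the
    contraction uses einsum so the floating-point reduction order does
    not depend on the batch size.
    """
    R, n = theta0.shape
    if record is None:
        record = np.arange(n)
    dt = step_s / substeps
    per_step_omega = omega.ndim == 3
    theta = theta0.astype(float, copy=True)
    out = np.empty((R, len(record), n_steps + 1))
    out[:, :, 0] = theta[:, record]
    coupled = np.any(K != 0)
    with np.errstate(over="ignore", invalid="ignore"):  # non-finite caught below
        for k in range(n_steps):
            w = omega[:, :, k] if per_step_omega else omega
            for _ in range(substeps):
                if coupled:
                    s = np.sin(theta)
                    c = np.cos(theta)
                    drive = w + c * np.einsum("ij,rj->ri", K, s) - s * np.einsum("ij,rj->ri", K, c)
                else:
                    drive = w
                theta = theta + dt * drive
            if not np.all(np.isfinite(theta)):
                bad = int(np.argwhere(~np.isfinite(theta))[0][0])
                raise IntegrationError(f"non-finite phase at output step {k + 1} (replicate {bad})")
            out[:, :, k + 1] = theta[:, record]
    return out


def integrate_kuramoto(
    config: SimulationConfig,
    K: CouplingMatrix | np.ndarray,
    omega: np.ndarray,
    theta0: np.ndarray,
    labels: tuple[str, ...] | None = None,
) -> PhaseTrajectory:
    """Integrate the Kuramoto dynamics for one replicate.

    Forward Euler with effective step ``config.step_s / config.substeps``;
    output is recorded every ``step_s`` including t=0, so the trajectory
    has ``config.n_samples`` samples.  Deterministic given its inputs.

    ``omega`` is (n,) in rad/s, or (n, n_steps) for per-step jitter.

    Raises
    ------
    IntegrationError
        If a phase becomes non-finite, naming the offending step.
    """
    Kmat = K.strengths if isinstance(K, CouplingMatrix) else np.asarray(K, dtype=float)
    theta0 = np.asarray(theta0, dtype=float)
    omega = np.asarray(omega, dtype=float)
    n = theta0.shape[0]
    if Kmat.shape != (n, n):
        raise ValueError("K, omega and theta0 dimensions disagree")
    if omega.shape[0] != n:
        raise ValueError("K, omega and theta0 dimensions disagree")
    if omega.ndim == 2 and omega.shape[1] != config.n_steps:
        raise ValueError(f"per-step omega must have {config.n_steps} columns")
    if labels is None:
        labels = (
            K.labels
            if isinstance(K, CouplingMatrix) and len(K.labels) == n
            else tuple(f"osc{i}" for i in range(n))
        )
    omega_b = omega[None, :, :] if omega.ndim == 2 else omega[None, :]
    phases = _euler_phases(
        theta0[None, :], omega_b, _effective_coupling(Kmat, config),
        config.n_steps, config.step_s, config.substeps,
    )[0]
    times = np.arange(config.n_samples) * config.step_s
    return PhaseTrajectory(phases=phases, times=times, omega=omega, labels=labels)
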