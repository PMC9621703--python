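"""Monte-Carlo sweep over (theta-IBC x CFC) and the paired delta-PLV z-tests.

One replicate is a full pipeline pass: build the two-brain coupling
matrix, draw natural frequencies and initial phases, integrate the
Kuramoto dynamics, synthesise noisy signals, band-pass filter, extract
analytic phases and compute the gamma-band PLV between the two gamma
oscillators A2 and B2.  A condition repeats this for many independent
replicates; the sweep covers an 11 x 11 grid of coupling levels
(0 to 1 by 0.1 on both axes at defaults).

For each CFC level the contrast of interest is the paired difference
delta-PLV = PLV(theta_ibc = max) - PLV(theta_ibc = min), replicate by
replicate, tested against zero with a one-sample z statistic
z = mean(delta) / (sd(delta)/sqrt(n)) and a one-sided upper-tail
p-value 1 - Phi(z).  This contrast — not the absolute PLV level, which
is inflated by spurious coupling between similar but unconnected
oscillators — is what carries the scientific conclusion.

The sweep protocol interprets the printed coupling levels (0 to 1) as
per-step phase kicks (``coupling_timescale="per_step"``, the
discrete-time Kuramoto map): see :func:`protocol_config`.  Under the
literal ODE reading a coupling of 1 rad/s is negligible against the
2*pi*34 rad/s theta-gamma band gap and the sweep has no effect to
detect; only the per-step reading produces the contrast of interest.

Randomness discipline: a master seed spawns one `numpy` SeedSequence
per condition, which spawns one child per replicate, which spawns
three sub-streams (frequencies, initial phases, observation noise).
Any replicate is therefore reproducible in isolation, and the
replicate-vectorised engine is sample-for-sample identical to running
the single-replicate pipeline sequentially.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model_core import (
    OscillatorSpec,
    SimulationConfig,
    build_two_brain_coupling_matrix,
    default_oscillators,
    integrate_kuramoto,
    sample_initial_phases,
    sample_natural_frequencies,
    _euler_phases,
)
from .observables import (
    GAMMA_BAND,
    PLVValue,
    _plv_batch,
    add_observation_noise,
    bandpass_filter,
    instantaneous_phase,
    plv,
    synthesize_signal,
)

__all__ = [
    "SweepGrid",
    "PLVSample",
    "ZTestResult",
    "SweepResult",
    "replicate_seed_sequence",
    "run_replicate",
    "run_condition",
    "run_sweep",
    "delta_plv_ztest",
    "ztest_series",
]

_DEFAULT_LEVELS = tuple(np.round(np.arange(0.0, 1.01, 0.1), 10))
_GAMMA_IDX = (1, 3)  # A2, B2 rows in the (A1, A2, B1, B2) order


def protocol_config(**overrides) -> SimulationConfig:
    """Default configuration of the sweep protocol.

    Identical to ``SimulationConfig()`` except that coupling strengths
    are per-step phase kicks, the reading of the printed 0-to-1
    coupling levels under which the theta chain can actually entrain
    the gamma oscillators.
    """
    overrides.setdefault("coupling_timescale", "per_step")
    return SimulationConfig(**overrides)


@dataclass(frozen=True)
class SweepGrid:
    """The sweep protocol: coupling levels, replicate count, base config."""

    theta_ibc_levels: tuple[float, ...] = _DEFAULT_LEVELS
    cfc_levels: tuple[float, ...] = _DEFAULT_LEVELS
    replicates: int = 10_000
    config: SimulationConfig = field(default_factory=protocol_config)
    master_seed: int = 0
    filter_band: tuple[float, float] | None = GAMMA_BAND
    edge_trim_s: float = 0.5

    def __post_init__(self) -> None:
        for levels in (self.theta_ibc_levels, self.cfc_levels):
            arr = np.asarray(levels, dtype=float)
            if arr.size < 1 or np.any(np.diff(arr) <= 0):
                raise ValueError("levels must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class PLVSample:
    """Per-replicate gamma-PLV values for one (theta_ibc, cfc) cell."""

    theta_ibc: float
    cfc: float
    plv_values: np.ndarray
    seed_entropy: int | None = None

    @property
    def n(self) -> int:
        return self.plv_values.size

    @property
    def mean(self) -> float:
        return float(self.plv_values.mean())


@dataclass(frozen=True)
class ZTestResult:
    """One-sample z-test of paired delta-PLV against zero at one CFC level."""

    cfc: float
    delta_mean: float
    delta_sd: float
    n: int
    z: float
    p_one_sided: float


def replicate_seed_sequence(
    condition_seed: int | np.random.SeedSequence, k: int
) -> np.random.SeedSequence:
    """SeedSequence of replicate ``k`` within a condition, reproducible in isolation."""
    parent = _as_seedseq(condition_seed)
    return np.random.SeedSequence(entropy=parent.entropy, spawn_key=parent.spawn_key + (k,))


def _as_seedseq(seed: int | np.random.SeedSequence) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(int(seed))


def _replicate_rngs(rep_ss: np.random.SeedSequence):
    """Frequency, initial-phase and noise generators of one replicate."""
    f_ss, p_ss, n_ss = rep_ss.spawn(3)
    return (
        np.random.default_rng(f_ss),
        np.random.default_rng(p_ss),
        np.random.default_rng(n_ss),
    )


def run_replicate(
    theta_ibc: float,
    cfc: float,
    config: SimulationConfig,
    replicate_seed: int | np.random.SeedSequence,
    oscillators: Sequence[OscillatorSpec] | None = None,
    filter_band: tuple[float, float] | None = GAMMA_BAND,
    edge_trim_s: float = 0.5,
) -> PLVValue:
    """One full pipeline pass; returns the gamma-PLV between A2 and B2.

    Deterministic given ``replicate_seed``.  ``filter_band=None``
    bypasses the pre-Hilbert band-pass.
    """
    specs = tuple(oscillators) if oscillators is not None else default_oscillators()
    rep_ss = _as_seedseq(replicate_seed)
    freq_rng, phase_rng, noise_rng = _replicate_rngs(rep_ss)
    K = build_two_brain_coupling_matrix(theta_ibc, cfc)
    omega = sample_natural_frequencies(
        specs, config.frequency_mode, freq_rng,
        n_steps=config.n_steps, distribution=config.frequency_distribution,
    )
    theta0 = sample_initial_phases(len(specs), phase_rng)
    try:
        traj = integrate_kuramoto(config, K, omega, theta0)
        signal = synthesize_signal(traj)
        noisy = add_observation_noise(signal, config.noise_mu, config.noise_sigma, noise_rng)
        if filter_band is not None:
            noisy = bandpass_filter(noisy, *filter_band)
        phases = instantaneous_phase(noisy, edge_trim_s=edge_trim_s)
    except Exception as err:
        raise type(err)(
            f"{err} [replicate seed entropy={rep_ss.entropy}, spawn_key={rep_ss.spawn_key}]"
        ) from err
    return plv(phases.channel("A2"), phases.channel("B2"))


def _condition_plvs_vectorized(
    theta_ibc: float,
    cfc: float,
    config: SimulationConfig,
    seed_seqs: list[np.random.SeedSequence],
    specs: tuple[OscillatorSpec, ...],
    filter_band: tuple[float, float] | None,
    edge_trim_s: float,
    chunk_size: int = 2000,
) -> np.ndarray:
    """Replicate-vectorised pipeline; identical samples to the sequential path."""
    from scipy.signal import butter, hilbert, sosfiltfilt

    from .model_core import _effective_coupling

    K = _effective_coupling(build_two_brain_coupling_matrix(theta_ibc, cfc).strengths, config)
    n = len(specs)
    n_steps, T = config.n_steps, config.n_samples
    fs = config.sampling_rate_hz
    n_trim = int(round(edge_trim_s * fs))
    if T - 2 * n_trim < 2:
        raise ValueError("signal too short after edge trimming")
    sos = None
    if filter_band is not None:
        low, high = filter_band
        if not (0 < low < high < fs / 2):
            raise ValueError(f"band ({low}, {high}) Hz outside (0, Nyquist)")
        sos = butter(4, [low, high], btype="band", fs=fs, output="sos")

    out = np.empty(len(seed_seqs))
    per_step = config.frequency_mode == "per_step_jitter"
    for start in range(0, len(seed_seqs), chunk_size):
        block = seed_seqs[start : start + chunk_size]
        R = len(block)
        theta0 = np.empty((R, n))
        omega = np.empty((R, n, n_steps)) if per_step else np.empty((R, n))
        noise_rngs = []
        for k, ss in enumerate(block):
            freq_rng, phase_rng, noise_rng = _replicate_rngs(ss)
            omega[k] = sample_natural_frequencies(
                specs, config.frequency_mode, freq_rng,
                n_steps=n_steps, distribution=config.frequency_distribution,
            )
            theta0[k] = sample_initial_phases(n, phase_rng)
            noise_rngs.append(noise_rng)
        gamma_phases = _euler_phases(
            theta0, omega, K, n_steps, config.step_s, config.substeps,
            record=np.array(_GAMMA_IDX),
        )
        sig = np.sin(gamma_phases)  # (R, 2, T)
        if config.noise_sigma != 0 or config.noise_mu != 0:
            for k, rng in enumerate(noise_rngs):
                # draw all-channel noise so samples match the sequential path
                noise = rng.normal(config.noise_mu, config.noise_sigma, size=(n, T))
                sig[k] += noise[list(_GAMMA_IDX)]
        if sos is not None:
            sig = sosfiltfilt(sos, sig, axis=-1)
        ph = np.angle(hilbert(sig, axis=-1))
        if n_trim:
            ph = ph[:, :, n_trim:-n_trim]
        out[start : start + R] = _plv_batch(ph[:, 0, :] - ph[:, 1, :])
    return out


def run_condition(
    theta_ibc: float,
    cfc: float,
    replicates: int,
    config: SimulationConfig,
    seed: int | np.random.SeedSequence,
    oscillators: Sequence[OscillatorSpec] | None = None,
    filter_band: tuple[float, float] | None = GAMMA_BAND,
    edge_trim_s: float = 0.5,
    vectorized: bool = True,
) -> PLVSample:
    """Independent replicates of one (theta_ibc, cfc) cell.

    The vectorised engine (default) produces the same PLV vector as
    sequential :func:`run_replicate` calls with the same spawned seeds.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    specs = tuple(oscillators) if oscillators is not None else default_oscillators()
    parent = _as_seedseq(seed)
    seqs = parent.spawn(replicates)
    if vectorized:
        values = _condition_plvs_vectorized(
            theta_ibc, cfc, config, seqs, specs, filter_band, edge_trim_s
        )
    else:
        values = np.array(
            [
                run_replicate(
                    theta_ibc, cfc, config, ss,
                    oscillators=specs, filter_band=filter_band, edge_trim_s=edge_trim_s,
                ).value
                for ss in seqs
            ]
        )
    entropy = parent.entropy if isinstance(parent.entropy, int) else None
    return PLVSample(theta_ibc=theta_ibc, cfc=cfc, plv_values=values, seed_entropy=entropy)


@dataclass
class SweepResult:
    """All per-cell PLV samples of a sweep plus derived summaries."""

    grid: SweepGrid
    samples: dict[tuple[float, float], PLVSample]

    def sample(self, theta_ibc: float, cfc: float) -> PLVSample:
        return self.samples[(float(theta_ibc), float(cfc))]

    def heatmap(self) -> pd.DataFrame:
        """Mean gamma-PLV per cell; rows = CFC levels, columns = theta-IBC levels."""
        data = [
            [self.samples[(ti, cf)].mean for ti in self.grid.theta_ibc_levels]
            for cf in self.grid.cfc_levels
        ]
        return pd.DataFrame(
            data,
            index=pd.Index(self.grid.cfc_levels, name="cfc"),
            columns=pd.Index(self.grid.theta_ibc_levels, name="theta_ibc"),
        )

    def ztest_table(self) -> pd.DataFrame:
        return ztest_series(self)


def _cell_seed(master_seed: int, i: int, j: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(master_seed), spawn_key=(i, j))


def run_sweep(
    grid: SweepGrid,
    checkpoint_dir: str | Path | None = None,
    progress: bool = False,
) -> SweepResult:
    """Run every (theta_ibc, cfc) cell of the grid.

    Each cell gets an independent seed stream derived from
    ``grid.master_seed`` and the cell's grid indices, so results do not
    depend on execution order and interrupted sweeps can resume.  With
    ``checkpoint_dir`` set, each completed cell is saved as a small
    ``.npz`` and replayed from disk on a rerun instead of recomputed.
    """
    ckpt = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt is not None:
        ckpt.mkdir(parents=True, exist_ok=True)
    samples: dict[tuple[float, float], PLVSample] = {}
    for i, cfc in enumerate(grid.cfc_levels):
        for j, theta_ibc in enumerate(grid.theta_ibc_levels):
            key = (float(theta_ibc), float(cfc))
            path = ckpt / f"cell_cfc{i:02d}_ibc{j:02d}.npz" if ckpt is not None else None
            if path is not None and path.exists():
                with np.load(path) as dat:
                    values = dat["plv_values"]
                if values.size != grid.replicates:
                    raise ValueError(
                        f"checkpoint {path.name} has {values.size} replicates, expected {grid.replicates}"
                    )
                samples[key] = PLVSample(
                    theta_ibc=key[0], cfc=key[1], plv_values=values,
                    seed_entropy=grid.master_seed,
                )
            else:
                samples[key] = run_condition(
                    theta_ibc, cfc, grid.replicates, grid.config,
                    _cell_seed(grid.master_seed, i, j),
                    filter_band=grid.filter_band, edge_trim_s=grid.edge_trim_s,
                )
                samples[key].seed_entropy = grid.master_seed
                if path is not None:
                    np.savez_compressed(
                        path, plv_values=samples[key].plv_values,
                        theta_ibc=key[0], cfc=key[1],
                    )
            if progress:
                print(
                    f"cell cfc={cfc:.1f} theta_ibc={theta_ibc:.1f} "
                    f"mean PLV={samples[key].mean:.4f} (seed {grid.master_seed}, key ({i},{j}))",
                    flush=True,
                )
    return SweepResult(grid=grid, samples=samples)


def delta_plv_ztest(sample_high: PLVSample, sample_low: PLVSample) -> ZTestResult:
    """One-sample z-test of paired delta-PLV = PLV_high - PLV_low against 0.

    Replicate k of the high-coupling condition is paired with replicate
    k of the low-coupling condition; z = mean(delta)/(sd(delta)/sqrt(n))
    with the n-1 sample SD, and p is the one-sided upper-tail
    probability 1 - Phi(z).
    """
    if sample_high.n != sample_low.n:
        raise ValueError("replicate counts differ between conditions")
    if sample_high.cfc != sample_low.cfc:
        raise ValueError("conditions must share the same CFC level")
    delta = sample_high.plv_values - sample_low.plv_values
    n = delta.size
    sd = float(delta.std(ddof=1)) if n > 1 else 0.0
    if sd == 0:
        raise ValueError("degenerate delta-PLV sample: zero standard deviation")
    z = float(delta.mean() / (sd / np.sqrt(n)))
    return ZTestResult(
        cfc=float(sample_high.cfc),
        delta_mean=float(delta.mean()),
        delta_sd=sd,
        n=n,
        z=z,
        p_one_sided=float(norm.sf(z)),
    )


def ztest_series(result: SweepResult) -> pd.DataFrame:
    """Delta-PLV z-test per CFC level (theta_ibc = max vs min of the grid)."""
    hi = result.grid.theta_ibc_levels[-1]
    lo = result.grid.theta_ibc_levels[0]
    rows = []
    for cfc in result.grid.cfc_levels:
        zt = delta_plv_ztest(result.sample(hi, cfc), result.sample(lo, cfc))
        rows.append(
            {
                "cfc": zt.cfc,
                "delta_mean": zt.delta_mean,
                "delta_sd": zt.delta_sd,
                "n": zt.n,
                "z": zt.z,
                "p_one_sided": zt.p_one_sided,
            }
        )
    return pd.DataFrame(rows)
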