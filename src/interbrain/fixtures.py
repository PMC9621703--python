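"""Small deterministic fixture datasets for tests and demos.

Everything here is synthetic and tiny (2 s runs, fixed seeds); the
expected PLV values bundled with the fixtures are computed with a naive
per-sample loop, independent of the vectorised implementation in
:mod:`interbrain.observables`.
"""

from __future__ import annotations

import cmath
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import SimulationConfig, default_oscillators
from .experiment import run_replicate

__all__ = ["generate_fixtures", "reference_plv"]

_FIXTURE_SEED = 51423687  # fixed; fixtures are stable across runs


def reference_plv(phase_a, phase_b) -> float:
    """Naive per-sample PLV loop (the test oracle for the vectorised path)."""
    if len(phase_a) != len(phase_b):
        raise ValueError("phase series must have equal length")
    acc = 0j
    for a, b in zip(phase_a, phase_b):
        acc += cmath.exp(1j * (float(a) - float(b)))
    return abs(acc) / len(phase_a)


def _write_phase_pair(path: Path, times, a, b) -> None:
    pd.DataFrame({"time_s": times, "phase_a": a, "phase_b": b}).to_csv(
        path, index=False, float_format="%.12g"
    )


def generate_fixtures(destination: str | Path) -> dict[str, float]:
    """Write the canned fixture runs and their expected PLVs.

    Fixtures
    --------
    ``locked_pair``
        Two identical 40 Hz phase ramps -> PLV exactly 1.
    ``offset_pair``
        Same ramp with a constant pi/3 offset -> PLV exactly 1.
    ``detuned_pair``
        40 vs 40.5 Hz ramps -> PLV given by the constant-detuning
        resultant.
    ``uniform_noise_pair``
        Independent uniform phases -> PLV near 1/sqrt(T).
    ``small_run``
        One full 2 s pipeline replicate (theta_ibc=1, cfc=1) with its
        gamma-PLV.

    Returns the mapping of fixture name to expected PLV, also written
    as ``expected_plv.json``.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    fs = 100.0
    times = np.arange(0, 2.0 + 1e-12, 1.0 / fs)
    expected: dict[str, float] = {}

    ramp = 2 * np.pi * 40.0 * times
    _write_phase_pair(dest / "locked_pair.csv", times, ramp, ramp)
    expected["locked_pair"] = reference_plv(ramp, ramp)

    _write_phase_pair(dest / "offset_pair.csv", times, ramp, ramp + np.pi / 3)
    expected["offset_pair"] = reference_plv(ramp, ramp + np.pi / 3)

    ramp_b = 2 * np.pi * 40.5 * times
    _write_phase_pair(dest / "detuned_pair.csv", times, ramp, ramp_b)
    expected["detuned_pair"] = reference_plv(ramp, ramp_b)

    rng = np.random.default_rng(_FIXTURE_SEED)
    ua = rng.uniform(0, 2 * np.pi, size=times.size)
    ub = rng.uniform(0, 2 * np.pi, size=times.size)
    _write_phase_pair(dest / "uniform_noise_pair.csv", times, ua, ub)
    expected["uniform_noise_pair"] = reference_plv(ua, ub)

    config = SimulationConfig(duration_s=2.0, master_seed=_FIXTURE_SEED)
    result = run_replicate(1.0, 1.0, config, _FIXTURE_SEED, oscillators=default_oscillators())
    expected["small_run"] = result.value
    (dest / "small_run.json").write_text(
        json.dumps(
            {
                "theta_ibc": 1.0,
                "cfc": 1.0,
                "duration_s": 2.0,
                "seed": _FIXTURE_SEED,
                "gamma_plv": result.value,
            },
            indent=2,
        )
        + "\n"
    )

    (dest / "expected_plv.json").write_text(json.dumps(expected, indent=2, sort_keys=True) + "\n")
    return expected
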