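# interbrain

Simulations of how gamma-band (~40 Hz) phase locking can emerge
*between* two brains that never exchange gamma-band signals.

EEG hyperscanning studies report inter-brain coupling (IBC) not only
in slow bands tied to behavioural coordination (theta, alpha) but also
in the gamma band, whose fast transient oscillations cannot plausibly
track interpersonal dynamics directly.  This package implements a
minimal mechanistic account: each brain is a pair of Kuramoto phase
oscillators — theta (6 ± 1 Hz) and gamma (40 ± 1 Hz) — with
within-brain theta-gamma cross-frequency coupling (CFC) and
between-brain theta-theta coupling, and *no* direct gamma-gamma
connection:

    dtheta_i/dt = omega_i(t) + sum_j K_ij sin(theta_j - theta_i)

over the oscillator order (A1, A2, B1, B2), with nonzero K only on
{A1,A2}, {B1,B2} (strength `cfc`) and {A1,B1} (strength `theta_ibc`).
Synthetic "EEG" is built from the phases (sin(theta) plus Gaussian
noise, sigma = 0.6), band-pass filtered, Hilbert-transformed, and the
gamma channels A2/B2 are compared with the phase-locking value

    PLV = (1/T) | sum_t exp(i (theta_A2(t) - theta_B2(t))) | ,

0 for unrelated phases, 1 for a constant relative phase.  A Monte-Carlo
sweep over the 11 × 11 grid of (theta_ibc, cfc) levels (0 to 1 by 0.1,
up to 10,000 replicates of 40 s per cell) and a paired z-test of
ΔPLV = PLV(theta_ibc=1) − PLV(theta_ibc=0) per CFC level quantify when
gamma IBC appears.  The headline behaviour: with cfc = 0 the contrast
is null (any PLV is spurious similarity, not interaction), while for
cfc ≳ 0.3 the contrast is strongly positive — gamma IBC rides on the
theta channel.

The audience is computational/social neuroscientists who want a
transparent, fully reproducible toy model for interpreting (and
stress-testing) inter-brain connectivity measures.

## Worked example

```python
import numpy as np
from interbrain import delta_plv_ztest, protocol_config, run_condition

config = protocol_config()          # 40 s, 10 ms steps, sigma=0.6, per-step kicks
for cfc in (0.0, 0.5):
    low  = run_condition(0.0, cfc, 500, config, np.random.SeedSequence(1, spawn_key=(int(cfc*10), 0)))
    high = run_condition(1.0, cfc, 500, config, np.random.SeedSequence(1, spawn_key=(int(cfc*10), 1)))
    zt = delta_plv_ztest(high, low)
    print(f"cfc={cfc:.1f}: mean gamma-PLV {low.mean:.3f} -> {high.mean:.3f}, "
          f"z={zt.z:.2f}, one-sided p={zt.p_one_sided:.3g}")
```

prints

```
cfc=0.0: mean gamma-PLV 0.029 -> 0.028, z=-0.36, one-sided p=0.641
cfc=0.5: mean gamma-PLV 0.030 -> 0.629, z=38.16, one-sided p=0
```

With no cross-frequency coupling, raising the inter-brain theta
coupling from 0 to 1 leaves the gamma PLV untouched (z within noise).
With cfc = 0.5 the same manipulation moves the mean gamma PLV from
0.03 to 0.63: a decisively positive paired z — inter-brain gamma
coupling produced entirely by theta-band interaction plus within-brain
CFC.

The same experiment from the shell (500 replicates/cell by default,
`--full` for 10,000):

```
interbrain sweep --out-dir sweep_out            # heatmap.csv, ztest.csv/json, manifest.json
interbrain plot --heatmap sweep_out/heatmap.csv # PNG heatmap
interbrain simulate --theta-ibc 1 --cfc 0.5 --seed 1 --out-dir one_run
```

Every output directory carries a `manifest.json` (config, seed,
convention flags) sufficient to reproduce its files byte-for-byte;
interrupted sweeps resume per-cell with `--resume`.

A note on conventions: the unit of the coupling strengths decides the
physics.  The sweep protocol treats the 0-to-1 couplings as per-step
phase kicks (the discrete-time Kuramoto map); under the literal
rad/s ODE reading such couplings are far too weak to bridge the 34 Hz
theta-gamma gap and every contrast is null.  `docs/methods.md` works
through this and the other modelling choices (frequency draws,
filtering, SNR convention) in detail.

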