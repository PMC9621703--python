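# Methods

## The model

Two "brains" (units A and B) are each reduced to a pair of Kuramoto
phase oscillators: a theta oscillator (A1, B1; mean 6 Hz) and a gamma
oscillator (A2, B2; mean 40 Hz).  Phases evolve under 1:1 sine
coupling,

    dtheta_i/dt = omega_i(t) + sum_j K_ij sin(theta_j(t) - theta_i(t)),

with a symmetric coupling matrix over the fixed order (A1, A2, B1, B2)
that has exactly three edges: A1-A2 and B1-B2 (within-unit theta-gamma
cross-frequency coupling, strength `cfc`) and A1-B1 (inter-brain theta
coupling, strength `theta_ibc`).  The gamma oscillators are never
directly connected, so any gamma-band phase locking between the units
is relayed through the theta chain A2 <- A1 <-> B1 -> B2.  Couplings
act instantaneously (no delays), amplitudes are not modelled, and no
n:m coupling term is introduced: a theta and a gamma oscillator
interact through the plain sine of their phase difference.

The measurement chain mimics an EEG hyperscanning analysis.  Each
phase trajectory is mapped to a signal x_i(t) = sin(theta_i(t)) (unit
amplitude; the phase-locking value is insensitive to any fixed
sinusoidal map), iid Gaussian observation noise N(mu=0, sigma=0.6) is
added to every sample, the gamma channels are band-pass filtered
(zero-phase Butterworth order 4, 35-45 Hz by default, with a bypass),
instantaneous phases are taken as the angle of the Hilbert analytic
signal with 0.5 s trimmed at each end, and phase locking between A2
and B2 is quantified by

    PLV = (1/T) | sum_{t=1..T} exp(i (theta_A2(t) - theta_B2(t))) | .

## Integration and the coupling-timescale convention

Integration is forward Euler on a 10 ms grid over 40 s (4,000 steps;
4,001 recorded samples including t=0; sampling rate 100 Hz).  An
optional `substeps` parameter refines the internal step (step_s /
substeps) while recording on the same output grid; the closed-form
oracles in the test suite use substeps=10 (1 ms) because a 40 Hz phase
advances about 2.51 rad per 10 ms step, which is coarse for resolving
continuous-time dynamics.

The unit of the coupling strengths is a genuine modelling choice that
the protocol statement leaves open, and it decides the outcome:

- `coupling_timescale="per_second"` (integrator default): K_ij is a
  rate in rad/s and the Euler update multiplies it by dt.  This is the
  literal ODE reading, and it keeps the textbook two-oscillator
  results exact (locking iff 2K >= |delta omega|; equal-frequency
  phase-difference decay dphi/dt = -2K sin phi).  Under this reading a
  coupling of at most 1 rad/s is negligible against the 2*pi*34 rad/s
  theta-gamma band gap — the induced gamma phase modulation is ~K/(2
  pi 34) ~ 0.005 rad — and even the theta pair (detuning SD sqrt(2)
  Hz, i.e. ~8.9 rad/s) locks in only about 18% of replicates.  We
  verified by direct simulation (both frequency modes, with and
  without the band-pass) that the sweep contrast is then statistically
  null at every CFC level: the gamma-pair detuning is fixed by the
  frequency draws and coupling cannot move it.

- `coupling_timescale="per_step"` (sweep-protocol default,
  `protocol_config()`): K_ij is the phase kick applied per 10 ms
  output step — the standard discrete-time Kuramoto map
  theta_{k+1} = theta_k + dt*omega + K sin(...), equivalent to an ODE
  coupling of K/step_s rad/s.  Kicks of order one per step are strong
  enough for the theta pair to entrain robustly and for the theta
  chain to imprint coherent structure on the gamma phases, so the
  inter-brain gamma contrast emerges: the paired delta-PLV z statistic
  is null at cfc=0 and large, positive and growing for cfc >= 0.3.
  This is the only reading of the printed 0-to-1 coupling levels under
  which the phenomenon the protocol was designed to exhibit exists at
  all, which is why the sweep layer adopts it; the printed coupling
  levels are used verbatim as kick amplitudes, with no rescaling.

Phases are stored unwrapped in radians; omega = 2*pi*f is in rad/s;
wrapping is applied only where a bounded difference is needed.  The
integrator contracts the coupling sum with `einsum` rather than BLAS
so that the floating-point reduction order — and therefore the bitwise
result — does not depend on how many replicates are batched together.
A non-finite phase aborts integration with the offending step named.

## Natural frequencies and randomness

The band means are 6 and 40 Hz with a +/-1 Hz spread.  Two readings of
the spread are provided because the protocol's omega_i(t) notation is
ambiguous:

- `per_run_constant` (default): one draw per oscillator per replicate,
  normal with SD 1 Hz (a `uniform` half-width-1 alternative is
  available).  Draw order is fixed (A1, A2, B1, B2).
- `per_step_jitter`: an independent redraw of every oscillator at
  every 10 ms output step.

The choice matters for the *absolute* PLV level: with per-run-constant
frequencies two unconnected gamma oscillators keep a fixed ~sqrt(2) Hz
detuning and their 40 s PLV is low (~0.03), whereas with per-step
jitter their phase difference is a slow random walk and the PLV floor
is much higher (~0.29) and flat across theta-IBC — the "spurious
coupling" regime in which similarity of unconnected oscillators is
mistaken for inter-brain synchrony.  The delta-PLV contrast, which is
what the z-tests assess, behaves the same way under both readings; the
default follows the constant-per-run reading and the manifest records
which was used.  Absolute PLV levels and the absolute SNR are for the
same reason treated as convention-dependent and are documented, not
asserted: the SNR helper uses the RMS(clean)/RMS(noise) convention
(unit sine against sigma=0.6 gives 20 log10(0.7071/0.6) = 1.43 dB) and
every output manifest names that convention.

Randomness is organised so any replicate is reproducible in isolation:
a master seed spawns one `numpy.random.SeedSequence` per grid cell
(spawn key = grid indices), each cell spawns one child per replicate,
and each replicate spawns three substreams (frequency draws, initial
phases — uniform on [0, 2 pi) — and observation noise).  The
replicate-vectorised engine consumes the same streams in the same
order as the sequential single-replicate path and is tested to produce
identical samples.

## The sweep and the paired z-test

The protocol sweeps theta_ibc and cfc over 0 to 1 in steps of 0.1
(11 x 11 grid) with 10,000 replicates per cell in the full protocol.
Per cell the gamma-PLV distribution is kept; the heatmap reports
per-cell means.  For each cfc level, replicate k at theta_ibc = 1 is
paired with replicate k at theta_ibc = 0 (independent seed streams),
delta_k = PLV_high,k - PLV_low,k, and the one-sample z statistic is

    z = mean(delta) / ( sd(delta) / sqrt(n) ) ,   sd with n-1,

with a one-sided upper-tail p = 1 - Phi(z).  The one-sided convention
is recorded in manifests; no multiple-comparison correction is applied
across cfc levels.  A zero sample SD raises rather than returning an
infinite z.

## Problem sizes used by the test suite

The suite runs the full pipeline at sizes chosen to make its
statistical assertions decisive: 1,000 replicate pairs per condition
for the null (|z| < 3) and incremental-effect (z ordering over cfc
0.3/0.5/0.8) checks, and 500 replicates per cell for the full 11 x 11
heatmap check (corner effect plus flatness of the cfc=0 row within
three pooled standard errors of a difference of means).  The
acceptance script (`scripts/acceptance.py`) runs the full
10,000-replicate protocol for the five reported CFC levels.

## Known limitations

- Phase-only dynamics: no amplitude modulation, so theta-gamma CFC is
  realised as phase-phase interaction rather than the phase-amplitude
  coupling usually reported for real EEG.
- The 1:1 sine coupling between 6 and 40 Hz oscillators has no n:m
  resonance; all cross-band influence is parameterised by the coupling
  timescale discussed above.
- The synthetic signals are stationary narrowband sinusoids in
  Gaussian noise; real EEG is nonstationary, broadband and
  volume-conducted, so passing tests here show internal consistency of
  the model and measurement chain, not properties of empirical
  hyperscanning data.
- Forward Euler at 10 ms is part of the protocol definition, not an
  accuracy choice; quantitative statements about the continuous-time
  system should use `substeps` >= 10.
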