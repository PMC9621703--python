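# Canonical simulation configuration: every key is optional and these
# values are the defaults of the sweep protocol.  Flags override file
# values; file values override built-in defaults.
duration_s: 40.0          # simulated time per replicate (s)
step_s: 0.01              # Euler output step (s) -> 100 Hz sampling
substeps: 1               # internal refinement of the Euler step
noise_sigma: 0.6          # observation-noise SD added to every sample
noise_mu: 0.0
frequency_mode: per_run_constant   # or per_step_jitter
frequency_distribution: normal     # or uniform (spread = half-width)
coupling_timescale: per_step       # or per_second (couplings in rad/s)

# sweep-only keys
replicates: 500
theta_ibc_levels: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
cfc_levels: [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
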