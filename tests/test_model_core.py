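"""Coupling topology, frequency/phase sampling, and the Euler integrator."""

import numpy as np
import pytest

from interbrain import (
    CouplingMatrix,
    IntegrationError,
    OscillatorSpec,
    SimulationConfig,
    build_two_brain_coupling_matrix,
    default_oscillators,
    integrate_kuramoto,
    sample_initial_phases,
    sample_natural_frequencies,
)

TWO_PI = 2 * np.pi


def _two_osc_config(**kw):
    kw.setdefault("duration_s", 40.0)
    kw.setdefault("noise_sigma", 0.0)
    return SimulationConfig(**kw)


class TestCouplingMatrix:
    def test_all_zero_for_absent_coupling(self):
        K = build_two_brain_coupling_matrix(0.0, 0.0)
        assert np.array_equal(K.strengths, np.zeros((4, 4)))

    def test_binary_topology_at_full_strength(self):
        K = build_two_brain_coupling_matrix(1.0, 1.0).strengths
        expected = np.zeros((4, 4))
        for i, j in [(0, 1), (2, 3), (0, 2)]:  # {A1,A2}, {B1,B2}, {A1,B1}
            expected[i, j] = expected[j, i] = 1.0
        assert np.array_equal(K, expected)

    def test_mixed_strengths_placed_on_correct_edges(self):
        K = build_two_brain_coupling_matrix(0.5, 0.3).strengths
        assert K[0, 2] == K[2, 0] == 0.5
        assert K[0, 1] == K[1, 0] == 0.3
        assert K[2, 3] == K[3, 2] == 0.3
        # six structural zeros plus the diagonal
        mask = np.ones((4, 4), bool)
        for i, j in [(0, 1), (1, 0), (2, 3), (3, 2), (0, 2), (2, 0)]:
            mask[i, j] = False
        assert np.all(K[mask] == 0)
        assert np.all(np.diag(K) == 0)

    @pytest.mark.parametrize("theta_ibc,cfc", [(-0.1, 0.0), (0.0, -1.0)])
    def test_negative_strength_rejected(self, theta_ibc, cfc):
        with pytest.raises(ValueError):
            build_two_brain_coupling_matrix(theta_ibc, cfc)

    def test_validation_and_csv_roundtrip(self, tmp_path):
        with pytest.raises(ValueError):
            CouplingMatrix(np.eye(4))  # nonzero diagonal
        K = build_two_brain_coupling_matrix(0.7, 0.2)
        K.to_csv(tmp_path / "K.csv")
        back = CouplingMatrix.from_csv(tmp_path / "K.csv")
        assert np.array_equal(back.strengths, K.strengths)
        assert back.labels == K.labels


class TestFrequencySampling:
    def test_zero_spread_is_exact_band_frequency(self, rng):
        specs = default_oscillators(spread_hz=0.0)
        omega = sample_natural_frequencies(specs, "per_run_constant", rng)
        assert omega == pytest.approx([TWO_PI * 6, TWO_PI * 40, TWO_PI * 6, TWO_PI * 40])
        assert omega[0] == pytest.approx(37.699, abs=1e-3)

    def test_sample_mean_concentrates_on_band_mean(self):
        # SE of the mean of 10,000 draws at SD 1 Hz is 0.01 Hz
        spec = OscillatorSpec("A2", mean_frequency_hz=40.0, frequency_spread_hz=1.0)
        rng = np.random.default_rng(7)
        draws = np.array(
            [sample_natural_frequencies([spec], "per_run_constant", rng)[0] for _ in range(10_000)]
        )
        assert abs(draws.mean() / TWO_PI - 40.0) < 0.05

    def test_fixed_seed_reproduces_draws(self):
        specs = default_oscillators()
        a = sample_natural_frequencies(specs, "per_run_constant", np.random.default_rng(3))
        b = sample_natural_frequencies(specs, "per_run_constant", np.random.default_rng(3))
        assert np.array_equal(a, b)

    def test_jitter_mode_shape_and_stats(self, rng):
        specs = default_oscillators()
        omega = sample_natural_frequencies(specs, "per_step_jitter", rng, n_steps=4000)
        assert omega.shape == (4, 4000)
        f = omega / TWO_PI
        assert f[1].mean() == pytest.approx(40.0, abs=0.1)
        assert f[1].std() == pytest.approx(1.0, abs=0.1)

    def test_uniform_distribution_bounded_by_halfwidth(self, rng):
        specs = default_oscillators()
        omega = sample_natural_frequencies(
            specs, "per_run_constant", rng, distribution="uniform"
        )
        f = omega / TWO_PI
        means = np.array([6.0, 40.0, 6.0, 40.0])
        assert np.all(np.abs(f - means) <= 1.0)

    def test_jitter_requires_n_steps(self, rng):
        with pytest.raises(ValueError):
            sample_natural_frequencies(default_oscillators(), "per_step_jitter", rng)


class TestInitialPhases:
    def test_range_and_determinism(self):
        a = sample_initial_phases(4, np.random.default_rng(5))
        b = sample_initial_phases(4, np.random.default_rng(5))
        assert np.array_equal(a, b)
        assert np.all((a >= 0) & (a < TWO_PI))

    def test_uniformity_by_resultant_length(self, rng):
        phases = sample_initial_phases(10_000, rng)
        resultant = abs(np.mean(np.exp(1j * phases)))
        assert resultant < 0.05  # Rayleigh expectation ~ sqrt(pi/4n) ~ 0.009


class TestIntegrator:
    def test_single_step_euler_update_is_exact(self):
        config = SimulationConfig(duration_s=0.01, step_s=0.01, noise_sigma=0.0)
        traj = integrate_kuramoto(config, np.zeros((1, 1)), np.array([TWO_PI * 6]), np.array([0.0]))
        assert traj.phases[0, 1] == 0.01 * TWO_PI * 6
        assert traj.phases[0, 1] == pytest.approx(0.376991, abs=1e-6)

    def test_zero_coupling_linearity(self, rng):
        config = _two_osc_config(duration_s=10.0)
        omega = TWO_PI * rng.uniform(4, 45, size=4)
        theta0 = rng.uniform(0, TWO_PI, size=4)
        traj = integrate_kuramoto(config, np.zeros((4, 4)), omega, theta0)
        expected = theta0[:, None] + omega[:, None] * traj.times[None, :]
        np.testing.assert_allclose(traj.phases, expected, rtol=0, atol=1e-8)

    def test_equal_frequency_pair_matches_closed_form_decay(self):
        # dphi/dt = -2K sin(phi)  =>  tan(phi/2) = tan(phi0/2) exp(-2Kt)
        K = 0.5
        config = _two_osc_config(duration_s=20.0, substeps=10)  # 1 ms effective step
        Kmat = np.array([[0.0, K], [K, 0.0]])
        omega = np.array([TWO_PI * 6, TWO_PI * 6])
        traj = integrate_kuramoto(config, Kmat, omega, np.array([np.pi / 2, 0.0]))
        phi = traj.phases[0] - traj.phases[1]
        expected = 2 * np.arctan(np.tan(np.pi / 4) * np.exp(-2 * K * traj.times))
        mask = expected > 1e-6  # relative comparison is meaningless at the fixed point
        np.testing.assert_allclose(phi[mask], expected[mask], rtol=0.01)
        assert phi[-1] < 1e-3
        assert np.all(np.diff(phi) < 1e-12)  # monotone decay

    def test_locking_threshold_matches_2k_equals_detuning(self):
        # empirical lock boundary on a K grid brackets K* = |delta omega| / 2
        config = _two_osc_config(substeps=10)
        for delta_f in (0.5, 1.0):
            d_omega = TWO_PI * delta_f
            k_star = d_omega / 2
            k_grid = k_star * np.arange(0.2, 1.7, 0.2)
            locked = []
            for K in k_grid:
                Kmat = np.array([[0.0, K], [K, 0.0]])
                omega = np.array([TWO_PI * 6 + d_omega, TWO_PI * 6])
                traj = integrate_kuramoto(config, Kmat, omega, np.array([0.0, 0.0]))
                phi = traj.phases[0] - traj.phases[1]
                half = phi.size // 2
                locked.append(abs(phi[-1] - phi[half]) < np.pi)
            assert not locked[0] and locked[-1]
            first_locked = k_grid[int(np.argmax(locked))]
            assert abs(first_locked - k_star) <= 0.2 * k_star + 1e-9

    def test_above_threshold_pair_locks_at_arcsin_offset(self):
        d_omega = TWO_PI  # 6 vs 7 Hz
        K = 4.0
        config = _two_osc_config(substeps=10)
        Kmat = np.array([[0.0, K], [K, 0.0]])
        omega = np.array([TWO_PI * 7, TWO_PI * 6])
        traj = integrate_kuramoto(config, Kmat, omega, np.array([0.0, 0.0]))
        phi = traj.phases[0] - traj.phases[1]
        assert abs(phi[-1] - np.arcsin(d_omega / (2 * K))) < 1e-3

    def test_below_threshold_pair_drifts_unbounded(self):
        config = _two_osc_config(substeps=10)
        Kmat = np.array([[0.0, 0.25], [0.25, 0.0]])
        omega = np.array([TWO_PI * 7, TWO_PI * 6])
        traj = integrate_kuramoto(config, Kmat, omega, np.array([0.0, 0.0]))
        phi = traj.phases[0] - traj.phases[1]
        assert phi[-1] - phi[0] > 4 * TWO_PI

    def test_per_step_coupling_is_unscaled_kick(self):
        config = SimulationConfig(
            duration_s=0.01, step_s=0.01, noise_sigma=0.0, coupling_timescale="per_step"
        )
        K = 0.3
        Kmat = np.array([[0.0, K], [K, 0.0]])
        omega = np.array([TWO_PI * 6, TWO_PI * 40])
        theta0 = np.array([0.4, 2.0])
        traj = integrate_kuramoto(config, Kmat, omega, theta0)
        expected = theta0 + 0.01 * omega + K * np.sin(theta0[::-1] - theta0)
        np.testing.assert_allclose(traj.phases[:, 1], expected, rtol=0, atol=1e-12)

    def test_trajectory_is_deterministic_and_finite(self, rng):
        config = _two_osc_config(duration_s=2.0)
        omega = TWO_PI * rng.uniform(4, 45, size=4)
        theta0 = rng.uniform(0, TWO_PI, size=4)
        K = build_two_brain_coupling_matrix(0.6, 0.4)
        a = integrate_kuramoto(config, K, omega, theta0)
        b = integrate_kuramoto(config, K, omega, theta0)
        assert np.array_equal(a.phases, b.phases)
        assert np.all(np.isfinite(a.phases))
        assert a.n_samples == config.n_samples

    def test_phase_increment_bounded_by_drive(self, rng):
        config = _two_osc_config(duration_s=2.0)
        omega = TWO_PI * rng.uniform(4, 45, size=4)
        theta0 = rng.uniform(0, TWO_PI, size=4)
        K = rng.uniform(0, 1, size=(4, 4))
        np.fill_diagonal(K, 0)
        K = (K + K.T) / 2
        traj = integrate_kuramoto(config, K, omega, theta0)
        bound = config.step_s * (np.abs(omega) + K.sum(axis=1)) + 1e-12
        assert np.all(np.abs(np.diff(traj.phases, axis=1)) <= bound[:, None])

    def test_nonfinite_phase_raises_with_step_number(self):
        config = SimulationConfig(duration_s=10.0, step_s=1.0, noise_sigma=0.0)
        with pytest.raises(IntegrationError, match="step"):
            integrate_kuramoto(config, np.zeros((1, 1)), np.array([1e308]), np.array([0.0]))

    def test_dimension_mismatch_rejected(self):
        config = SimulationConfig(duration_s=0.1, step_s=0.01)
        with pytest.raises(ValueError):
            integrate_kuramoto(config, np.zeros((3, 3)), np.zeros(4), np.zeros(4))


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"duration_s": 1.005, "step_s": 0.01},
            {"noise_sigma": -0.1},
            {"substeps": 0},
            {"frequency_mode": "sometimes"},
            {"frequency_distribution": "cauchy"},
            {"coupling_timescale": "per_fortnight"},
            {"time_delays": 0.05},
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)

    def test_default_protocol_shape(self):
        config = SimulationConfig()
        assert config.n_steps == 4000
        assert config.n_samples == 4001
        assert config.sampling_rate_hz == pytest.approx(100.0)
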