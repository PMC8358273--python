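"""Phase dynamics: drift, Euler integration, synchrony and frequency measures."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from colsync.dynamics import (
    OscillatorEnsemble,
    SimulationConfig,
    drift,
    integrate,
    mean_effective_frequency,
    order_parameter,
    simulate_batch,
    trial_seed_sequence,
)
from colsync.network import build_directed, build_uniform
from colsync.tuning import angular_velocity, intrinsic_frequency

TWO_PI = 2 * np.pi


def two_oscillators(f1_hz, f2_hz, K):
    omegas = angular_velocity(np.array([f1_hz, f2_hz]))
    coupling = np.array([[0.0, K], [K, 0.0]])
    return OscillatorEnsemble(omegas=omegas, coupling=coupling)


class TestDrift:
    def test_aligned_phases_give_intrinsic_velocities(self):
        ens = OscillatorEnsemble(omegas=np.array([1.0, 2.0, 3.0]), coupling=build_uniform(25.0))
        assert np.array_equal(drift(np.full(3, 0.7), ens), ens.omegas)

    def test_zero_coupling_gives_intrinsic_velocities(self, rng):
        ens = OscillatorEnsemble(omegas=np.array([5.0, -2.0, 0.3]), coupling=build_uniform(0.0))
        assert np.array_equal(drift(rng.uniform(0, TWO_PI, 3), ens), ens.omegas)

    def test_two_oscillator_quarter_turn(self):
        """Hand evaluation: phases (0, pi/2), omegas 0 -> drift (K/2, -K/2)."""
        K = 6.0
        ens = two_oscillators(0.0, 0.0, K)
        assert drift(np.array([0.0, np.pi / 2]), ens) == pytest.approx([K / 2, -K / 2])

    def test_dimension_mismatch_rejected(self):
        ens = two_oscillators(1.0, 2.0, 1.0)
        with pytest.raises(ValueError):
            drift(np.zeros(3), ens)


class TestOrderParameter:
    def test_aligned_is_one(self):
        assert order_parameter(np.full(5, 1.3)) == pytest.approx(1.0)

    def test_balanced_triple_is_zero(self):
        assert order_parameter(np.array([0.0, TWO_PI / 3, 2 * TWO_PI / 3])) == pytest.approx(0.0, abs=1e-12)

    def test_two_up_one_down_is_one_third(self):
        assert order_parameter(np.array([0.0, 0.0, np.pi])) == pytest.approx(1 / 3)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            order_parameter(np.array([]))

    @given(st.lists(st.floats(-10.0, 10.0), min_size=1, max_size=8))
    def test_bounded_in_unit_interval(self, phases):
        r = order_parameter(np.array(phases))
        assert 0.0 <= r <= 1.0 + 1e-12


class TestIntegrate:
    def test_single_oscillator_linear_phase_growth(self):
        omega = angular_velocity(40.0)
        ens = OscillatorEnsemble(omegas=np.array([omega]), coupling=np.zeros((1, 1)))
        cfg = SimulationConfig(master_seed=0)
        trial = integrate(ens, cfg, initial_phases=np.array([0.25]))
        t = np.arange(cfg.n_steps) * cfg.dt
        assert trial.phases[:, 0] == pytest.approx(0.25 + omega * t, abs=1e-9)
        assert mean_effective_frequency(trial) == pytest.approx([40.0], abs=1e-12)

    def test_step_count_is_duration_over_dt(self):
        ens = two_oscillators(40.0, 40.0, 1.0)
        trial = integrate(ens, SimulationConfig(), initial_phases=np.zeros(2))
        assert trial.phases.shape == (500, 2)
        assert trial.r_trace.shape == (500,)

    def test_identical_oscillators_stay_aligned(self):
        ens = two_oscillators(40.0, 40.0, 8.0)
        trial = integrate(ens, SimulationConfig(), initial_phases=np.array([1.0, 1.0]))
        assert np.array_equal(trial.phases[:, 0], trial.phases[:, 1])
        assert trial.r_trace == pytest.approx(np.ones(500))

    def test_locked_pair_converges_to_mean_frequency(self):
        """Contrasts 50 and 30 under strong coupling: both effective
        frequencies settle at the mean of the intrinsic frequencies."""
        f1, f2 = intrinsic_frequency(50.0), intrinsic_frequency(30.0)
        ens = two_oscillators(f1, f2, 50.0)  # K exceeds |delta omega| = 43.2
        trial = integrate(ens, SimulationConfig(master_seed=2), initial_phases=np.array([0.0, 1.0]))
        f_eff = mean_effective_frequency(trial)
        assert f_eff == pytest.approx([(f1 + f2) / 2] * 2, abs=0.05)
        # once the transient has fully decayed the locked velocities are equal
        f_late = mean_effective_frequency(trial, discard_steps=400)
        assert abs(f_late[0] - f_late[1]) < 1e-6

    def test_zero_detuning_synchronizes_from_random_phases(self, rng):
        omega = angular_velocity(intrinsic_frequency(50.0))
        ens = OscillatorEnsemble(omegas=np.full(3, omega), coupling=build_uniform(10.0))
        for _ in range(5):
            trial = integrate(ens, SimulationConfig(), initial_phases=rng.uniform(0, TWO_PI, 3))
            assert trial.r_trace[-1] > 0.99

    def test_determinism_bit_identical(self):
        ens = two_oscillators(40.0, 35.0, 12.0)
        cfg = SimulationConfig(master_seed=77)
        a = integrate(ens, cfg)
        b = integrate(ens, cfg)
        assert np.array_equal(a.phases, b.phases)
        assert np.array_equal(a.phase_velocities, b.phase_velocities)
        assert a.r_mean == b.r_mean

    def test_noise_is_reproducible_and_excluded_from_velocity(self):
        ens = two_oscillators(40.0, 40.0, 0.0)
        cfg = SimulationConfig(master_seed=5, noise_sd=1.0)
        a = integrate(ens, cfg, initial_phases=np.zeros(2))
        b = integrate(ens, cfg, initial_phases=np.zeros(2))
        assert np.array_equal(a.phases, b.phases)
        # recorded velocities are the deterministic drift: constant here
        assert np.array_equal(a.phase_velocities, np.tile(ens.omegas, (500, 1)))
        # but the noisy phases are not the deterministic straight line
        assert not np.allclose(a.phases[-1], ens.omegas * 499 * cfg.dt)

    def test_discard_exceeding_trace_rejected(self):
        ens = two_oscillators(40.0, 41.0, 1.0)
        trial = integrate(ens, SimulationConfig(master_seed=0))
        with pytest.raises(ValueError):
            mean_effective_frequency(trial, discard_steps=500)


class TestConservation:
    def test_symmetric_coupling_conserves_mean_frequency(self):
        """Sine-coupling antisymmetry: the summed drift equals the summed
        intrinsic velocity at every Euler step for any symmetric matrix."""
        f = intrinsic_frequency(np.array([20.0, 50.0, 80.0]))
        ens = OscillatorEnsemble(omegas=angular_velocity(f), coupling=build_uniform(14.0))
        trial = integrate(ens, SimulationConfig(master_seed=1))
        total = trial.phase_velocities.sum(axis=1)
        assert np.max(np.abs(total - ens.omegas.sum())) / abs(ens.omegas.sum()) < 1e-12

    def test_directed_coupling_breaks_conservation(self):
        f = intrinsic_frequency(np.array([50.0, 30.0, 50.0]))
        ens = OscillatorEnsemble(omegas=angular_velocity(f), coupling=build_directed(14.0, 4.0))
        trial = integrate(ens, SimulationConfig(master_seed=1))
        total = trial.phase_velocities.sum(axis=1)
        assert np.max(np.abs(total - ens.omegas.sum())) / abs(ens.omegas.sum()) > 1e-6


class TestDecoupling:
    def test_zero_K_effective_equals_intrinsic_exactly(self):
        f = intrinsic_frequency(np.array([25.0, 50.0, 75.0]))
        ens = OscillatorEnsemble(omegas=angular_velocity(f), coupling=build_uniform(0.0))
        trial = integrate(ens, SimulationConfig(master_seed=3))
        assert np.max(np.abs(mean_effective_frequency(trial) - f)) < 1e-12


class TestSimulateBatch:
    def test_batch_matches_per_trial_integration(self):
        """The vectorized batch path and the trajectory-recording path are
        independent implementations; they must agree to machine precision."""
        f = intrinsic_frequency(np.array([35.0, 50.0, 35.0]))
        omegas = angular_velocity(f)
        M = build_uniform(9.0)
        cfg = SimulationConfig(n_reps=4, master_seed=11)
        rng = np.random.default_rng(4)
        init = rng.uniform(0, TWO_PI, size=(4, 3))
        r_b, f_b = simulate_batch(np.tile(omegas, (4, 1)), M, cfg, init)
        ens = OscillatorEnsemble(omegas=omegas, coupling=M)
        for b in range(4):
            trial = integrate(ens, cfg, initial_phases=init[b])
            assert trial.r_mean == pytest.approx(r_b[b], abs=1e-12)
            assert mean_effective_frequency(trial) == pytest.approx(f_b[b], abs=1e-12)

    def test_per_trial_coupling_matrices(self):
        omegas = angular_velocity(intrinsic_frequency(np.array([30.0, 50.0, 30.0])))
        cfg = SimulationConfig(n_reps=2, master_seed=0)
        init = np.zeros((2, 3)) + np.array([[0.1, 0.2, 0.3], [0.3, 0.2, 0.1]])
        Ms = np.stack([build_uniform(0.0), build_uniform(40.0)])
        _, f_eff = simulate_batch(np.tile(omegas, (2, 1)), Ms, cfg, init)
        # K=0 trial keeps intrinsic frequencies; K=40 trial pulls them together
        assert f_eff[0] == pytest.approx(omegas / TWO_PI, abs=1e-12)
        assert np.ptp(f_eff[1]) < np.ptp(f_eff[0])

    def test_noise_requires_seed_streams(self):
        cfg = SimulationConfig(n_reps=2, master_seed=0, noise_sd=0.5)
        with pytest.raises(ValueError):
            simulate_batch(np.zeros((2, 2)), np.zeros((2, 2)), cfg, np.zeros((2, 2)))


class TestRThresholdContour:
    def test_order_parameter_contour_sits_above_entrainment_boundary(self):
        """A locked pair at lag phi* has r = cos(phi*/2); r crosses 0.95 at
        K = |d omega| / sin(2 arccos 0.95), well above K = |d omega|."""
        f1, f2 = intrinsic_frequency(50.0), intrinsic_frequency(65.0)
        d_omega = abs(angular_velocity(f2 - f1))
        k_star = d_omega / np.sin(2 * np.arccos(0.95))
        cfg = SimulationConfig(n_reps=8, master_seed=6)
        rng = np.random.default_rng(8)
        for K, expect_above in ((0.85 * k_star, False), (1.15 * k_star, True)):
            init = rng.uniform(0, TWO_PI, size=(cfg.n_reps, 2))
            omegas = np.tile(angular_velocity(np.array([f1, f2])), (cfg.n_reps, 1))
            r, _ = simulate_batch(omegas, np.array([[0.0, K], [K, 0.0]]), cfg, init)
            assert (r.mean() >= 0.95) == expect_above


class TestSeedStreams:
    def test_streams_are_order_insensitive_functions_of_keys(self):
        a = trial_seed_sequence(3, (4, 5), 6).generate_state(4)
        b = trial_seed_sequence(3, (4, 5), 6).generate_state(4)
        c = trial_seed_sequence(3, (4, 5), 7).generate_state(4)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"dt": 0.0},
        {"duration": 0.1, "discard_steps": 99},
        {"n_reps": 0},
        {"noise_sd": -1.0},
    ])
    def test_rejects_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)
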