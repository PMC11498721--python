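"""Simulator loop: perturbation, controller, observer, full-trial behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sfcpitch.kalman import compute_kalman_gain
from sfcpitch.params import ParameterSet, noise_covariances
from sfcpitch.simulate import (
    PerturbationSpec,
    apply_perturbation,
    control_law,
    observer_step,
    simulate_batch,
    simulate_mean_response,
    simulate_trial,
    simulate_trial_reference,
)


class TestApplyPerturbation:
    def test_auditory_addend_inside_window(self):
        y = apply_perturbation(np.array([5.0, 3.0]), 0.1, PerturbationSpec())
        np.testing.assert_allclose(y, [-95.0, 3.0])

    def test_identity_outside_window(self):
        y = apply_perturbation(np.array([5.0, 3.0]), 0.5, PerturbationSpec())
        np.testing.assert_allclose(y, [5.0, 3.0])

    @given(st.floats(0.0, 1.2))
    @settings(max_examples=50, deadline=None)
    def test_zero_magnitude_is_identity_everywhere(self, t):
        y = apply_perturbation(np.array([5.0, 3.0]), t, PerturbationSpec(magnitude=0.0))
        np.testing.assert_allclose(y, [5.0, 3.0])

    def test_window_is_half_open(self):
        pert = PerturbationSpec()
        assert apply_perturbation(np.array([0.0, 0.0]), 0.0, pert)[0] == -100.0
        assert apply_perturbation(np.array([0.0, 0.0]), 0.3999, pert)[0] == -100.0
        assert apply_perturbation(np.array([0.0, 0.0]), 0.400, pert)[0] == 0.0


class TestControlLaw:
    def test_zero_error_zero_command(self):
        assert control_law(np.zeros(3), np.zeros(3), 3.1) == 0.0

    def test_gain_scales_error(self):
        e = np.array([2.0, 0.0, 0.0])
        assert control_law(np.zeros(3), -e, 3.1) == pytest.approx(3.1 * 2.0)
        assert control_law(np.zeros(3), -e, 6.2) == pytest.approx(2 * control_law(np.zeros(3), -e, 3.1))


class TestObserverStep:
    def test_impulse_appears_after_auditory_delay(self, plant, ca_params):
        """A one-frame impulse on auditory feedback enters the state correction
        exactly Δa frames later."""
        K = compute_kalman_gain(plant, noise_covariances(ca_params)).K
        delays = (5, 3)
        n = 12
        fb = np.zeros((n, 2))
        pred = np.zeros((n, 2))
        impulse_frame = 2
        fb[impulse_frame, 0] = 1.0  # prediction history stays 0 → error = 1
        x_est = np.zeros(3)
        corrections = []
        for t in range(n):
            x_new, x_pred = observer_step(x_est, 0.0, fb, pred, K, delays, plant, t)
            corrections.append(x_new - x_pred)
            x_est = np.zeros(3)  # isolate the correction path each step
            pred[t] = 0.0  # keep predictions at zero for the hand-built trace
        hits = [t for t, c in enumerate(corrections) if np.any(c != 0)]
        assert hits == [impulse_frame + delays[0]]
        np.testing.assert_allclose(corrections[impulse_frame + delays[0]], K[:, 0])

    def test_zero_gain_gives_open_loop_prediction(self, plant):
        fb = np.ones((4, 2))
        pred = np.zeros((4, 2))
        prev = np.array([1.0, 0.5, -0.2])
        x_est, x_pred = observer_step(prev, 0.3, fb, pred, np.zeros((3, 2)), (1, 1), plant, 3)
        np.testing.assert_allclose(x_est, x_pred)
        np.testing.assert_allclose(x_pred, plant.Ad @ prev + plant.Bd[:, 0] * 0.3)

    def test_subframe_delay_rejected(self, plant):
        with pytest.raises(ValueError, match="one frame"):
            observer_step(np.zeros(3), 0.0, np.zeros((4, 2)), np.zeros((4, 2)),
                          np.zeros((3, 2)), (0, 1), plant, 3)


class TestSimulateTrial:
    def test_grid_is_300_frames_over_trial(self, ca_params):
        traj = simulate_trial(ca_params, seed=0)
        assert traj.n_frames == 300
        assert traj.dt == pytest.approx(0.004)
        assert traj.t[-1] == pytest.approx(1.196)

    def test_no_perturbation_tiny_noise_stays_flat(self):
        params = ParameterSet(91.5, 15.5, -6.4, 1.0, 3.1)
        traj = simulate_trial(params, PerturbationSpec(magnitude=0.0), seed=3, sigma_q=1e-18)
        assert np.max(np.abs(traj.f_o)) < 0.01

    @pytest.mark.parametrize("group", ["ca", "control"])
    def test_compensation_opposes_downward_shift(self, group, ca_params, control_params):
        """Produced pitch rises above baseline while auditory feedback is
        shifted down by 100 cents."""
        params = ca_params if group == "ca" else control_params
        traj = simulate_trial(params, seed=1)
        window = (traj.t >= 0.0) & (traj.t < 0.4)
        assert traj.f_o[window].mean() > 0
        assert not traj.unstable

    def test_deterministic_given_seed(self, ca_params):
        a = simulate_trial(ca_params, seed=42)
        b = simulate_trial(ca_params, seed=42)
        assert np.array_equal(a.f_o, b.f_o)
        c = simulate_trial(ca_params, seed=43)
        assert not np.array_equal(a.f_o, c.f_o)

    def test_reference_and_batch_paths_agree(self, ca_params):
        ref = simulate_trial_reference(ca_params, seed=9)
        fast = simulate_trial(ca_params, seed=9)
        np.testing.assert_allclose(fast.f_o, ref.f_o, atol=1e-8)

    def test_superposition_in_zero_noise_limit(self, ca_params):
        """The loop is linear: ±100-cent perturbations give mirror responses."""
        params = ParameterSet(91.5, 15.5, -5.6, 1.0, 3.1)
        down = simulate_trial(params, PerturbationSpec(magnitude=-100.0), seed=0, sigma_q=1e-30)
        up = simulate_trial(params, PerturbationSpec(magnitude=+100.0), seed=0, sigma_q=1e-30)
        np.testing.assert_allclose(down.f_o, -up.f_o, atol=1e-6)

    def test_instability_is_flagged_not_raised(self):
        # long somatosensory delay + high gain destabilizes the delayed loop
        params = ParameterSet(91.5, 79.0, -6.4, 0.1, 7.9)
        traj = simulate_trial(params, seed=0)
        assert traj.unstable


class TestMeanResponse:
    def test_se_small_at_ca_inferred_set(self, ca_params):
        _, se = simulate_mean_response(ca_params, n_runs=100, seed=5)
        assert np.max(se) < 0.1

    def test_se_vanishes_without_stochasticity(self, ca_params):
        params = ParameterSet(91.5, 15.5, -12.0, 1.0, 3.1)
        _, se = simulate_mean_response(params, n_runs=10, seed=5, sigma_q=1e-30)
        assert np.max(se) < 1e-10

    def test_se_scales_inverse_sqrt_runs(self, ca_params):
        _, se25 = simulate_mean_response(ca_params, n_runs=25, seed=6)
        _, se100 = simulate_mean_response(ca_params, n_runs=100, seed=7)
        ratio = np.mean(se25) / np.mean(se100)
        assert 1.5 < ratio < 2.5

    def test_requires_two_runs(self, ca_params):
        with pytest.raises(ValueError):
            simulate_mean_response(ca_params, n_runs=1, seed=0)


class TestBatch:
    def test_matches_single_trials(self, ca_params, control_params):
        thetas = np.vstack([ca_params.to_array(), control_params.to_array()])
        f, unstable = simulate_batch(thetas, seed=11)
        assert f.shape == (2, 300)
        assert not unstable.any()

    def test_delay_below_frame_rejected(self):
        theta = np.array([[91.5, 1.0, -5.6, 1.0, 3.1]])
        with pytest.raises(ValueError, match="at least one frame"):
            simulate_batch(theta, seed=0)
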