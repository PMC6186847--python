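"""The scalar-covariance Kalman smoother against its matrix-form oracle."""

import numpy as np
import pytest

import phasesmooth as ps
from oracles import matrix_kalman_filter, matrix_rts_smoother


def _run_both(om, sigma, alpha, T, seed):
    """Run the package smoother and the full-matrix oracle on one draw."""
    _, x = ps.simulate_state_space(om, sigma, alpha, T, seed=seed)
    params = ps.KalmanParams(omega0=om, sigma=sigma, alpha=alpha)
    fr = ps.forward_pass(x, params)
    sr = ps.backward_pass(fr)
    obs2 = np.column_stack([x.real, x.imag])
    B = ps.rotation_matrix(om)
    mu1, p1 = params.initial(x[0])
    m, C, _ = matrix_kalman_filter(
        obs2, B, sigma * np.eye(2), alpha * np.eye(2), np.array([mu1.real, mu1.imag]), p1 * np.eye(2)
    )
    sm, sc = matrix_rts_smoother(m, C, B, sigma * np.eye(2))
    return fr, sr, (m, C), (sm, sc)


class TestForwardPass:
    def test_matches_matrix_oracle(self):
        rng = np.random.default_rng(7)
        for i in range(25):
            om = rng.uniform(0, np.pi)
            sigma, alpha = 10 ** rng.uniform(-3, 0.5, size=2)
            T = int(rng.integers(5, 400))
            fr, _, (m, C), _ = _run_both(om, sigma, alpha, T, seed=100 + i)
            assert np.max(np.abs(fr.filtered_means - m)) < 1e-10
            for t in range(T):
                assert np.max(np.abs(C[t] - fr.filtered_vars[t] * np.eye(2))) < 1e-10

    def test_huge_alpha_follows_pure_prediction(self):
        om = 0.3
        rng = np.random.default_rng(1)
        x = rng.normal(size=200) + 1j * rng.normal(size=200)
        params = ps.KalmanParams(omega0=om, sigma=1.0, alpha=1e12, mu1=1.0 + 0j, p1=1.0)
        fr = ps.forward_pass(x, params)
        assert np.all(fr.gains[1:] < 1e-9)
        expected = np.exp(1j * om * np.arange(200))
        assert np.allclose(fr.filtered_complex, expected, atol=1e-6)

    def test_noiseless_rotation_tracked_with_zero_process_noise(self):
        om = 0.5
        s, x = ps.simulate_state_space(om, 0.0, 0.0, 300, seed=0)
        fr = ps.forward_pass(x, ps.KalmanParams(omega0=om, sigma=0.0, alpha=1e-4, p1=1e-3))
        assert np.max(np.abs(fr.filtered_complex - s)) < 1e-8
        assert fr.filtered_vars[-1] < 1e-6  # p* = 0 when sigma = 0

    def test_riccati_convergence_to_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            sigma, alpha = 10 ** rng.uniform(-2, 1, size=2)
            fr = ps.forward_pass(
                np.ones(1000, complex), ps.KalmanParams(omega0=0.3, sigma=sigma, alpha=alpha)
            )
            p_star = ps.riccati_fixed_point(sigma, alpha)
            assert abs(fr.filtered_vars[-1] - p_star) < 1e-8
            # monotone approach after the first step
            dif = np.diff(fr.filtered_vars[1:])
            assert np.all(dif <= 1e-12) or np.all(dif >= -1e-12)

    def test_gain_bounded_and_variances_positive(self):
        _, x = ps.simulate_state_space(0.7, 0.3, 0.8, 400, seed=2)
        fr = ps.forward_pass(x, ps.KalmanParams(omega0=0.7, sigma=0.3, alpha=0.8))
        assert np.all((fr.gains >= 0) & (fr.gains <= 1))
        assert np.all(fr.filtered_vars > 0)

    def test_explicitly_degenerate_model_rejected(self):
        with pytest.raises(ValueError):
            ps.KalmanParams(omega0=0.3, sigma=0.0, alpha=0.0, p1=0.0)


class TestBackwardPass:
    def test_matches_rts_oracle_and_never_inflates_variance(self):
        rng = np.random.default_rng(8)
        for i in range(25):
            om = rng.uniform(0, np.pi)
            sigma, alpha = 10 ** rng.uniform(-3, 0.5, size=2)
            T = int(rng.integers(5, 400))
            fr, sr, _, (sm, sc) = _run_both(om, sigma, alpha, T, seed=300 + i)
            assert np.max(np.abs(sr.smoothed_means - sm)) < 1e-10
            for t in range(T):
                assert np.max(np.abs(sc[t] - sr.smoothed_vars[t] * np.eye(2))) < 1e-10
            assert np.all(sr.smoothed_vars <= fr.filtered_vars + 1e-15)

    def test_terminal_state_equals_filtered(self):
        _, x = ps.simulate_state_space(0.4, 0.2, 0.5, 150, seed=4)
        fr = ps.forward_pass(x, ps.KalmanParams(omega0=0.4, sigma=0.2, alpha=0.5))
        sr = ps.backward_pass(fr)
        assert np.array_equal(sr.smoothed_means[-1], fr.filtered_means[-1])
        assert sr.smoothed_vars[-1] == fr.filtered_vars[-1]

    def test_zero_process_noise_on_noiseless_rotation_changes_nothing(self):
        s, x = ps.simulate_state_space(0.5, 0.0, 0.0, 200, seed=0)
        fr = ps.forward_pass(x, ps.KalmanParams(omega0=0.5, sigma=0.0, alpha=1e-6, p1=1e-4))
        sr = ps.backward_pass(fr)
        assert np.max(np.abs(sr.smoothed_complex - fr.filtered_complex)) < 1e-7

    def test_identity_in_the_noise_free_limit(self):
        # sigma = alpha = 0: the smoother returns a pure rotation unchanged
        om = 0.37
        z = np.exp(1j * om * np.arange(100))
        fr = ps.forward_pass(z, ps.KalmanParams(omega0=om, sigma=0.0, alpha=0.0))
        sr = ps.backward_pass(fr)
        assert np.max(np.abs(sr.smoothed_complex - z)) < 1e-12

    def test_mismatched_params_rejected(self):
        _, x = ps.simulate_state_space(0.4, 0.2, 0.5, 50, seed=4)
        fr = ps.forward_pass(x, ps.KalmanParams(omega0=0.4, sigma=0.2, alpha=0.5))
        with pytest.raises(ValueError):
            ps.backward_pass(fr, ps.KalmanParams(omega0=0.9, sigma=0.2, alpha=0.5))


class TestEstimateSigma:
    def test_zero_alpha_upper_bound_is_epsilon(self):
        _, x = ps.simulate_state_space(0.3, 0.1, 0.0, 2000, seed=1)
        se = ps.estimate_sigma(x, 0.3, alpha=0.0, beta=1.0)
        assert se.sigma_point == se.epsilon == se.sigma_range[1]

    def test_recovers_known_sigma_from_simulated_model(self):
        sigma_true, alpha_true = 0.04, 0.02
        errs = []
        for seed in range(5):
            _, x = ps.simulate_state_space(0.19, sigma_true, alpha_true, 50_000, seed=seed)
            se = ps.estimate_sigma(x, 0.19, alpha=alpha_true, beta=1.0)
            errs.append(abs((se.epsilon - 2 * alpha_true) - sigma_true) / sigma_true)
        assert max(errs) < 0.10

    def test_beta_zero_selects_zero_sigma(self):
        _, x = ps.simulate_state_space(0.3, 0.1, 0.05, 1000, seed=2)
        se = ps.estimate_sigma(x, 0.3, alpha=0.05, beta=0.0)
        assert se.sigma_point == 0.0
        assert se.sigma_range[1] == se.epsilon

    def test_constant_observations_warn_and_give_zero(self):
        z = np.full(50, 1.0 + 0.5j)
        with pytest.warns(UserWarning):
            se = ps.estimate_sigma(z, 0.0, alpha=0.0)
        assert se.epsilon == 0.0 and se.sigma_range == (0.0, 0.0)


class TestEstimateAlpha:
    def _make_ensemble(self, members, fs=100.0, M=None):
        spec = ps.FilterSpec(fc=10.0, bandwidth=1.0, M=M or len(members))
        sigs = [ps.AnalyticSignal(m, fs=fs) for m in members]
        mean = ps.AnalyticSignal(np.mean(members, axis=0), fs=fs)
        return ps.FilterEnsemble(members=sigs, mean_signal=mean, spec=spec)

    def test_identical_members_give_zero(self):
        base = np.exp(1j * 0.3 * np.arange(100))
        ens = self._make_ensemble([base.copy() for _ in range(4)])
        assert ps.estimate_alpha(ens) == 0.0

    def test_recovers_injected_component_variance(self):
        rng = np.random.default_rng(0)
        base = np.exp(1j * 0.3 * np.arange(4000))
        v = 0.03
        members = [
            base + rng.normal(0, np.sqrt(v), 4000) + 1j * rng.normal(0, np.sqrt(v), 4000)
            for _ in range(40)
        ]
        alpha_hat = ps.estimate_alpha(self._make_ensemble(members))
        assert abs(alpha_hat - v) / v < 0.05

    def test_invariant_under_common_offset(self):
        rng = np.random.default_rng(1)
        members = [rng.normal(size=300) + 1j * rng.normal(size=300) for _ in range(6)]
        e1 = ps.estimate_alpha(self._make_ensemble(members))
        shifted = [m + (3.0 - 2.0j) for m in members]
        e2 = ps.estimate_alpha(self._make_ensemble(shifted))
        assert np.isclose(e1, e2)

    def test_single_member_rejected(self):
        base = np.exp(1j * 0.3 * np.arange(100))
        ens = self._make_ensemble([base])
        with pytest.raises(ValueError):
            ps.estimate_alpha(ens)

    def test_phase_mode_positive_for_perturbed_ensemble(self, tone):
        x = tone(fc=7.4, fs=250.0, duration=6.0)
        ens = ps.ensemble_filter(x, ps.FilterSpec(fc=7.4, bandwidth=2.0, M=8, perturbation_scale=0.02))
        assert ps.estimate_alpha(ens, mode="phase") > 0


class TestSmoothPhase:
    def test_pure_tone_residual_not_roughened(self, tone):
        x = tone(fc=10.0, fs=250.0, duration=8.0)
        spec = ps.FilterSpec(fc=10.0, bandwidth=2.0, M=8, perturbation_scale=0.005, seed=0)
        sr = ps.smooth_phase(x, spec, beta=0.5)
        mask = ps.transient_mask(len(x), x.fs, spec.bandwidth)
        pre = np.ptp(sr.pre_phase.residual[~mask])
        post = np.ptp(sr.smoothed_phase.residual[~mask])
        assert post <= pre + 1e-9

    def test_low_envelope_excursions_reduced_on_synthetic_eeg(self):
        # noisy sinusoid mixture band-passed at 7.6 Hz: residual excursions
        # inside low-envelope windows shrink after smoothing
        lab = ps.generate_synthetic_eeg(
            ps.SyntheticEEGSpec(fs=250.0, duration=12.0, target_snr=0.11, seed=3)
        )
        spec = ps.FilterSpec(fc=7.6, bandwidth=1.0, M=10, perturbation_scale=0.01, seed=0)
        sr = ps.smooth_phase(lab.signal, spec, beta=0.005)
        mask_t = ps.transient_mask(len(lab.signal), 250.0, spec.bandwidth)
        env = sr.pre_phase.envelope
        low = (env < 0.2 * np.median(env[~mask_t]) / 0.63) & ~mask_t  # low-envelope interior
        if low.sum() > 10:
            pre_exc = np.abs(np.diff(sr.pre_phase.residual))[low[1:]].max()
            post_exc = np.abs(np.diff(sr.smoothed_phase.residual))[low[1:]].max()
            assert post_exc < pre_exc

    def test_deterministic_given_seed(self, tone):
        x = tone(fc=10.0, fs=250.0, duration=6.0)
        spec = ps.FilterSpec(fc=10.0, bandwidth=2.0, M=5, perturbation_scale=0.01, seed=4)
        r1 = ps.smooth_phase(x, spec)
        r2 = ps.smooth_phase(x, spec)
        assert np.array_equal(r1.smoothed_means, r2.smoothed_means)
        assert r1.diagnostics == r2.diagnostics

    def test_stage_errors_are_tagged(self, tone):
        x = tone(fc=10.0, fs=250.0, duration=6.0)
        bad = ps.FilterSpec(fc=124.9, bandwidth=4.0, M=2)
        with pytest.raises(RuntimeError, match=r"\[ensemble_filter\]"):
            ps.smooth_phase(x, bad)

    def test_diagnostics_reported(self, tone):
        x = tone(fc=10.0, fs=250.0, duration=6.0)
        sr = ps.smooth_phase(x, ps.FilterSpec(fc=10.0, bandwidth=2.0, M=5), beta=0.3)
        d = sr.diagnostics
        assert set(d) >= {"epsilon", "alpha", "sigma", "sigma_range", "beta", "p_star"}
        assert d["sigma_range"][0] <= d["epsilon"] and d["sigma"] <= d["epsilon"]
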