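"""Information-form filter vs textbook oracles; static (GLS) limit."""

import numpy as np
import pytest

import myokin as mk
from myokin.evaluation import fit_pipeline, pool_trials
from myokin.kalman import (
    KalmanState,
    filter_trajectory,
    predict,
    static_estimate,
    update,
)
from myokin.statespace import StateSpaceModel, make_static


def _random_system(rng, D, m):
    """Random stable system + measurement model of dimension (D states, m obs)."""
    F = rng.standard_normal((D, D)) * 0.3
    F /= max(1.0, 1.1 * np.max(np.abs(np.linalg.eigvals(F))))
    A = rng.standard_normal((D, D))
    Cw = A @ A.T * 0.1 + 0.01 * np.eye(D)
    H = rng.standard_normal((m, D))
    B = rng.standard_normal((m, m))
    R = B @ B.T + 0.1 * np.eye(m)
    return F, Cw, H, R


def _gain_form_step(x, P, F, Cw, H, R, y):
    """Textbook covariance/gain-form Kalman step (independent oracle)."""
    x_pred = F @ x
    P_pred = F @ P @ F.T + Cw
    S = H @ P_pred @ H.T + R
    K = P_pred @ H.T @ np.linalg.inv(S)
    x_post = x_pred + K @ (y - H @ x_pred)
    P_post = (np.eye(len(x)) - K @ H) @ P_pred
    return x_post, P_post


class TestPredict:
    def test_identity_dynamics_keep_state(self, rng):
        D = 3
        C = np.eye(D) * 2.0
        model = StateSpaceModel(order=1, D=D, F1=np.eye(D), Cw1=np.zeros((D, D)))
        s = predict(KalmanState(x_hat=np.ones(D), C=C), model)
        np.testing.assert_allclose(s.x_hat, np.ones(D))
        np.testing.assert_allclose(s.C, C)

    def test_zero_dynamics_reset_to_process_noise(self, rng):
        D = 2
        Cw = np.diag([0.5, 0.7])
        model = StateSpaceModel(order=1, D=D, F1=np.zeros((D, D)), Cw1=Cw)
        s = predict(KalmanState(x_hat=np.ones(D), C=np.eye(D)), model)
        np.testing.assert_allclose(s.x_hat, 0.0)
        np.testing.assert_allclose(s.C, Cw)

    def test_dimension_mismatch_rejected(self):
        model = StateSpaceModel(order=1, D=2, F1=np.eye(2), Cw1=np.eye(2))
        with pytest.raises(ValueError, match="dimension"):
            predict(KalmanState(x_hat=np.zeros(3), C=np.eye(3)), model)


class TestUpdate:
    def test_matches_gain_form_on_random_systems(self, rng):
        """Information form == covariance/gain form over 100 random systems."""
        worst = 0.0
        for _ in range(100):
            D = int(rng.integers(1, 6))
            m = int(rng.integers(D, 12))
            F, Cw, H, R = _random_system(rng, D, m)
            x = rng.standard_normal(D)
            P = np.eye(D)
            model = StateSpaceModel(order=1, D=D, F1=F, Cw1=Cw)
            for _ in range(50):
                y = rng.standard_normal(m)
                s = update(predict(KalmanState(x_hat=x, C=P), model), y, H, R)
                x_ref, P_ref = _gain_form_step(x, P, F, Cw, H, R, y)
                worst = max(
                    worst,
                    np.max(np.abs(s.x_hat - x_ref)),
                    np.max(np.abs(s.C - P_ref)),
                )
                x, P = x_ref, P_ref
        assert worst < 1e-8

    def test_uninformative_measurement_keeps_prior(self, rng):
        D, m = 3, 6
        _, _, H, R = _random_system(rng, D, m)
        prior = KalmanState(x_hat=rng.standard_normal(D), C=np.eye(D))
        s = update(prior, rng.standard_normal(m), H, R * 1e12)
        np.testing.assert_allclose(s.x_hat, prior.x_hat, atol=1e-6)
        np.testing.assert_allclose(s.C, prior.C, atol=1e-6)

    def test_uninformative_prior_returns_measurement(self, rng):
        D = 3
        y = rng.standard_normal(D)
        prior = KalmanState(x_hat=np.zeros(D), C=np.eye(D) * 1e12)
        s = update(prior, y, np.eye(D), np.eye(D))
        np.testing.assert_allclose(s.x_hat, y, atol=1e-6)

    def test_covariance_contracts(self, rng):
        """C(t|t) <= C(t|t-1) in the PSD order."""
        D, m = 4, 8
        _, _, H, R = _random_system(rng, D, m)
        prior = KalmanState(x_hat=np.zeros(D), C=np.eye(D) * 2.0)
        s = update(prior, rng.standard_normal(m), H, R)
        assert np.all(np.linalg.eigvalsh(prior.C - s.C) > -1e-9)

    def test_posterior_trace_monotone_in_measurement_precision(self, rng):
        D, m = 3, 6
        _, _, H, R = _random_system(rng, D, m)
        prior = KalmanState(x_hat=np.zeros(D), C=np.eye(D))
        y = rng.standard_normal(m)
        traces = [
            np.trace(update(prior, y, H, R * s).C) for s in (0.25, 1.0, 4.0, 16.0)
        ]
        assert all(a <= b + 1e-12 for a, b in zip(traces, traces[1:]))


@pytest.fixture(scope="module")
def fitted_noisy(latent_small):
    fts, gt = latent_small
    G, X, bounds = pool_trials(fts, fts.repetitions)
    mm, ssm = fit_pipeline(G, X, bounds, 1, mk.DesignParams(D=4, c_v=0.1, c_w=0.2))
    return fts, gt, mm, ssm


class TestFilterTrajectory:
    def test_zero_noise_recovers_truth(self, latent_noiseless):
        """Exact measurements at D = D_true give sub-micrometre errors."""
        fts, gt = latent_noiseless
        G, X, bounds = pool_trials(fts, fts.repetitions)
        mm, ssm = fit_pipeline(
            G, X, bounds, 1, mk.DesignParams(D=gt.config.D_true, c_v=0.0, c_w=0.0)
        )
        _, X_hat = filter_trajectory(mm, ssm, G, boundaries=bounds)
        assert np.max(np.abs(X_hat - X)) < 1e-3

    def test_causality(self, fitted_noisy, rng):
        """Permuting trailing frames leaves earlier outputs unchanged."""
        fts, _, mm, ssm = fitted_noisy
        G = fts.features[(1, 1)]
        _, X1 = filter_trajectory(mm, ssm, G)
        G2 = G.copy()
        G2[40:] = G2[40:][::-1]
        _, X2 = filter_trajectory(mm, ssm, G2)
        np.testing.assert_allclose(X1[:40], X2[:40], atol=1e-10)

    def test_nan_features_named(self, fitted_noisy):
        fts, _, mm, ssm = fitted_noisy
        G = fts.features[(1, 1)].copy()
        G[7, 3] = np.nan
        with pytest.raises(ValueError, match="frame 7"):
            filter_trajectory(mm, ssm, G)

    def test_high_noise_filter_beats_static(self):
        """With noisy measurements, dynamic filtering outperforms the
        measurement-only (static) estimate."""
        cfg = mk.SynthConfig(
            seed=21, D_true=4, n_instructions=6, n_repetitions=2,
            frames_per_trial=80, measurement_noise=2.0, marker_noise_mm=0.0,
        )
        fts, gt = mk.generate_latent_mode(cfg)
        G, X, bounds = pool_trials(fts, fts.repetitions)
        mm, ssm = fit_pipeline(G, X, bounds, 1, mk.DesignParams(D=4, c_v=0.1, c_w=0.2))
        _, X_dyn = filter_trajectory(mm, ssm, G, boundaries=bounds)
        _, X_sta = filter_trajectory(mm, make_static(ssm), G, boundaries=bounds)
        clean = np.concatenate(
            [gt.clean_markers[k] for r in fts.repetitions for k in
             sorted(k for k in fts.features if k[1] == r)]
        )
        assert mk.rms_error(X_dyn, clean) <= mk.rms_error(X_sta, clean)


class TestStaticEstimate:
    def test_consistency_without_noise(self, fitted_noisy, rng):
        _, _, mm, _ = fitted_noisy
        b = rng.standard_normal(mm.D)
        g_norm = mm.Y_g @ b
        np.testing.assert_allclose(static_estimate(mm, g_norm), b, atol=1e-8)

    def test_identity_noise_reduces_to_ols(self, fitted_noisy, rng):
        from dataclasses import replace

        _, _, mm, _ = fitted_noisy
        mm_id = replace(mm, C_v=np.eye(152))
        g = rng.standard_normal(152)
        ols = np.linalg.lstsq(mm_id.Y_g, g, rcond=None)[0]
        np.testing.assert_allclose(static_estimate(mm_id, g), ols, atol=1e-8)

    def test_agrees_with_static_filter(self, fitted_noisy):
        """make_static + filter == frame-wise GLS within 1e-6."""
        fts, _, mm, ssm = fitted_noisy
        G = fts.features[(2, 1)]
        B_hat, _ = filter_trajectory(mm, make_static(ssm), G)
        gls = static_estimate(mm, mm.normalize_features(G))
        np.testing.assert_allclose(B_hat, gls, atol=1e-6)

    def test_static_filter_idempotent(self, fitted_noisy):
        fts, _, mm, ssm = fitted_noisy
        G = fts.features[(2, 1)]
        _, X1 = filter_trajectory(mm, make_static(ssm), G)
        _, X2 = filter_trajectory(mm, make_static(make_static(ssm)), G)
        np.testing.assert_allclose(X1, X2, atol=1e-9)
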