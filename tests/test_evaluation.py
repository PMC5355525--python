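"""Pooling, cross-validation protocol, design optimisation, Wilcoxon test."""

import itertools

import numpy as np
import pytest

from myokin.datatypes import FeatureTrialSet
from myokin.evaluation import (
    compare_models,
    cross_validate,
    optimize_design,
    pool_trials,
    rms_error,
)
from myokin.statespace import DesignParams


def _grid_fts(rng, n_instructions, n_reps, frames, p=16):
    features = {
        (i, r): rng.standard_normal((frames, p))
        for i in range(1, n_instructions + 1)
        for r in range(1, n_reps + 1)
    }
    markers = {k: rng.standard_normal((frames, 30)) for k in features}
    return FeatureTrialSet(features=features, markers=markers)


class TestPoolTrials:
    def test_reference_protocol_counts(self, rng):
        """19 instructions x 4 repetitions x 100 frames -> 7600 frames and
        75 interior segment boundaries."""
        fts = _grid_fts(rng, 19, 5, 100)
        G, X, bounds = pool_trials(fts, [1, 2, 3, 4])
        assert G.shape[0] == X.shape[0] == 7600
        assert len(bounds) == 75

    def test_single_trial_has_no_boundaries(self, rng):
        fts = _grid_fts(rng, 1, 1, 40)
        _, _, bounds = pool_trials(fts, [1])
        assert bounds == []

    def test_boundaries_strictly_increasing_in_range(self, rng):
        for trial_rng in [np.random.default_rng(s) for s in range(3)]:
            ni, nr = int(trial_rng.integers(2, 6)), int(trial_rng.integers(2, 4))
            frames = int(trial_rng.integers(5, 30))
            fts = _grid_fts(trial_rng, ni, nr, frames)
            G, _, bounds = pool_trials(fts, range(1, nr + 1))
            assert all(b2 > b1 for b1, b2 in zip(bounds, bounds[1:]))
            assert all(0 < b < G.shape[0] for b in bounds)
            assert len(bounds) == ni * nr - 1

    def test_missing_trial_named(self, rng):
        fts = _grid_fts(rng, 3, 2, 10)
        del fts.features[(2, 1)], fts.markers[(2, 1)]
        with pytest.raises(KeyError, match="instruction=2, repetition=1"):
            pool_trials(fts, [1, 2])


class TestRmsError:
    def test_worked_examples(self):
        X = np.zeros((100, 30))
        assert rms_error(X, X) == 0.0
        assert rms_error(X + 1.0, X) == pytest.approx(1.0)
        Y = X.copy()
        Y[0, 0] = 3.0
        assert rms_error(Y, X) == pytest.approx(np.sqrt(9.0 / 3000.0))

    def test_distance_variant(self, rng):
        X = np.zeros((10, 30))
        Y = X.copy()
        Y[:, 0] = 3.0  # one marker offset by 3 mm in x for all frames
        assert rms_error(Y, X, distance=True) == pytest.approx(np.sqrt(9.0 / 10.0))
        assert rms_error(Y, X) == pytest.approx(np.sqrt(9.0 / 30.0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            rms_error(np.zeros((5, 30)), np.zeros((6, 30)))


class TestCrossValidate:
    def test_noiseless_data_reconstructs(self, latent_noiseless):
        fts, gt = latent_noiseless
        res = cross_validate(fts, 1, DesignParams(D=gt.config.D_true, c_v=0.0, c_w=0.0))
        assert res.mean_rms < 0.01
        assert res.mean_rms == pytest.approx(np.mean(res.per_fold_rms))

    def test_fold_errors_permutation_invariant(self, latent_small):
        """Relabelling repetitions permutes the per-fold errors only."""
        fts, _ = latent_small
        relabel = {1: 3, 2: 1, 3: 2}
        fts2 = FeatureTrialSet(
            features={(i, relabel[r]): v for (i, r), v in fts.features.items()},
            markers={(i, relabel[r]): v for (i, r), v in fts.markers.items()},
        )
        d = DesignParams(D=4, c_v=0.1, c_w=0.2)
        r1 = cross_validate(fts, 1, d)
        r2 = cross_validate(fts2, 1, d)
        assert sorted(r1.per_fold_rms) == pytest.approx(sorted(r2.per_fold_rms))

    def test_test_marker_noise_adds_in_quadrature(self, latent_noiseless, rng):
        """Adding 1 mm iid noise to the markers raises the cross-validated
        RMS to ~sqrt(err0^2 + 1) = ~1 mm on noiseless data."""
        fts, gt = latent_noiseless
        noisy = FeatureTrialSet(
            features=dict(fts.features),
            markers={
                k: v + rng.standard_normal(v.shape) for k, v in fts.markers.items()
            },
        )
        d = DesignParams(D=gt.config.D_true, c_v=0.0, c_w=0.0)
        err0 = cross_validate(fts, 1, d).mean_rms
        err1 = cross_validate(noisy, 1, d).mean_rms
        assert err1 == pytest.approx(np.sqrt(err0**2 + 1.0), rel=0.05)

    def test_training_markers_do_not_reach_test_inputs(self, latent_small, monkeypatch):
        """Leakage check: corrupting training-repetition markers leaves the
        feature series handed to the filter for each fold unchanged."""
        import myokin.evaluation as ev

        fts, _ = latent_small
        seen: list[np.ndarray] = []
        orig = ev.filter_trajectory

        def spy(mm, ssm, feats, boundaries=None):
            seen.append(np.array(feats))
            return orig(mm, ssm, feats, boundaries=boundaries)

        monkeypatch.setattr(ev, "filter_trajectory", spy)
        d = DesignParams(D=4, c_v=0.1, c_w=0.2)
        cross_validate(fts, 1, d)
        clean_inputs = [s.copy() for s in seen]
        seen.clear()
        corrupted = FeatureTrialSet(
            features=dict(fts.features),
            markers={
                k: (v + 1e3 if k[1] != 1 else v) for k, v in fts.markers.items()
            },
        )
        cross_validate(corrupted, 1, d)
        # fold 1 holds out repetition 1: its test features must be identical
        np.testing.assert_array_equal(clean_inputs[0], seen[0])

    def test_too_few_repetitions_rejected(self, rng):
        fts = _grid_fts(rng, 2, 1, 30)
        with pytest.raises(ValueError, match="repetition"):
            cross_validate(fts, 1, DesignParams(D=2))


class TestOptimizeDesign:
    @staticmethod
    def _quadratic(design):
        return (
            0.5
            + 0.01 * (design.D - 7) ** 2
            + (design.c_v - 0.3) ** 2
            + (design.c_w - 0.6) ** 2
        )

    def test_recovers_analytic_minimum(self):
        best, res = optimize_design(
            None, 1, bounds={"D": (2, 20)}, objective=self._quadratic
        )
        assert best.D == 7
        assert best.c_v == pytest.approx(0.3, abs=1e-3)
        assert best.c_w == pytest.approx(0.6, abs=1e-3)

    def test_deterministic_evaluation_trajectory(self):
        calls_a, calls_b = [], []

        def make_obj(log):
            def obj(d):
                log.append((d.D, d.c_v, d.c_w))
                return self._quadratic(d)

            return obj

        optimize_design(None, 1, seed=3, objective=make_obj(calls_a))
        optimize_design(None, 1, seed=3, objective=make_obj(calls_b))
        assert calls_a == calls_b

    def test_never_worse_than_initial(self, latent_small):
        fts, _ = latent_small
        init = DesignParams(D=4, c_v=0.1, c_w=0.2)
        score0 = cross_validate(fts, 1, init).mean_rms
        _, res = optimize_design(
            fts, 1, initial=init, bounds={"D": (2, 8)}, max_cycles=1
        )
        assert res.mean_rms <= score0 + 1e-12


class TestCompareModels:
    def test_all_improved_gives_exact_binomial_tail(self):
        a = np.array([2.0, 2.1, 2.2, 2.3, 2.4])
        assert compare_models(a, a - 0.1) == pytest.approx(1.0 / 32.0)

    def test_matches_exhaustive_enumeration(self, rng):
        """Exact p equals brute-force enumeration of all sign patterns."""
        a = rng.standard_normal(7) + 0.5
        b = a - rng.uniform(-0.5, 1.0, size=7)
        d = a - b
        ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
        w_obs = ranks[d > 0].sum()
        count = sum(
            1
            for signs in itertools.product([0, 1], repeat=7)
            if ranks[np.array(signs, dtype=bool)].sum() >= w_obs
        )
        assert compare_models(a, b) == pytest.approx(count / 2**7)

    def test_all_ties_rejected(self):
        a = np.ones(5)
        with pytest.raises(ValueError, match="zero"):
            compare_models(a, a)

    def test_zero_differences_dropped(self):
        a = np.array([2.0, 2.1, 2.2, 2.3, 2.4, 3.0])
        b = np.concatenate([a[:5] - 0.1, [3.0]])
        assert compare_models(a, b) == pytest.approx(1.0 / 32.0)
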