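"""Stimulus regressor, PLS subspace and trial-wise decoding."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from popnoise import (
    ActivityMatrix,
    AnalysisError,
    StimulusKernel,
    build_stimulus_kernel,
    decode_stimulus,
    fit_pls,
    make_gcamp_kernel,
    trial_features,
)
from popnoise.encoding import TrialFeatures
from popnoise.synthetic import TrialSchedule


def _schedule(onsets, sizes, sides, duration=3.0):
    n = len(onsets)
    return TrialSchedule(
        trial_id=np.arange(n),
        size_deg=np.asarray(sizes, dtype=float),
        side=np.asarray(sides),
        onset_s=np.asarray(onsets, dtype=float),
        duration_s=np.full(n, duration),
    )


class TestStimulusKernel:
    def test_single_trial_sign_follows_side(self, frame_kernel):
        for side, sign in (("left", 1.0), ("right", -1.0)):
            sch = _schedule([10.0], [11.0], [side])
            reg = build_stimulus_kernel(sch, frame_kernel, 5.0, 200)
            peak = reg.values[np.argmax(np.abs(reg.values))]
            assert np.sign(peak) == sign
        # amplitude is proportional to the stimulus size
        r11 = build_stimulus_kernel(_schedule([10.0], [11.0], ["left"]), frame_kernel, 5.0, 200)
        r44 = build_stimulus_kernel(_schedule([10.0], [44.0], ["left"]), frame_kernel, 5.0, 200)
        assert np.isclose(np.abs(r44.values).max() / np.abs(r11.values).max(), 4.0)

    def test_zero_outside_trial_support(self, frame_kernel):
        sch = _schedule([10.0], [11.0], ["left"])
        reg = build_stimulus_kernel(sch, frame_kernel, 5.0, 500)
        assert np.all(reg.values[:50] == 0.0)

    def test_superposition(self, frame_kernel):
        a = _schedule([10.0], [4.0], ["left"])
        b = _schedule([12.0], [44.0], ["right"])
        both = _schedule([10.0, 12.0], [4.0, 44.0], ["left", "right"], duration=1.5)
        a.duration_s[:] = 1.5
        b.duration_s[:] = 1.5
        ra = build_stimulus_kernel(a, frame_kernel, 5.0, 300).values
        rb = build_stimulus_kernel(b, frame_kernel, 5.0, 300).values
        rab = build_stimulus_kernel(both, frame_kernel, 5.0, 300).values
        assert np.allclose(rab, ra + rb, atol=1e-12)

    def test_trial_past_recording_truncated(self, frame_kernel):
        sch = _schedule([10.0], [11.0], ["left"])
        reg = build_stimulus_kernel(sch, frame_kernel, 5.0, 52)  # ends mid-trial
        assert reg.values.size == 52


class TestFitPLS:
    def test_perfect_single_neuron_predictor(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(30, 2000))
        target = X[7].copy()
        am = ActivityMatrix(values=X, frame_rate_hz=5.0)
        reg = StimulusKernel(values=target, frame_rate_hz=5.0, sizes_deg=np.array([1.0]))
        model = fit_pls(am, reg, d_max=3, folds=6, repeats=1, seed=0)
        assert np.argmax(np.abs(model.w_opt)) == 7
        pred = model.project(X.T) @ np.linalg.lstsq(model.loadings, model.w_opt, rcond=None)[0]
        # prediction through the latent space correlates essentially
        # perfectly with the regressor
        scores = model.project(X.T)
        w_lat = model.w_opt_latent
        assert abs(np.corrcoef(scores @ w_lat, target)[0, 1]) > 0.999

    def test_planted_direction_recovered_at_high_snr(self):
        from popnoise import fit_bleach_trend, generate_population, generate_trial_schedule, make_ground_truth, normalize_activity

        sch = generate_trial_schedule(90, seed=51)
        truth = make_ground_truth(sch, 300, seed=52)
        am = generate_population(sch, truth, 300, snr=12.0, seed=53)
        norm = normalize_activity(am, fit_bleach_trend(am.values.mean(axis=0), dt_s=0.2))
        reg = build_stimulus_kernel(sch, make_gcamp_kernel(dt_s=0.2), 5.0, norm.n_frames)
        model = fit_pls(norm, reg, d_max=6, folds=6, repeats=1, seed=54)
        angle = np.degrees(np.arccos(abs(model.w_opt @ truth.w_true)))
        assert angle < 10.0

    def test_pure_noise_shows_no_spurious_fit(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 3000))
        y = np.zeros(3000)
        y[::50] = 1.0
        k = make_gcamp_kernel(dt_s=0.2)
        from popnoise.preprocessing import convolve_causal

        y = convolve_causal(y, k)
        am = ActivityMatrix(values=X, frame_rate_hz=5.0)
        reg = StimulusKernel(values=y, frame_rate_hz=5.0, sizes_deg=np.array([1.0]))
        model = fit_pls(am, reg, d_max=5, folds=6, repeats=1, seed=1)
        assert model.cv_mse.min() >= 0.95 * np.var(y)

    def test_training_mse_non_increasing_in_dimensionality(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(40, 1500))
        y = X[:3].sum(axis=0) + 0.5 * rng.normal(size=1500)
        mses = []
        for d in range(1, 6):
            pls = PLSRegression(n_components=d, scale=False).fit(X.T, y)
            mses.append(np.mean((pls.predict(X.T).ravel() - y) ** 2))
        assert np.all(np.diff(mses) <= 1e-9)

    def test_constant_regressor_rejected(self):
        rng = np.random.default_rng(13)
        am = ActivityMatrix(values=rng.normal(size=(10, 500)), frame_rate_hz=5.0)
        reg = StimulusKernel(values=np.ones(500), frame_rate_hz=5.0, sizes_deg=np.array([1.0]))
        with pytest.raises(AnalysisError):
            fit_pls(am, reg, d_max=3)

    def test_latent_basis_is_orthonormal(self, normalized_session):
        act = normalized_session["activity"]
        reg = build_stimulus_kernel(
            normalized_session["schedule"], make_gcamp_kernel(dt_s=0.2), 5.0, act.n_frames
        )
        model = fit_pls(act, reg, d_max=4, folds=6, repeats=1, seed=2)
        G = model.loadings.T @ model.loadings
        assert np.allclose(G, np.eye(model.d), atol=1e-10)


class TestTrialFeatures:
    def test_constant_activity(self):
        am = ActivityMatrix(values=np.full((4, 400), 2.5), frame_rate_hz=5.0)
        sch = _schedule([10.0, 30.0], [4.0, 4.0], ["left", "right"])
        feats = trial_features(am, sch)
        assert np.all(feats.X == 2.5)

    def test_single_frame_window(self):
        rng = np.random.default_rng(14)
        vals = rng.normal(size=(3, 300))
        am = ActivityMatrix(values=vals, frame_rate_hz=5.0)
        sch = _schedule([10.0], [4.0], ["left"], duration=0.2)
        feats = trial_features(am, sch)
        assert np.allclose(feats.X[0], vals[:, 50])

    def test_manual_three_trial_oracle(self):
        vals = np.arange(2 * 100, dtype=float).reshape(2, 100)
        am = ActivityMatrix(values=vals, frame_rate_hz=5.0)
        sch = _schedule([2.0, 8.0, 14.0], [4.0, 11.0, 44.0], ["left", "right", "left"], duration=1.0)
        feats = trial_features(am, sch)
        for ti, onset in enumerate([2.0, 8.0, 14.0]):
            i0 = int(onset * 5)
            assert np.allclose(feats.X[ti], vals[:, i0 : i0 + 5].mean(axis=1))

    def test_empty_window_rejected(self):
        am = ActivityMatrix(values=np.zeros((2, 100)), frame_rate_hz=5.0)
        sch = _schedule([5.0], [4.0], ["left"], duration=0.01)
        with pytest.raises(AnalysisError):
            trial_features(am, sch)


class TestDecodeStimulus:
    def _features(self, X, labels):
        labels = np.asarray(labels)
        sizes = np.array([float(l.split("_")[0]) for l in labels])
        sides = np.array([l.split("_")[1] for l in labels])
        return TrialFeatures(X=X, labels=labels, size_deg=sizes, side=sides)

    def test_separable_classes_decode_perfectly(self):
        rng = np.random.default_rng(15)
        X = rng.normal(0, 0.1, size=(48, 20))
        y = np.array(["4_left"] * 24 + ["4_right"] * 24)
        X[:24, 0] += 3.0
        X[24:, 0] -= 3.0
        res = decode_stimulus(self._features(X, y), folds=6, repeats=1, seed=0)
        assert res.accuracy == 1.0
        assert np.allclose(res.confusion, np.eye(2))

    def test_confusion_rows_are_stochastic(self):
        rng = np.random.default_rng(16)
        X = rng.normal(size=(60, 15))
        y = np.array(["4_left", "4_right", "11_left"] * 20)
        res = decode_stimulus(self._features(X, y), folds=6, repeats=1, seed=1)
        assert np.allclose(res.confusion.sum(axis=1), 1.0, atol=1e-9)

    def test_shuffled_labels_decode_at_chance(self):
        rng = np.random.default_rng(17)
        n = 120
        X = rng.normal(size=(n, 30))
        y = rng.permutation(np.array(["4_left", "4_right"] * (n // 2)))
        res = decode_stimulus(self._features(X, y), folds=6, repeats=2, seed=2)
        # binomial 99% band around 0.5 for n=120 held-out trials
        assert abs(res.accuracy - 0.5) < 2.58 * np.sqrt(0.25 / n) + 0.05

    def test_too_few_trials_per_class_rejected(self):
        X = np.zeros((8, 5))
        y = np.array(["4_left"] * 5 + ["4_right"] * 3)
        with pytest.raises(AnalysisError):
            decode_stimulus(self._features(X, y), folds=6)
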