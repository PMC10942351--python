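"""Trial selection, time warping, window-swept decoding and significance."""

import numpy as np
import pytest

from popnoise import (
    ActivityMatrix,
    AnalysisError,
    ConfigurationError,
    TrialLabels,
    f_score,
    project_trajectories,
    region_distribution,
    region_distribution_report,
    select_trials,
    significant_neurons,
    time_warp,
    window_classify,
)
from popnoise.premotor import WarpedTensor, default_windows
from popnoise.synthetic import TrialSchedule


def _labels(turns, rts):
    turns = np.asarray(turns)
    rts = np.asarray(rts, dtype=float)
    responded = turns != "none"
    rts = np.where(responded, rts, np.nan)
    curv = np.where(turns == "left", 1.0, np.where(turns == "right", -1.0, 0.0))
    return TrialLabels(
        trial_id=np.arange(turns.size),
        responded=responded,
        turn=turns,
        reaction_time_s=rts,
        mean_bout_curvature=curv,
        sigma_active=0.5,
    )


def _schedule(n, gap=12.0, duration=3.0, start=20.0):
    onsets = start + gap * np.arange(n)
    return TrialSchedule(
        trial_id=np.arange(n),
        size_deg=np.full(n, 11.0),
        side=np.array(["left", "right"] * (n // 2 + 1))[:n],
        onset_s=onsets,
        duration_s=np.full(n, duration),
    )


class TestSelectTrials:
    def test_counts_on_toy_labels(self):
        lab = _labels(["left"] * 3 + ["right"] * 3 + ["none"] * 2, [1.5] * 8)
        sets = select_trials(lab, min_rt_s=1.0)
        assert sets["turn"].size == 6
        assert sets["responsive"].size == 6
        assert sets["nonresponsive"].size == 2

    def test_fast_reactions_empty_the_turn_set(self):
        lab = _labels(["left"] * 4 + ["right"] * 4, [0.5] * 8)
        with pytest.raises(AnalysisError):
            select_trials(lab, min_rt_s=1.0)

    def test_matches_hand_filtered_table(self, behavior_session):
        lab = behavior_session["labels"]
        sets = select_trials(lab, min_rt_s=1.0)
        expected = np.flatnonzero(
            lab.responded
            & (lab.reaction_time_s >= 1.0)
            & (np.abs(lab.mean_bout_curvature) > lab.sigma_active)
            & (lab.turn != "none")
        )
        assert np.array_equal(sets["turn"], expected)


class TestTimeWarp:
    def _activity(self, n_neurons=4, T=1200, fs=5.0, fill="ramp"):
        if fill == "ramp":
            vals = np.tile(np.arange(T, dtype=float) / fs, (n_neurons, 1))
        else:
            vals = np.random.default_rng(0).normal(size=(n_neurons, T))
        return ActivityMatrix(values=vals, frame_rate_hz=fs)

    def test_equal_rts_make_middle_segment_identity(self):
        sch = _schedule(8)
        lab = _labels(["left", "right"] * 4, [2.0] * 8)
        act = self._activity(fill="noise")
        tensor = time_warp(act, sch, lab, seed=0)
        fs = act.frame_rate_hz
        for row, i in enumerate(tensor.trial_id):
            onset_f = int(sch.onset_s[i] * fs)
            direct = act.values[:, onset_f + 1 : onset_f + 1 + 10]
            mid = tensor.values[row, :, tensor.stimulus_onset_idx + 1 : tensor.movement_idx + 1]
            assert np.allclose(mid, direct, atol=1e-9)

    def test_linear_signal_stays_linear_in_warped_index(self):
        sch = _schedule(6)
        lab = _labels(["left", "right"] * 3, [1.3, 2.4, 1.9, 2.7, 1.1, 2.2])
        tensor = time_warp(self._activity(), sch, lab, seed=0)
        mid = tensor.values[:, 0, tensor.stimulus_onset_idx : tensor.movement_idx + 1]
        for row in mid:
            diffs = np.diff(row)
            assert np.allclose(diffs, diffs[0], atol=1e-9)

    def test_landmarks_shared_across_random_rts(self):
        rng = np.random.default_rng(30)
        sch = _schedule(12)
        lab = _labels(["left", "right"] * 6, rng.uniform(1.0, 2.8, 12))
        tensor = time_warp(self._activity(fill="noise"), sch, lab, seed=1)
        fs = 5.0
        # the onset landmark samples exactly the onset frame of every trial
        for row, i in enumerate(tensor.trial_id):
            onset_f = int(sch.onset_s[i] * fs)
            assert np.allclose(tensor.values[row, :, tensor.stimulus_onset_idx], self._activity(fill="noise").values[:, onset_f], atol=1e-9)
        assert 0 <= tensor.stimulus_onset_idx < tensor.movement_idx < tensor.n_timepoints

    def test_nonresponsive_trials_get_surrogate_rts(self):
        sch = _schedule(6)
        lab = _labels(["left", "none", "right", "none", "left", "right"], [1.5, np.nan, 2.0, np.nan, 1.8, 2.2])
        tensor = time_warp(self._activity(fill="noise"), sch, lab, seed=2)
        assert tensor.n_trials == 6
        assert np.all(np.isfinite(tensor.reaction_time_s))
        surr = tensor.reaction_time_s[~tensor.responded]
        assert np.all(np.isin(surr, [1.5, 2.0, 1.8, 2.2]))

    def test_rows_follow_schedule_order(self):
        sch = _schedule(6)
        lab = _labels(["left", "right"] * 3, [1.5] * 6)
        tensor = time_warp(self._activity(fill="noise"), sch, lab, seed=0)
        assert np.array_equal(tensor.trial_id, np.arange(6))


class TestFScore:
    @pytest.mark.parametrize(
        "conf,expected",
        [
            ([[10, 0], [0, 10]], 1.0),
            ([[0, 10], [10, 0]], 0.0),
            ([[8, 2], [4, 6]], (8 / 11 + 2 / 3) / 2),
        ],
    )
    def test_hand_arithmetic(self, conf, expected):
        assert np.isclose(f_score(np.array(conf)), expected, atol=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(AnalysisError):
            f_score(np.zeros((2, 2)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            f_score(np.array([[1, -1], [0, 2]]))


def _toy_tensor(n_trials=36, n_neurons=12, L=20, separable=True, seed=0):
    rng = np.random.default_rng(seed)
    turns = np.array(["left", "right"] * (n_trials // 2))
    values = rng.normal(0, 1.0, size=(n_trials, n_neurons, L))
    if separable:
        sgn = np.where(turns == "left", 1.0, -1.0)
        values[:, 0, 8:15] += 4.0 * sgn[:, None]
    return WarpedTensor(
        values=values,
        stimulus_onset_idx=5,
        movement_idx=14,
        frame_rate_hz=5.0,
        trial_id=np.arange(n_trials),
        turn=turns,
        responded=np.ones(n_trials, dtype=bool),
        stimulus_label=np.array(["11_left", "11_right"] * (n_trials // 2)),
        reaction_time_s=np.full(n_trials, 1.8),
        true_reaction_time_s=np.full(n_trials, 1.8),
        dropped_trials=np.array([], dtype=int),
    )


class TestWindowClassify:
    def test_separable_epoch_reaches_perfect_f(self):
        tensor = _toy_tensor(separable=True)
        res = window_classify(tensor, "turn", folds=6, repeats=1, n_label_shuffles=0, seed=0)
        covering = [wi for wi, (s, e) in enumerate(res.windows) if s >= 8 and e <= 14]
        assert max(res.f_mean[wi] for wi in covering) == 1.0

    def test_shuffled_labels_stay_at_chance(self):
        tensor = _toy_tensor(separable=False, seed=3)
        res = window_classify(tensor, "turn", folds=6, repeats=1, n_label_shuffles=0, seed=1)
        assert abs(res.f_mean.mean() - 0.5) < 0.12

    def test_profile_is_max_over_windows_sharing_an_end(self):
        tensor = _toy_tensor(separable=True, seed=4)
        res = window_classify(tensor, "turn", folds=6, repeats=1, n_label_shuffles=0, seed=2)
        for ei, e in enumerate(res.ends):
            best = max(res.f_mean[wi] for wi, (s, we) in enumerate(res.windows) if we == e)
            assert np.isclose(res.profile_f[ei], best)

    def test_adding_candidate_windows_never_lowers_the_profile(self):
        tensor = _toy_tensor(separable=True, seed=5)
        few = window_classify(tensor, "turn", windows=[(0, 10), (4, 10)], folds=6, repeats=1, n_label_shuffles=0, seed=3)
        more = window_classify(
            tensor, "turn", windows=[(0, 10), (4, 10), (6, 10), (8, 10)], folds=6, repeats=1, n_label_shuffles=0, seed=3
        )
        assert more.profile_f[0] >= few.profile_f[0] - 1e-12

    def test_single_class_rejected(self):
        tensor = _toy_tensor()
        tensor.turn[:] = "left"
        with pytest.raises(AnalysisError):
            window_classify(tensor, "turn")

    def test_unknown_task_rejected(self):
        with pytest.raises(ConfigurationError):
            window_classify(_toy_tensor(), "velocity")


class TestSignificantNeurons:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(31)
        coefs = rng.normal(size=(6, 50))
        mask, _ = significant_neurons(coefs, coefs.copy())
        assert not mask.any()

    def test_degenerate_variance_branch(self):
        real = np.ones((6, 3))
        perm = np.zeros((6, 3))
        mask, p = significant_neurons(real, perm)
        assert mask.all() and np.all(p == 0.0)

    def test_type_one_error_controlled_on_null(self):
        rng = np.random.default_rng(32)
        n = 4000
        real = rng.normal(size=(6, n))
        perm = rng.normal(size=(60, n))
        mask, _ = significant_neurons(real, perm)
        se = np.sqrt(0.05 * 0.95 / n)
        assert mask.mean() <= 0.05 + 2 * se

    def test_planted_neurons_detected(self):
        rng = np.random.default_rng(33)
        real = rng.normal(size=(6, 100))
        perm = rng.normal(size=(60, 100))
        real[:, [5, 50]] += 5.0
        mask, _ = significant_neurons(real, perm)
        assert mask[5] and mask[50]


class TestRegionDistribution:
    def test_concentrated_and_sum(self):
        regions = np.array(["Tel"] * 5 + ["Tec"] * 5 + ["Cer"] * 5 + ["Hind"] * 5)
        mask = regions == "Tec"
        pct = region_distribution(mask, regions)
        assert pct == {"Tel": 0.0, "Tec": 100.0, "Cer": 0.0, "Hind": 0.0}
        rng = np.random.default_rng(34)
        mask2 = rng.random(20) < 0.5
        if mask2.any():
            assert np.isclose(sum(region_distribution(mask2, regions).values()), 100.0, atol=1e-9)

    def test_uniform_null_shows_no_pairwise_difference(self):
        rng = np.random.default_rng(35)
        regions = np.repeat(["Tel", "Tec", "Cer", "Hind"], 100)
        masks, region_lists = [], []
        for _ in range(20):
            masks.append(rng.random(400) < 0.2)
            region_lists.append(regions)
        _, pvals = region_distribution_report(masks, region_lists)
        assert sum(p < 0.05 for p in pvals.values()) <= 1

    def test_empty_mask_rejected(self):
        with pytest.raises(AnalysisError):
            region_distribution(np.zeros(8, dtype=bool), np.array(["Tel"] * 8))


class TestProjectTrajectories:
    def test_zero_activity_gives_zero_trajectories(self):
        tensor = _toy_tensor()
        tensor.values[:] = 0.0
        traj, avg = project_trajectories(tensor, np.ones(12), np.ones(12))
        assert np.all(traj == 0.0)

    def test_planted_left_right_ramps_separate_in_sign(self):
        tensor = _toy_tensor(separable=True, seed=6)
        axis = np.zeros(12)
        axis[0] = 1.0
        traj, avg = project_trajectories(tensor, axis, axis)
        sep = avg["left"][8:15, 0] - avg["right"][8:15, 0]
        assert np.all(sep > 0)

    def test_zero_axis_rejected(self):
        with pytest.raises(AnalysisError):
            project_trajectories(_toy_tensor(), np.zeros(12), np.ones(12))
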