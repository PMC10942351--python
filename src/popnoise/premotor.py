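"""Time-warped single-trial decoding of turn direction, responsiveness and
stimulus identity.

Reaction times vary across trials, so each trial is time-warped to align
the stimulus onset and movement-initiation landmarks: a pre-stimulus
segment sampled at the native rate, a stimulus-to-movement segment
linearly resampled to a fixed number of points, and a post-movement
segment at the native rate.  Lasso-logistic classifiers are trained on
activity averaged over a grid of (start, end) windows of warped time;
predictability at a timepoint is the best window ending there, and is
compared against label-shuffled models.  Neurons with reliably larger
|coefficients| than shuffled-label models (one-tailed t-test, p < 0.05)
form the significant ensemble, whose anatomical spread is summarized per
brain region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import RepeatedStratifiedKFold

from .behavior import TrialLabels
from .encoding import fit_lasso_logistic, lasso_coefs
from .errors import AnalysisError, ConfigurationError
from .preprocessing import REGIONS, ActivityMatrix
from .synthetic import TrialSchedule

log = logging.getLogger("popnoise.premotor")

TASKS = ("turn", "responsiveness", "stimulus")


@dataclass
class WarpedTensor:
    """trials x neurons x warped-time array with aligned landmarks."""

    values: np.ndarray
    stimulus_onset_idx: int
    movement_idx: int
    frame_rate_hz: float
    trial_id: np.ndarray
    turn: np.ndarray
    responded: np.ndarray
    stimulus_label: np.ndarray
    reaction_time_s: np.ndarray  # surrogate RT filled in for non-responders
    true_reaction_time_s: np.ndarray  # NaN for non-responders
    dropped_trials: np.ndarray

    def __post_init__(self) -> None:
        if not (0 <= self.stimulus_onset_idx < self.movement_idx < self.values.shape[2]):
            raise ConfigurationError("landmarks must be strictly ordered within the warped grid")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[2]


@dataclass
class WindowResult:
    task: str
    classes: np.ndarray
    windows: list
    f_mean: np.ndarray  # (windows,)
    f_folds: np.ndarray  # (windows, splits)
    acc_mean: np.ndarray
    shuffled_f_mean: np.ndarray  # (windows,) averaged over shuffles
    shuffled_f_folds: np.ndarray  # (windows, splits) averaged over shuffles
    ends: np.ndarray
    profile_f: np.ndarray  # best window ending at each end point
    profile_window: list
    profile_shuffled_f: np.ndarray
    profile_p: np.ndarray  # paired one-tailed t across CV splits
    best_window: tuple
    best_f: float
    best_confusion: np.ndarray  # row-stochastic
    best_coefs: np.ndarray  # (splits, neurons), signed, class order = classes
    best_intercepts: np.ndarray
    shuffled_best_coefs: np.ndarray  # (shuffles*splits, neurons)


def select_trials(labels: TrialLabels, min_rt_s: float = 1.0, sigma_active: float | None = None) -> dict:
    """Index sets for the three classification tasks.

    Turn trials are responsive trials with reaction time >= ``min_rt_s``
    (enough pre-motor data) and |mean bout curvature| > sigma_active (a
    clear left/right turn rather than forward locomotion); responsiveness
    uses all trials; stimulus pooling uses all trials of every size.
    """
    sig = labels.sigma_active if sigma_active is None else sigma_active
    resp = np.asarray(labels.responded, dtype=bool)
    rt = np.asarray(labels.reaction_time_s, dtype=float)
    curv = np.asarray(labels.mean_bout_curvature, dtype=float)
    turn_set = np.flatnonzero(resp & (rt >= min_rt_s) & (np.abs(curv) > sig) & (np.asarray(labels.turn) != "none"))
    if turn_set.size == 0:
        raise AnalysisError("turn-direction set is empty after reaction-time and curvature selection")
    return {
        "turn": turn_set,
        "responsive": np.flatnonzero(resp),
        "nonresponsive": np.flatnonzero(~resp),
        "all": np.arange(labels.n_trials),
    }


def time_warp(
    activity: ActivityMatrix,
    schedule: TrialSchedule,
    labels: TrialLabels,
    t_pre_s: float = 4.0,
    t_post_s: float = 2.0,
    n_mid: int | None = None,
    seed: int = 0,
) -> WarpedTensor:
    """Align stimulus onset and movement initiation across trials.

    The warped grid has ``n_pre`` native-rate points ending at the onset,
    ``n_mid`` points linearly spanning (onset, onset + RT] (default: the
    median responsive reaction time at the frame rate), and ``n_post``
    native-rate points after the movement.  Non-responsive trials receive
    a surrogate reaction time drawn (seeded) from the responsive
    distribution; trials whose middle segment would span fewer than two
    frames, or that fall outside the recording, are dropped and logged.
    """
    fs = activity.frame_rate_hz
    rt_true = np.asarray(labels.reaction_time_s, dtype=float)
    resp_rts = rt_true[np.isfinite(rt_true)]
    if resp_rts.size == 0:
        raise AnalysisError("no responsive trials: cannot define the warp grid")
    if n_mid is None:
        n_mid = max(2, int(round(np.median(resp_rts) * fs)))
    rng = np.random.default_rng(seed)
    rt = rt_true.copy()
    missing = ~np.isfinite(rt)
    rt[missing] = rng.choice(resp_rts, size=int(missing.sum()), replace=True)

    n_pre = int(round(t_pre_s * fs)) + 1
    n_post = int(round(t_post_s * fs))
    L = n_pre + n_mid + n_post
    onset_idx = n_pre - 1
    movement_idx = n_pre - 1 + n_mid

    kept, rows = [], []
    times = np.arange(activity.n_frames) / fs
    for i in range(schedule.n_trials):
        if rt[i] * fs < 2:
            log.info("trial %d dropped: reaction time below two frames", i)
            continue
        onset = schedule.onset_s[i]
        move = onset + rt[i]
        tq = np.concatenate(
            [
                onset + (np.arange(n_pre) - (n_pre - 1)) / fs,
                onset + rt[i] * np.arange(1, n_mid + 1) / n_mid,
                move + np.arange(1, n_post + 1) / fs,
            ]
        )
        if tq[0] < 0 or tq[-1] > times[-1]:
            log.info("trial %d dropped: warp window outside the recording", i)
            continue
        pos = tq * fs
        i0 = np.clip(np.floor(pos).astype(int), 0, activity.n_frames - 2)
        w = pos - i0
        rows.append(activity.values[:, i0] * (1 - w) + activity.values[:, i0 + 1] * w)
        kept.append(i)
    if not rows:
        raise AnalysisError("no trials survived time-warping")
    kept = np.asarray(kept, dtype=int)
    dropped = np.setdiff1d(np.arange(schedule.n_trials), kept)
    return WarpedTensor(
        values=np.asarray(rows),
        stimulus_onset_idx=onset_idx,
        movement_idx=movement_idx,
        frame_rate_hz=fs,
        trial_id=np.asarray(schedule.trial_id)[kept],
        turn=np.asarray(labels.turn)[kept],
        responded=np.asarray(labels.responded)[kept],
        stimulus_label=schedule.class_labels[kept],
        reaction_time_s=rt[kept],
        true_reaction_time_s=rt_true[kept],
        dropped_trials=dropped,
    )


def f_score(confusion: np.ndarray) -> float:
    """Macro-averaged F score from a confusion-count matrix.

    Per class, F = 2PR / (P + R) with F = 0 when P + R = 0; the macro mean
    runs over all classes.
    """
    M = np.asarray(confusion, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ConfigurationError("confusion must be square")
    if np.any(M < 0):
        raise ConfigurationError("confusion counts must be non-negative")
    if M.sum() == 0:
        raise AnalysisError("all-zero confusion matrix")
    tp = np.diag(M)
    col = M.sum(axis=0)
    row = M.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(col > 0, tp / np.where(col > 0, col, 1), 0.0)
        R = np.where(row > 0, tp / np.where(row > 0, row, 1), 0.0)
        F = np.where(P + R > 0, 2 * P * R / np.where(P + R > 0, P + R, 1), 0.0)
    return float(F.mean())


def _task_labels(tensor: WarpedTensor, task: str, min_rt_s: float = 0.0):
    if task == "turn":
        keep = np.flatnonzero((tensor.turn != "none") & (tensor.reaction_time_s >= min_rt_s))
        y = tensor.turn[keep]
    elif task == "responsiveness":
        keep = np.arange(tensor.n_trials)
        y = np.where(tensor.responded, "resp", "nonresp")
    elif task == "stimulus":
        keep = np.arange(tensor.n_trials)
        y = tensor.stimulus_label
    else:
        raise ConfigurationError(f"unknown task {task!r}; expected one of {TASKS}")
    return np.asarray(y), keep


def default_windows(n_timepoints: int, start_step: int = 4, end_step: int = 2, min_len: int = 2):
    """All (start, end) index pairs on a coarse grid, end exclusive-ish:
    windows average warped indices start..end inclusive."""
    ends = np.arange(min_len, n_timepoints, end_step)
    windows = []
    for e in ends:
        for s in range(0, e - min_len + 1, start_step):
            windows.append((int(s), int(e)))
    return windows


def _cv_window_scores(F, y, splits, reg_grid):
    """Best-regularization CV metrics for one window's features.

    Returns (f per split, acc per split, confusion counts, coefs per
    split, intercepts) at the regularization with the best mean F.
    """
    classes = np.unique(y)
    best = None
    for C in reg_grid:
        fs_, accs, confs, coefs, icepts = [], [], [], [], []
        for tr, te in splits:
            clf = fit_lasso_logistic(F[tr], y[tr], C)
            cm = confusion_matrix(y[te], clf.predict(F[te]), labels=classes)
            fs_.append(f_score(cm))
            accs.append(np.trace(cm) / cm.sum())
            confs.append(cm)
            W, b = lasso_coefs(clf)
            coefs.append(W)
            icepts.append(b)
        mean_f = float(np.mean(fs_))
        if best is None or mean_f > best[0]:
            best = (mean_f, np.asarray(fs_), np.asarray(accs), np.sum(confs, axis=0), np.asarray(coefs), np.asarray(icepts))
    return best[1], best[2], best[3], best[4], best[5]


def window_classify(
    tensor: WarpedTensor,
    task: str,
    windows: list | None = None,
    folds: int = 6,
    repeats: int = 3,
    reg_grid=(0.1, 1.0, 10.0),
    n_label_shuffles: int = 10,
    seed: int = 0,
    min_rt_s: float = 0.0,
    start_step: int = 4,
    end_step: int = 2,
) -> WindowResult:
    """Sweep integration windows and classify single-trial behavior.

    For every window, per-trial features are the mean warped activity over
    the window; stratified 6-fold x 3 CV yields macro-F, accuracy and a
    confusion matrix, with the regularization re-swept per window.  The
    identical procedure runs on ``n_label_shuffles`` label permutations
    (regularization re-swept per shuffle, conservatively).  The
    best-window-ending-at-t profile and a per-endpoint paired one-tailed
    t-test (real vs shuffled F across CV splits) summarize when behavior
    becomes decodable.  Coefficients (real and shuffled) are kept for the
    overall best window for downstream significant-neuron analysis.
    """
    y, keep = _task_labels(tensor, task, min_rt_s=min_rt_s)
    V = tensor.values[keep]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise AnalysisError(f"task {task}: only one class present")
    if counts.min() < folds:
        raise AnalysisError(f"task {task}: class {classes[np.argmin(counts)]} has {counts.min()} < folds={folds} trials")
    if windows is None:
        windows = default_windows(tensor.n_timepoints, start_step=start_step, end_step=end_step)
    for s, e in windows:
        if not (0 <= s < e < tensor.n_timepoints):
            raise ConfigurationError(f"window ({s}, {e}) outside the warped grid")
    csum = np.concatenate([np.zeros((V.shape[0], V.shape[1], 1)), np.cumsum(V, axis=2)], axis=2)

    def feats(s, e):
        return (csum[:, :, e + 1] - csum[:, :, s]) / (e + 1 - s)

    rng = np.random.default_rng(seed)
    reg_grid = np.asarray(reg_grid, dtype=float)

    def run(y_run, cv_seed):
        cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=cv_seed)
        splits = list(cv.split(np.zeros(len(y_run)), y_run))
        n_splits = len(splits)
        f_folds = np.zeros((len(windows), n_splits))
        accs = np.zeros(len(windows))
        confs, coefs, icepts = [], [], []
        for wi, (s, e) in enumerate(windows):
            fvals, avals, cm, W, b = _cv_window_scores(feats(s, e), y_run, splits, reg_grid)
            f_folds[wi] = fvals
            accs[wi] = avals.mean()
            confs.append(cm)
            coefs.append(W)
            icepts.append(b)
        return f_folds, accs, confs, coefs, icepts

    f_folds, accs, confs, coefs, icepts = run(y, cv_seed=seed)
    f_mean = f_folds.mean(axis=1)

    # pre-motor model: best window ending at (or nearest before) the
    # movement landmark — the window whose coefficients generalize to
    # spontaneous movements
    all_ends = np.unique([e for _, e in windows])
    move_ends = [e for e in all_ends if e <= tensor.movement_idx]
    pm_end = move_ends[-1] if move_ends else all_ends[0]
    pm_wis = [wi for wi, (s, e) in enumerate(windows) if e == pm_end]
    best_wi = max(pm_wis, key=lambda wi: f_mean[wi])

    shuf_fold_list = []  # per shuffle: (windows, splits)
    shuf_coefs_all = []
    for si in range(n_label_shuffles):
        y_s = rng.permutation(y)
        sf, _, _, scoefs, _ = run(y_s, cv_seed=seed + 7919 * (si + 1))
        shuf_fold_list.append(sf)
        shuf_coefs_all.append(scoefs[best_wi])
    shuf_folds = np.mean(shuf_fold_list, axis=0) if shuf_fold_list else np.zeros_like(f_folds)
    shuf_mean = shuf_folds.mean(axis=1)

    # best-window-ending-at-t profiles; each shuffle selects its own best
    # window so the maximization bias is identical for data and null
    ends = np.unique([e for _, e in windows])
    profile_f = np.full(ends.size, -np.inf)
    profile_windows = [None] * ends.size
    profile_shuf = np.zeros(ends.size)
    profile_p = np.ones(ends.size)
    for ei, e in enumerate(ends):
        wis = [wi for wi, (s, we) in enumerate(windows) if we == e]
        best = max(wis, key=lambda wi: f_mean[wi])
        profile_f[ei] = f_mean[best]
        profile_windows[ei] = windows[best]
        if shuf_fold_list:
            per_shuffle_best = []
            for sf in shuf_fold_list:
                sbest = max(wis, key=lambda wi: sf[wi].mean())
                per_shuffle_best.append(sf[sbest])
            shuf_best_folds = np.mean(per_shuffle_best, axis=0)
            profile_shuf[ei] = float(shuf_best_folds.mean())
            diff = f_folds[best] - shuf_best_folds
            if np.allclose(diff.std(), 0):
                profile_p[ei] = 1.0 if diff.mean() <= 0 else 0.0
            else:
                profile_p[ei] = float(stats.ttest_rel(f_folds[best], shuf_best_folds, alternative="greater").pvalue)

    # signed per-split coefficient vector for the "positive" (last) class
    best_conf = confs[best_wi].astype(float)
    rowsum = best_conf.sum(axis=1, keepdims=True)
    best_conf_norm = best_conf / np.where(rowsum > 0, rowsum, 1.0)
    best_coefs = coefs[best_wi][:, -1, :]
    shuf_best = (
        np.concatenate([W[:, -1, :] for W in shuf_coefs_all], axis=0)
        if shuf_coefs_all
        else np.empty((0, V.shape[1]))
    )
    return WindowResult(
        task=task,
        classes=classes,
        windows=windows,
        f_mean=f_mean,
        f_folds=f_folds,
        acc_mean=accs,
        shuffled_f_mean=shuf_mean,
        shuffled_f_folds=shuf_folds,
        ends=ends,
        profile_f=profile_f,
        profile_window=profile_windows,
        profile_shuffled_f=profile_shuf,
        profile_p=profile_p,
        best_window=windows[best_wi],
        best_f=float(f_mean[best_wi]),
        best_confusion=best_conf_norm,
        best_coefs=best_coefs,
        best_intercepts=icepts[best_wi][:, -1],
        shuffled_best_coefs=shuf_best,
    )


def significant_neurons(real_coefs: np.ndarray, permuted_coefs: np.ndarray, alpha: float = 0.05):
    """One-tailed two-sample t-test per neuron: real |coefs| > permuted.

    Returns (mask, p-values).  Neurons with all-zero coefficients in both
    sets are never significant; a strictly larger real mean with zero
    variance in both sets counts as significant (p = 0).
    """
    R = np.abs(np.asarray(real_coefs, dtype=float))
    P = np.abs(np.asarray(permuted_coefs, dtype=float))
    if R.ndim != 2 or P.ndim != 2 or R.shape[1] != P.shape[1]:
        raise ConfigurationError("coefficient sets must be (folds, neurons) with matching neuron count")
    if R.shape[0] < 2 or P.shape[0] < 2:
        raise ConfigurationError("need at least 2 folds in each coefficient set")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(R, P, axis=0, equal_var=False, alternative="greater")
        p = np.asarray(res.pvalue)
    degenerate = ~np.isfinite(p)
    if np.any(degenerate):
        mr, mp = R.mean(axis=0), P.mean(axis=0)
        p = np.where(degenerate, np.where(mr > mp, 0.0, 1.0), p)
    mask = (p < alpha) & ~np.all(R == 0, axis=0)
    return mask, p


def region_distribution(mask: np.ndarray, regions: np.ndarray) -> dict:
    """Percentage of significant neurons in each brain region."""
    mask = np.asarray(mask, dtype=bool)
    regions = np.asarray(regions)
    if not np.any(mask):
        raise AnalysisError("no significant neurons: region distribution undefined")
    unknown = set(np.unique(regions)) - set(REGIONS)
    if unknown:
        raise ConfigurationError(f"unknown region labels: {unknown}")
    total = mask.sum()
    return {r: 100.0 * np.sum(mask & (regions == r)) / total for r in REGIONS}


def region_distribution_report(masks, regions_list):
    """Per-replicate region percentages and pairwise paired t-tests.

    ``masks`` / ``regions_list`` are parallel sequences over replicates
    (synthetic fish).  Returns (percentages array [replicates x regions],
    {(region_i, region_j): p-value}).
    """
    pct = np.array([[region_distribution(m, r)[reg] for reg in REGIONS] for m, r in zip(masks, regions_list)])
    pvals = {}
    for i in range(len(REGIONS)):
        for j in range(i + 1, len(REGIONS)):
            d = pct[:, i] - pct[:, j]
            if np.allclose(d.std(), 0):
                pvals[(REGIONS[i], REGIONS[j])] = 1.0
            else:
                pvals[(REGIONS[i], REGIONS[j])] = float(stats.ttest_rel(pct[:, i], pct[:, j]).pvalue)
    return pct, pvals


def project_trajectories(tensor: WarpedTensor, turn_axis: np.ndarray, resp_axis: np.ndarray):
    """Project every warped trial onto the turn and responsiveness axes.

    Returns (trajectories [trials x time x 2], class-averaged
    trajectories keyed by 'left'/'right'/'resp'/'nonresp').
    """
    ta = np.asarray(turn_axis, dtype=float)
    ra = np.asarray(resp_axis, dtype=float)
    if not np.any(ta) or not np.any(ra):
        raise AnalysisError("projection axes must be nonzero")
    traj = np.stack([np.einsum("int,n->it", tensor.values, ta), np.einsum("int,n->it", tensor.values, ra)], axis=2)
    averages = {}
    for lab in ("left", "right"):
        m = tensor.turn == lab
        if np.any(m):
            averages[lab] = traj[m].mean(axis=0)
    for lab, m in (("resp", tensor.responded), ("nonresp", ~tensor.responded)):
        if np.any(m):
            averages[lab] = traj[m].mean(axis=0)
    return traj, averages
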