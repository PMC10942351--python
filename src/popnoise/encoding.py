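"""Stimulus regressor construction, PLS evoked subspace, and trial decoding.

A single stimulus regressor summarizes all presentations: a boxcar per
trial with height equal to the stimulus size (negated for right-side
trials), summed and convolved with the calcium kernel.  Partial least
squares (PLS) regression of the neural timeseries onto this regressor
defines the visually-evoked low-dimensional subspace; the regression
coefficient vector of the refit optimal model is the optimal stimulus
decoding direction w_opt.  Trial-wise stimulus identity is decoded from
mean in-window responses with lasso-regularized logistic regression under
repeated stratified cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.multiclass import OneVsRestClassifier

from .errors import AnalysisError, ConfigurationError
from .preprocessing import ActivityMatrix, Kernel, convolve_causal
from .synthetic import TrialSchedule

log = logging.getLogger("popnoise.encoding")


@dataclass
class StimulusKernel:
    """Size-weighted, side-signed stimulus regressor at the imaging rate."""

    values: np.ndarray
    frame_rate_hz: float
    sizes_deg: np.ndarray
    kernel_id: str = "gcamp"


@dataclass
class PLSModel:
    """Visually-evoked subspace and optimal decoding direction.

    ``loadings`` (neurons x d) maps centered activity into the latent
    space via ``(X - x_mean) @ loadings``; ``w_opt`` is the unit-norm
    regression coefficient vector in neuron space and ``w_opt_latent`` its
    exact representation in the latent basis.
    """

    d: int
    loadings: np.ndarray
    w_opt: np.ndarray
    w_opt_latent: np.ndarray
    x_mean: np.ndarray
    y_mean: float
    cv_mse: np.ndarray  # mean CV MSE per candidate dimensionality
    d_max: int
    patterns: np.ndarray | None = None  # (neurons x d) activity patterns

    def project(self, M: np.ndarray) -> np.ndarray:
        """Project rows of a (samples x neurons) matrix into latent space."""
        return (np.asarray(M, dtype=float) - self.x_mean) @ self.loadings

    def to_neuron_space(self, v_latent: np.ndarray) -> np.ndarray:
        out = self.loadings @ np.asarray(v_latent, dtype=float)
        n = np.linalg.norm(out)
        return out / n if n > 0 else out


@dataclass
class TrialFeatures:
    """Per-trial mean in-window response of every neuron, plus class labels."""

    X: np.ndarray  # (trials, neurons)
    labels: np.ndarray  # (trials,) '<size>_<side>'
    size_deg: np.ndarray
    side: np.ndarray


@dataclass
class ClassifierResult:
    classes: np.ndarray
    reg_grid: np.ndarray
    cv_accuracy: np.ndarray  # mean held-out accuracy per regularization value
    best_C: float
    accuracy: float
    confusion: np.ndarray  # row-stochastic, rows = true class
    coefs: np.ndarray  # (splits, classes, neurons) at best_C
    intercepts: np.ndarray


def build_stimulus_kernel(
    schedule: TrialSchedule,
    kernel: Kernel,
    frame_rate_hz: float,
    n_frames: int,
) -> StimulusKernel:
    """Sum of per-trial boxcars of height size_deg (negative on the right),
    causally convolved with the calcium kernel."""
    if frame_rate_hz <= 0:
        raise ConfigurationError("frame_rate_hz must be positive")
    box = np.zeros(n_frames)
    for i in range(schedule.n_trials):
        i0 = int(round(schedule.onset_s[i] * frame_rate_hz))
        i1 = int(round((schedule.onset_s[i] + schedule.duration_s[i]) * frame_rate_hz))
        if i0 >= n_frames:
            log.warning("trial %d starts past the recording end; skipped", i)
            continue
        if i1 > n_frames:
            log.warning("trial %d extends past the recording end; truncated", i)
            i1 = n_frames
        sign = 1.0 if schedule.side[i] == "left" else -1.0
        box[i0:i1] += sign * schedule.size_deg[i]
    return StimulusKernel(
        values=convolve_causal(box, kernel),
        frame_rate_hz=float(frame_rate_hz),
        sizes_deg=np.unique(schedule.size_deg),
    )


def _contiguous_splits(T: int, folds: int, repeats: int):
    """Contiguous time blocks as CV folds; repeats rotate block boundaries."""
    idx = np.arange(T)
    for rep in range(repeats):
        shift = rep * (T // (folds * repeats)) if repeats > 1 else 0
        rolled = np.roll(idx, -shift)
        for block in np.array_split(rolled, folds):
            test = np.sort(block)
            train = np.setdiff1d(idx, test)
            yield train, test


def fit_pls(
    activity: ActivityMatrix,
    regressor: StimulusKernel,
    d_max: int = 8,
    folds: int = 6,
    repeats: int = 3,
    seed: int = 0,
    d_min: int = 1,
) -> PLSModel:
    """PLS regression of activity onto the stimulus regressor.

    Candidate dimensionalities d_min..d_max are scored by contiguous-block
    cross-validation over timepoints (contiguous blocks avoid leakage
    through temporal autocorrelation); the best d is refit on all
    timepoints.  PLS components nest, so a single d_max-component fit per
    fold scores every truncation.  ``d_min`` floors the subspace size: to
    represent every stimulus class mean the evoked subspace needs at
    least one dimension per stimulus size, and CV can underestimate d
    when an evoked direction carries strong stimulus-independent
    variance.
    """
    X = activity.values.T
    y = np.asarray(regressor.values, dtype=float)
    T = X.shape[0]
    if y.shape != (T,):
        raise ConfigurationError("regressor length must match the number of frames")
    if np.std(y) < 1e-12:
        raise AnalysisError("degenerate (constant) stimulus regressor")
    if T < 5 * d_max:
        raise AnalysisError("too few timepoints for the requested d_max")
    mses = []
    for train, test in _contiguous_splits(T, folds, repeats):
        pls = PLSRegression(n_components=d_max, scale=False).fit(X[train], y[train])
        scores = (X[test] - X[train].mean(axis=0)) @ pls.x_rotations_
        q = pls.y_loadings_.ravel()  # (d_max,)
        y_mean = y[train].mean()
        fold_mse = [
            float(np.mean((scores[:, :d] @ q[:d] + y_mean - y[test]) ** 2))
            for d in range(1, d_max + 1)
        ]
        mses.append(fold_mse)
    cv_mse = np.asarray(mses).mean(axis=0)
    if not 1 <= d_min <= d_max:
        raise ConfigurationError("require 1 <= d_min <= d_max")
    d = int(np.argmin(cv_mse[d_min - 1 :])) + d_min
    final = PLSRegression(n_components=d, scale=False).fit(X, y)
    w = np.asarray(final.coef_).reshape(-1)
    if not np.any(w):
        raise AnalysisError("PLS produced an all-zero coefficient vector")
    w_unit = w / np.linalg.norm(w)
    # orthonormal basis of the PLS span: latent coordinates then preserve
    # neuron-space angles of subspace vectors (x_rotations_ is oblique)
    R, _ = np.linalg.qr(final.x_rotations_)
    w_lat = R.T @ w_unit
    return PLSModel(
        d=d,
        loadings=R,
        w_opt=w_unit,
        w_opt_latent=w_lat,
        x_mean=X.mean(axis=0),
        y_mean=float(y.mean()),
        cv_mse=cv_mse,
        d_max=d_max,
        patterns=final.x_loadings_,
    )


def trial_features(activity: ActivityMatrix, schedule: TrialSchedule) -> TrialFeatures:
    """Mean response of each neuron over each trial's stimulus window."""
    fs = activity.frame_rate_hz
    rows = []
    for i in range(schedule.n_trials):
        i0 = int(round(schedule.onset_s[i] * fs))
        i1 = int(round((schedule.onset_s[i] + schedule.duration_s[i]) * fs))
        i1 = min(i1, activity.n_frames)
        if i1 <= i0:
            raise AnalysisError(f"trial {i}: empty stimulus window at this frame rate")
        rows.append(activity.values[:, i0:i1].mean(axis=1))
    labels = schedule.class_labels
    return TrialFeatures(X=np.asarray(rows), labels=labels, size_deg=schedule.size_deg, side=schedule.side)


def fit_lasso_logistic(X: np.ndarray, y: np.ndarray, C: float):
    """Lasso-regularized logistic regression; one-vs-rest beyond 2 classes."""
    base = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear", max_iter=5000, random_state=0)
    clf = OneVsRestClassifier(base) if np.unique(y).size > 2 else base
    return clf.fit(X, y)


def lasso_coefs(clf) -> tuple[np.ndarray, np.ndarray]:
    """Per-class (coef matrix, intercepts); binary expanded to two rows
    (row order matches ``classes_``, positive score = second class)."""
    if hasattr(clf, "estimators_"):
        W = np.vstack([e.coef_ for e in clf.estimators_])
        b = np.concatenate([e.intercept_ for e in clf.estimators_])
    else:
        W, b = clf.coef_, clf.intercept_
    if W.shape[0] == 1:
        W = np.vstack([-W, W])
        b = np.concatenate([-b, b])
    return W, b


def default_lasso_grid(X: np.ndarray, y: np.ndarray, n_points: int = 15, decades: float = 4.0) -> np.ndarray:
    """Log-spaced inverse-regularization (C) grid centered by a max-penalty
    heuristic: the grid midpoint is the C at which the strongest univariate
    class-vs-rest gradient would first activate a coefficient."""
    Xc = X - X.mean(axis=0)
    lam_max = 0.0
    for c in np.unique(y):
        z = (y == c).astype(float)
        lam_max = max(lam_max, np.abs(Xc.T @ (z - z.mean())).max() / len(y))
    c0 = 1.0 / max(lam_max, 1e-9)
    return c0 * np.logspace(-decades / 2, decades / 2, n_points)


def decode_stimulus(
    features: TrialFeatures,
    folds: int = 6,
    repeats: int = 3,
    reg_grid: np.ndarray | None = None,
    seed: int = 0,
) -> ClassifierResult:
    """One-vs-rest lasso-logistic decoding of stimulus class across trials.

    The regularization parameter is swept; the model with the highest mean
    held-out accuracy is reported together with the held-out confusion
    matrix (counts summed across folds, then row-normalized per true
    class).
    """
    X, y = features.X, features.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise AnalysisError(
            f"class {classes[np.argmin(counts)]} has {counts.min()} trials; need >= {folds} per class"
        )
    grid = np.asarray(reg_grid if reg_grid is not None else default_lasso_grid(X, y), dtype=float)
    cv = RepeatedStratifiedKFold(n_splits=folds, n_repeats=repeats, random_state=seed)
    splits = list(cv.split(X, y))
    acc = np.zeros((grid.size, len(splits)))
    for gi, C in enumerate(grid):
        for si, (tr, te) in enumerate(splits):
            clf = fit_lasso_logistic(X[tr], y[tr], C)
            acc[gi, si] = clf.score(X[te], y[te])
    mean_acc = acc.mean(axis=1)
    best = int(np.argmax(mean_acc))
    conf = np.zeros((classes.size, classes.size))
    coefs, intercepts = [], []
    for tr, te in splits:
        clf = fit_lasso_logistic(X[tr], y[tr], grid[best])
        conf += confusion_matrix(y[te], clf.predict(X[te]), labels=classes)
        W, b = lasso_coefs(clf)
        coefs.append(W)
        intercepts.append(b)
    row = conf.sum(axis=1, keepdims=True)
    conf = conf / np.where(row > 0, row, 1.0)
    return ClassifierResult(
        classes=classes,
        reg_grid=grid,
        cv_accuracy=mean_acc,
        best_C=float(grid[best]),
        accuracy=float(mean_acc[best]),
        confusion=conf,
        coefs=np.asarray(coefs),
        intercepts=np.asarray(intercepts),
    )


def shuffled_wopt_coefs(
    activity: ActivityMatrix,
    schedule: TrialSchedule,
    kernel: Kernel,
    n_shuffles: int = 10,
    seed: int = 0,
    **pls_kwargs,
) -> list[np.ndarray]:
    """w_opt coefficient vectors under permuted stimulus-presentation labels.

    Each shuffle permutes the (size, side) assignment across trials,
    rebuilds the stimulus regressor and refits the PLS model, yielding the
    null coefficient distribution used for the 3-SD significance rule.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_shuffles):
        perm = rng.permutation(schedule.n_trials)
        shuffled = TrialSchedule(
            trial_id=schedule.trial_id,
            size_deg=schedule.size_deg[perm],
            side=schedule.side[perm],
            onset_s=schedule.onset_s,
            duration_s=schedule.duration_s,
        )
        reg = build_stimulus_kernel(shuffled, kernel, activity.frame_rate_hz, activity.n_frames)
        out.append(fit_pls(activity, reg, **pls_kwargs).w_opt)
    return out
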