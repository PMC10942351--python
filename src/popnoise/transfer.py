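"""Transfer of the visually-evoked turn-direction model to spontaneous turns.

Spontaneous turns are bouts outside every stimulus window (inter-trial
intervals or the stimulus-free pre-session period) that satisfy the same
+/- sigma_active turn criterion as evoked trials.  The evoked
turn-direction classifier is applied, frozen, to the mean population
activity in the second preceding each spontaneous turn; agreement between
the model score and the observed tail curvature tests whether a shared
pre-motor circuit drives both evoked and spontaneous turning.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .behavior import Bout
from .errors import AnalysisError, ConfigurationError
from .preprocessing import ActivityMatrix
from .synthetic import TrialSchedule

log = logging.getLogger("popnoise.transfer")


@dataclass
class SpontaneousEvent:
    turn_onset_s: float
    sign: str  # 'left' / 'right'
    peak_curvature: float
    mean_curvature: float
    context: str  # 'ITI' / 'pre-session'


@dataclass
class TurnModel:
    """Frozen turn-direction classifier (read-only at transfer time).

    ``positive_class`` names the class assigned when the decision score is
    positive (sklearn convention: the lexicographically larger label).
    """

    coefs: np.ndarray
    intercept: float
    positive_class: str = "right"

    def checksum(self) -> str:
        h = hashlib.sha256(np.ascontiguousarray(self.coefs).tobytes())
        h.update(np.float64(self.intercept).tobytes())
        return h.hexdigest()


def select_spontaneous(
    bouts: list[Bout],
    schedule: TrialSchedule,
    sigma_active: float,
    presession_s: float = 120.0,
    buffer_s: float = 2.0,
) -> list[SpontaneousEvent]:
    """Bouts outside every stimulus window that meet the turn criterion.

    A bout is excluded if it overlaps any [onset, offset + buffer_s)
    window (the buffer avoids stimulus carry-over).  Context is
    'pre-session' for bouts before the first onset (within the
    ``presession_s`` stimulus-free period), otherwise 'ITI'.
    """
    events = []
    for b in bouts:
        inside = np.any((b.end_s >= schedule.onset_s) & (b.start_s < schedule.offset_s + buffer_s))
        if inside:
            continue
        if abs(b.mean_curvature) <= sigma_active:
            continue
        context = "pre-session" if b.start_s < schedule.onset_s[0] else "ITI"
        if context == "pre-session" and b.start_s > presession_s:
            context = "ITI"
        events.append(
            SpontaneousEvent(
                turn_onset_s=b.start_s,
                sign="left" if b.mean_curvature > 0 else "right",
                peak_curvature=b.peak_abs_curvature,
                mean_curvature=b.mean_curvature,
                context=context,
            )
        )
    return events


def transfer_predict(
    events: list[SpontaneousEvent],
    activity: ActivityMatrix,
    model: TurnModel,
    window_s: float = 1.0,
    all_bouts: list[Bout] | None = None,
):
    """Score each spontaneous event from its pre-motor population activity.

    The feature is the per-neuron mean over [onset - window_s, onset); the
    score is feature . coefs + intercept, and the predicted class follows
    the score sign.  Events preceded by another bout inside the window are
    excluded (their pre-motor window is contaminated).  Returns
    (scores, predicted_labels, kept_event_indices).  The model is treated
    as read-only; a checksum guards against accidental refitting.
    """
    before = model.checksum()
    fs = activity.frame_rate_hz
    scores, pred, kept = [], [], []
    for k, ev in enumerate(events):
        i1 = int(np.floor(ev.turn_onset_s * fs))
        i0 = i1 - int(round(window_s * fs))
        if i0 < 0:
            log.info("event %d excluded: pre-motor window precedes the recording", k)
            continue
        if all_bouts is not None and any(
            b.end_s > ev.turn_onset_s - window_s and b.start_s < ev.turn_onset_s and b.start_s != ev.turn_onset_s
            for b in all_bouts
        ):
            log.info("event %d excluded: another bout inside the pre-motor window", k)
            continue
        feat = activity.values[:, i0:i1].mean(axis=1)
        s = float(feat @ model.coefs + model.intercept)
        scores.append(s)
        other = "left" if model.positive_class == "right" else "right"
        pred.append(model.positive_class if s > 0 else other)
        kept.append(k)
    if model.checksum() != before:
        raise AnalysisError("turn model was modified during transfer prediction")
    return np.asarray(scores), np.asarray(pred), np.asarray(kept, dtype=int)


def evaluate_transfer(scores: np.ndarray, curvatures: np.ndarray, signs: np.ndarray, positive_class: str = "right"):
    """Correlate model scores with observed curvature and score sign accuracy.

    Scores are oriented so that positive means a leftward prediction
    (matching the positive-curvature-is-left convention) before computing
    the Pearson correlation.  Returns (r, confusion[rows=true left/right],
    accuracy).
    """
    s = np.asarray(scores, dtype=float)
    c = np.asarray(curvatures, dtype=float)
    g = np.asarray(signs)
    if s.size < 3:
        raise AnalysisError("need at least 3 spontaneous events")
    if np.std(s) == 0:
        raise AnalysisError("constant scores: correlation undefined")
    oriented = s if positive_class == "left" else -s
    r = float(stats.pearsonr(oriented, c)[0])
    pred = np.where(oriented > 0, "left", "right")
    labels = ("left", "right")
    conf = np.zeros((2, 2))
    for i, t in enumerate(labels):
        for j, q in enumerate(labels):
            conf[i, j] = np.sum((g == t) & (pred == q))
    acc = float(np.trace(conf) / conf.sum()) if conf.sum() else np.nan
    return r, conf, acc
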