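"""Tail-kinematics and locomotion metrics.

Tail curvature is the summed inter-segment angle along the tail (radians;
positive = leftward).  Bouts are maximal runs where |curvature| exceeds
sigma_active, one standard deviation of the absolute curvature over the
whole recording.  Trial outcomes follow the +/- sigma_active rule on the
mean bout curvature within the stimulus window.  For comparison with
calcium signals, the convolved absolute / signed curvature define the tail
vigor / direction regressors.  For freely swimming sessions, each bout near
the stimulus is scored by its change in distance to the stimulus (positive
= avoidance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, ConfigurationError
from .preprocessing import Kernel, convolve_causal

log = logging.getLogger("popnoise.behavior")


@dataclass
class TailTrace:
    time_s: np.ndarray
    curvature: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.curvature = np.asarray(self.curvature, dtype=float)
        if self.time_s.shape != self.curvature.shape or self.time_s.ndim != 1:
            raise ConfigurationError("time_s and curvature must be equal-length vectors")
        if self.time_s.size >= 2 and np.any(np.diff(self.time_s) <= 0):
            raise ConfigurationError("time_s must be strictly increasing")
        if self.rate_hz < 20:
            raise ConfigurationError("tail traces must be sampled at >= 20 Hz")


@dataclass
class Bout:
    start_s: float
    end_s: float
    mean_curvature: float
    peak_abs_curvature: float

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ConfigurationError("bout end must follow start")


@dataclass
class TrialLabels:
    """Behavioral outcome per trial under the +/- sigma_active turn rule."""

    trial_id: np.ndarray
    responded: np.ndarray
    turn: np.ndarray  # 'left' / 'right' / 'none'
    reaction_time_s: np.ndarray  # NaN when not responded
    mean_bout_curvature: np.ndarray
    sigma_active: float

    def __post_init__(self) -> None:
        resp = np.asarray(self.responded, dtype=bool)
        turn = np.asarray(self.turn)
        if np.any((turn != "none") & ~resp):
            raise ConfigurationError("a turn label requires a response")
        rt = np.asarray(self.reaction_time_s, dtype=float)
        if np.any(np.isfinite(rt) != resp):
            raise ConfigurationError("reaction time must be present iff responded")

    @property
    def n_trials(self) -> int:
        return np.asarray(self.trial_id).size


def compute_sigma_active(trace: TailTrace) -> float:
    """Standard deviation of |curvature| over the whole recording."""
    if trace.curvature.size == 0:
        raise AnalysisError("empty tail trace")
    a = np.abs(trace.curvature)
    if not np.any(a > 0):
        log.warning("all-zero tail trace: sigma_active = 0, no bouts extractable")
        return 0.0
    return float(np.std(a))


def extract_bouts(
    trace: TailTrace,
    sigma_active: float,
    min_gap_s: float = 0.1,
    min_dur_s: float = 0.05,
) -> list[Bout]:
    """Maximal runs with |curvature| >= sigma_active.

    Runs separated by less than ``min_gap_s`` are merged; runs shorter than
    ``min_dur_s`` are discarded (suppresses chatter at threshold crossings).
    """
    if sigma_active <= 0:
        raise ConfigurationError("sigma_active must be positive for bout extraction")
    active = np.abs(trace.curvature) >= sigma_active
    if not np.any(active):
        return []
    edges = np.diff(active.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1))
    if active[0]:
        starts.insert(0, 0)
    if active[-1]:
        ends.append(active.size - 1)
    runs = list(zip(starts, ends))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if trace.time_s[s] - trace.time_s[merged[-1][1]] < min_gap_s:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    bouts = []
    for s, e in merged:
        if trace.time_s[e] - trace.time_s[s] < min_dur_s:
            continue
        seg = trace.curvature[s : e + 1]
        bouts.append(
            Bout(
                start_s=float(trace.time_s[s]),
                end_s=float(trace.time_s[e]),
                mean_curvature=float(seg.mean()),
                peak_abs_curvature=float(np.abs(seg).max()),
            )
        )
    return bouts


def label_trials(trace: TailTrace, bouts: list[Bout], schedule, sigma_active: float) -> TrialLabels:
    """Label each trial from the bout samples inside its stimulus window.

    The window is half-open, [onset, onset + duration).  The mean bout
    curvature is taken over bout samples falling inside the window (bouts
    straddling a boundary contribute only their in-window samples); a trial
    turns left/right when that mean exceeds +/- sigma_active.  Reaction
    time is measured to the start of the first bout at or after onset.
    """
    n = schedule.n_trials
    responded = np.zeros(n, dtype=bool)
    turn = np.full(n, "none", dtype="U5")
    rts = np.full(n, np.nan)
    means = np.zeros(n)
    for i in range(n):
        lo, hi = schedule.onset_s[i], schedule.onset_s[i] + schedule.duration_s[i]
        samples = []
        first_start = None
        for b in bouts:
            if b.end_s < lo or b.start_s >= hi:
                continue
            if b.start_s < lo or b.end_s >= hi:
                log.info("trial %d: bout straddles window boundary; counting in-window samples only", i)
            mask = (trace.time_s >= max(b.start_s, lo)) & (trace.time_s <= min(b.end_s, hi)) & (trace.time_s < hi)
            samples.append(trace.curvature[mask])
            if b.start_s >= lo and first_start is None:
                first_start = b.start_s
        if not samples:
            continue
        seg = np.concatenate(samples)
        if seg.size == 0:
            continue
        responded[i] = True
        rts[i] = (first_start if first_start is not None else lo) - lo
        means[i] = seg.mean()
        if means[i] > sigma_active:
            turn[i] = "left"
        elif means[i] < -sigma_active:
            turn[i] = "right"
    return TrialLabels(
        trial_id=np.asarray(schedule.trial_id),
        responded=responded,
        turn=turn,
        reaction_time_s=rts,
        mean_bout_curvature=means,
        sigma_active=float(sigma_active),
    )


def vigor_and_direction(
    trace: TailTrace,
    kernel: Kernel,
    target_rate_hz: float,
    n_out: int | None = None,
):
    """Calcium-kernel-convolved |curvature| (vigor) and curvature (direction).

    Both are convolved at the tail sampling rate and then resampled to the
    imaging frame grid (frame k at k / target_rate_hz) by linear
    interpolation.  ``n_out`` pads/truncates to a fixed frame count.
    """
    if target_rate_hz > trace.rate_hz:
        raise ConfigurationError("target rate must not exceed the tail sampling rate")
    dt = 1.0 / trace.rate_hz
    vig = convolve_causal(np.abs(trace.curvature), kernel, dt_s=dt)
    dirn = convolve_causal(trace.curvature, kernel, dt_s=dt)
    if n_out is None:
        n_out = int(np.floor(trace.time_s[-1] * target_rate_hz)) + 1
    t_frames = np.arange(n_out) / target_rate_hz
    vigor = np.interp(t_frames, trace.time_s, vig, left=0.0, right=vig[-1])
    direction = np.interp(t_frames, trace.time_s, dirn, left=0.0, right=dirn[-1])
    return vigor, direction


def approach_avoidance(
    time_s: np.ndarray,
    centroid_xy: np.ndarray,
    stimulus_xy: np.ndarray,
    bouts: list[Bout],
    max_dist_bodylengths: float = 6.0,
    body_length: float = 4.0,
):
    """Per-bout change in distance to the stimulus (positive = avoidance).

    Only bouts that start within ``max_dist_bodylengths * body_length`` of
    the stimulus are scored; bouts containing missing tracking samples are
    excluded.  Returns (delta_distance, included_bout_indices).
    """
    time_s = np.asarray(time_s, dtype=float)
    centroid = np.asarray(centroid_xy, dtype=float)
    stimulus = np.asarray(stimulus_xy, dtype=float)
    if centroid.shape != stimulus.shape or centroid.shape[0] != time_s.size:
        raise ConfigurationError("trajectories must be time-aligned and equal-shaped")
    dist = np.linalg.norm(centroid - stimulus, axis=1)
    deltas, idx = [], []
    for j, b in enumerate(bouts):
        i0 = int(np.searchsorted(time_s, b.start_s))
        i1 = min(int(np.searchsorted(time_s, b.end_s)), time_s.size - 1)
        if np.any(~np.isfinite(dist[i0 : i1 + 1])):
            log.info("bout %d excluded: missing tracking samples", j)
            continue
        if dist[i0] > max_dist_bodylengths * body_length:
            continue
        deltas.append(dist[i1] - dist[i0])
        idx.append(j)
    return np.asarray(deltas), np.asarray(idx, dtype=int)
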