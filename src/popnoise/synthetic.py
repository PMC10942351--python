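"""Synthetic whole-brain recordings with planted, known population structure.

The generator emulates a head-fixed larval-zebrafish session: moving-dot
stimuli of several sizes presented on the left or right (3 s trials,
inter-trial intervals ~ N(9 s, 3 s) truncated at 1 s), a tail-curvature
trace with evoked and spontaneous swim bouts, and a neurons x time calcium
matrix built from

* per-size stimulus-encoding directions (signed by stimulus side), whose
  unit-normalized sum is the planted optimal decoding direction ``w_true``;
* shared trial-to-trial "noise" factors: a tail-vigor factor planted at a
  configurable angle to ``w_true`` *inside* the evoked subspace, slow
  Ornstein-Uhlenbeck turn-direction and responsiveness biases, and signed
  ramps that rise ~1 s before each movement;
* GCaMP-kernel convolution, a bi-exponential photobleaching trend, and
  i.i.d. Gaussian noise.

Every quantity a downstream stage should recover (loadings, latents,
per-trial outcomes, spontaneous-turn times) is recorded in
:class:`SyntheticGroundTruth`, so each analysis stage has an exact
acceptance surface.  All three generators are deterministic given a seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit, logit

from .errors import ConfigurationError
from .preprocessing import REGIONS, ActivityMatrix, BleachFit, Kernel, convolve_causal, make_gcamp_kernel

log = logging.getLogger("popnoise.synthetic")

SIDES = ("left", "right")

#: Latent amplitudes in "sustained-response" units: drive terms are
#: convolved with a *mass-normalized* calcium kernel, so an amplitude of 1
#: means a sustained latent of unit value produces a unit-height neural
#: response along its loading.  The budget reflects the study conditions:
#: visual responses are the strongest evoked signal (robust decoding),
#: motor-bout transients (vigor) are the largest source of within-class
#: trial-to-trial covariance while keeping their overall temporal variance
#: below the stimulus variance (so regression-based decoding directions
#: are not shrunk along the shared-noise dimension), slow bias factors are
#: weak-but-decodable, and movement ramps are mid-sized.
DEFAULT_AMPLITUDES = {
    "stimulus": 5.0,
    "vigor": 14.0,
    "turn_bias": 0.05,
    "resp_bias": 0.05,
    "turn_ramp": 1.0,
    "resp_ramp": 1.0,
    "spont_ramp": 1.0,
}


@dataclass
class TrialSchedule:
    """Per-trial stimulus size/side/onset bookkeeping (times in seconds)."""

    trial_id: np.ndarray
    size_deg: np.ndarray
    side: np.ndarray
    onset_s: np.ndarray
    duration_s: np.ndarray

    def __post_init__(self) -> None:
        self.trial_id = np.asarray(self.trial_id, dtype=int)
        self.size_deg = np.asarray(self.size_deg, dtype=float)
        self.side = np.asarray(self.side, dtype="U5")
        self.onset_s = np.asarray(self.onset_s, dtype=float)
        self.duration_s = np.asarray(self.duration_s, dtype=float)
        n = self.trial_id.size
        for name in ("size_deg", "side", "onset_s", "duration_s"):
            if getattr(self, name).shape != (n,):
                raise ConfigurationError(f"schedule field {name} has wrong length")
        if n and np.any(np.diff(self.onset_s) <= 0):
            raise ConfigurationError("trial onsets must be strictly increasing")
        if np.any(self.duration_s <= 0) or np.any(self.size_deg <= 0):
            raise ConfigurationError("durations and sizes must be positive")
        if n > 1 and np.any(self.onset_s[1:] < self.onset_s[:-1] + self.duration_s[:-1]):
            raise ConfigurationError("consecutive trials overlap")
        bad = set(np.unique(self.side)) - set(SIDES)
        if bad:
            raise ConfigurationError(f"unknown sides: {bad}")

    @property
    def n_trials(self) -> int:
        return self.trial_id.size

    @property
    def offset_s(self) -> np.ndarray:
        return self.onset_s + self.duration_s

    @property
    def class_labels(self) -> np.ndarray:
        """Stimulus class per trial as '<size>_<side>' strings."""
        return np.array([f"{s:g}_{d}" for s, d in zip(self.size_deg, self.side)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trial_id": self.trial_id,
                "size_deg": self.size_deg,
                "side": self.side,
                "onset_s": self.onset_s,
                "duration_s": self.duration_s,
            }
        )


@dataclass
class SyntheticGroundTruth:
    """Planted structure of a synthetic session; the recovery target.

    ``noise_loadings`` rows are unit vectors over neurons; row 0 is the
    tail-vigor factor, planted at ``angle_deg`` to ``w_true``.
    """

    w_true: np.ndarray
    size_directions: np.ndarray  # (n_sizes, n_neurons), orthonormal rows
    sizes_deg: np.ndarray
    noise_loadings: np.ndarray  # (n_factors, n_neurons)
    factor_names: tuple
    angle_deg: float
    bias_turn: np.ndarray  # frame-rate series
    bias_resp: np.ndarray
    frame_rate_hz: float
    tau_bias_s: float
    ramp_onset_s: float
    turn_truth: np.ndarray  # 'left' / 'right' / 'none'
    responded: np.ndarray
    reaction_time_s: np.ndarray  # NaN for non-responsive trials
    trial_amplitude: np.ndarray  # bout amplitude per responsive trial (rad)
    spont_onset_s: np.ndarray
    spont_sign: np.ndarray  # +1 = left
    spont_amplitude: np.ndarray
    bout_duration_s: float
    markov_persistence: float
    shared_spontaneous: bool
    total_duration_s: float
    seed: int

    @property
    def n_neurons(self) -> int:
        return self.w_true.size

    def loading(self, name: str) -> np.ndarray:
        return self.noise_loadings[self.factor_names.index(name)]


def _truncated_normal(rng, mean, sd, low, size):
    if sd == 0:
        return np.full(size, max(mean, low), dtype=float)
    out = rng.normal(mean, sd, size)
    bad = out < low
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < low
    return out


def generate_trial_schedule(
    n_trials: int,
    sizes_deg=(4.0, 11.0, 44.0),
    duration_s: float = 3.0,
    iti_mean_s: float = 9.0,
    iti_sd_s: float = 3.0,
    seed: int = 0,
    start_s: float = 120.0,
) -> TrialSchedule:
    """Randomized, (size, side)-balanced schedule with truncated-normal ITIs.

    Cell counts over the (size, side) grid differ by at most one trial.
    The first onset is at ``start_s`` (a stimulus-free pre-session period);
    ITIs are drawn from N(iti_mean_s, iti_sd_s) truncated below at 1 s.
    """
    sizes = np.asarray(list(sizes_deg), dtype=float)
    if sizes.size == 0:
        raise ConfigurationError("sizes_deg must be non-empty")
    if n_trials < 1 or duration_s <= 0 or iti_sd_s < 0:
        raise ConfigurationError("need n_trials >= 1, duration_s > 0, iti_sd_s >= 0")
    rng = np.random.default_rng(seed)
    cells = [(s, side) for s in sizes for side in SIDES]
    base, rem = divmod(n_trials, len(cells))
    extra = np.zeros(len(cells), dtype=int)
    extra[rng.permutation(len(cells))[:rem]] = 1
    assign = np.repeat(np.arange(len(cells)), base + extra)
    rng.shuffle(assign)
    itis = _truncated_normal(rng, iti_mean_s, iti_sd_s, low=1.0, size=n_trials - 1)
    onsets = float(start_s) + np.concatenate([[0.0], np.cumsum(itis + duration_s)])
    return TrialSchedule(
        trial_id=np.arange(n_trials),
        size_deg=np.array([cells[i][0] for i in assign]),
        side=np.array([cells[i][1] for i in assign]),
        onset_s=onsets,
        duration_s=np.full(n_trials, float(duration_s)),
    )


def recording_duration_s(schedule: TrialSchedule, pad_s: float = 20.0) -> float:
    return float(schedule.onset_s[-1] + schedule.duration_s[-1] + pad_s)


def _ou_series(rng, n, dt_s, tau_s):
    """Unit-variance Ornstein-Uhlenbeck samples (exact discretization)."""
    a = np.exp(-dt_s / tau_s)
    s = np.sqrt(1.0 - a * a)
    burn = int(np.ceil(5 * tau_s / dt_s))
    e = rng.standard_normal(n + burn)
    x = lfilter([s], [1.0, -a], e)
    return x[burn:]


def make_ground_truth(
    schedule: TrialSchedule,
    n_neurons: int,
    *,
    frame_rate_hz: float = 5.0,
    angle_deg: float = 90.0,
    tau_bias_s: float = 60.0,
    ramp_onset_s: float = 1.0,
    p_respond: float = 0.6,
    bias_gain: float = 1.5,
    resp_gain: float = 1.5,
    stim_gain: float = 1.2,
    crossover_deg: float = 7.5,
    rt_median_s: float = 1.5,
    rt_sigma: float = 0.35,
    rt_min_s: float = 0.5,
    rt_max_s: float = 2.8,
    markov_persistence: float = 0.8,
    spont_rate_hz: float = 0.08,
    bout_duration_s: float = 0.6,
    shared_spontaneous: bool = True,
    pad_s: float = 20.0,
    seed: int = 0,
) -> SyntheticGroundTruth:
    """Draw planted loadings, latent biases and per-trial outcomes.

    Turn direction follows a logistic link on the slow turn bias plus a
    signed, size-dependent stimulus drive (approach below ``crossover_deg``,
    avoidance above); responsiveness follows a logistic link on a second
    slow bias.  Spontaneous turns alternate via a two-state Markov chain
    with the given persistence.  The vigor factor loading is constructed at
    ``angle_deg`` to ``w_true`` within the span of the encoding directions,
    so the planted geometry lives inside the visually-evoked subspace.
    """
    rng = np.random.default_rng(seed)
    sizes = np.unique(schedule.size_deg)
    shared_names = ("vigor", "turn_bias", "resp_bias", "turn_ramp", "resp_ramp")
    factor_names = shared_names if shared_spontaneous else shared_names + ("spont_ramp",)
    n_extra = len(factor_names) - 1  # all but vigor are drawn orthonormal
    if n_neurons < 2 * len(factor_names):
        raise ConfigurationError("n_neurons must be at least twice the number of planted factors")
    n_dirs = sizes.size + n_extra
    raw = rng.standard_normal((n_neurons, n_dirs))
    q, _ = np.linalg.qr(raw)
    size_directions = q[:, : sizes.size].T
    extra = q[:, sizes.size :].T
    # Asymptotic regression direction: the stimulus regressor weights each
    # size's boxcar by its size, while the neural drive along w_k follows
    # that size's response envelope.  On noise-free data the regression of
    # the regressor on the drive reduces to least squares over the per-size
    # latents; the kernel normalization cancels in the direction.
    total_s = recording_duration_s(schedule, pad_s)
    n_frames = int(np.ceil(total_s * frame_rate_hz))
    dt = 1.0 / frame_rate_hz
    kern = make_gcamp_kernel(dt_s=dt)
    stim = stimulus_latents(schedule, sizes, n_frames, frame_rate_hz)
    C = np.array([convolve_causal(s, kern) for s in stim])
    ybox = np.zeros(n_frames)
    for i in range(schedule.n_trials):
        i0 = int(round(schedule.onset_s[i] * frame_rate_hz))
        i1 = min(int(round((schedule.onset_s[i] + schedule.duration_s[i]) * frame_rate_hz)), n_frames)
        sgn = 1.0 if schedule.side[i] == "left" else -1.0
        ybox[i0:i1] += sgn * schedule.size_deg[i]
    y_conv = convolve_causal(ybox, kern)
    g = np.linalg.solve(C @ C.T, C @ y_conv)
    w_true = g @ size_directions
    w_true /= np.linalg.norm(w_true)
    # In-span direction orthogonal to w_true for the planted-angle
    # construction.  Weighted by size so the shared-noise loading
    # concentrates on the strongly regressor-weighted (hence reliably
    # recovered) populations, as motor noise does in the evoked subspace.
    combo = (rng.standard_normal(sizes.size) * sizes / sizes.max()) @ size_directions
    u = combo - (combo @ w_true) * w_true
    u /= np.linalg.norm(u)
    phi = np.deg2rad(angle_deg)
    vigor_loading = np.cos(phi) * w_true + np.sin(phi) * u
    vigor_loading /= np.linalg.norm(vigor_loading)
    noise_loadings = np.vstack([vigor_loading, extra])

    total_s = recording_duration_s(schedule, pad_s)
    n_frames = int(np.ceil(total_s * frame_rate_hz))
    bias_turn = _ou_series(rng, n_frames, 1.0 / frame_rate_hz, tau_bias_s)
    bias_resp = _ou_series(rng, n_frames, 1.0 / frame_rate_hz, tau_bias_s)

    onset_idx = np.clip((schedule.onset_s * frame_rate_hz).astype(int), 0, n_frames - 1)
    side_sign = np.where(schedule.side == "left", 1.0, -1.0)
    g = np.clip((crossover_deg - schedule.size_deg) / crossover_deg, -1.0, 1.0)
    p_left = expit(bias_gain * bias_turn[onset_idx] + stim_gain * g * side_sign)
    p_resp = expit(logit(p_respond) + resp_gain * bias_resp[onset_idx])
    responded = rng.random(schedule.n_trials) < p_resp
    turn = np.where(rng.random(schedule.n_trials) < p_left, "left", "right")
    turn = np.where(responded, turn, "none").astype("U5")
    rt = np.clip(rng.lognormal(np.log(rt_median_s), rt_sigma, schedule.n_trials), rt_min_s, rt_max_s)
    rt = np.where(responded, rt, np.nan)
    trial_amp = rng.lognormal(0.0, 0.25, schedule.n_trials)

    # spontaneous bouts in the pre-session period and in inter-trial intervals
    windows = []
    if schedule.onset_s[0] > 10.0:
        windows.append((5.0, schedule.onset_s[0] - 5.0))
    for i in range(schedule.n_trials - 1):
        lo = schedule.offset_s[i] + 2.0
        hi = schedule.onset_s[i + 1] - 2.0
        if hi - lo > 1.5:
            windows.append((lo, hi))
    spont_times = []
    for lo, hi in windows:
        k = rng.poisson(spont_rate_hz * (hi - lo))
        if k:
            ts = np.sort(rng.uniform(lo, hi, k))
            keep = np.concatenate([[True], np.diff(ts) > 1.5])
            spont_times.append(ts[keep])
    spont_onset = np.sort(np.concatenate(spont_times)) if spont_times else np.empty(0)
    # ARTR-like alternation: a two-state Markov chain whose per-event left
    # probability is additionally steered by the slow turn bias — the
    # spontaneous-turn circuitry and the turn bias are the same planted
    # ensemble.  The bias coupling is severed in the independent-circuit
    # control (shared_spontaneous=False).
    signs = np.empty(spont_onset.size)
    if spont_onset.size:
        persist_logit = logit(np.clip(markov_persistence, 1e-6, 1 - 1e-6))
        ev_idx = np.clip((spont_onset * frame_rate_hz).astype(int), 0, n_frames - 1)
        ev_bias = bias_turn[ev_idx] if shared_spontaneous else np.zeros(spont_onset.size)
        signs[0] = 1.0 if rng.random() < expit(bias_gain * ev_bias[0]) else -1.0
        for i in range(1, spont_onset.size):
            p_left = expit(persist_logit * signs[i - 1] + bias_gain * ev_bias[i])
            signs[i] = 1.0 if rng.random() < p_left else -1.0
    spont_amp = 0.8 * rng.lognormal(0.0, 0.25, spont_onset.size)

    return SyntheticGroundTruth(
        w_true=w_true,
        size_directions=size_directions,
        sizes_deg=sizes,
        noise_loadings=noise_loadings,
        factor_names=factor_names,
        angle_deg=float(angle_deg),
        bias_turn=bias_turn,
        bias_resp=bias_resp,
        frame_rate_hz=float(frame_rate_hz),
        tau_bias_s=float(tau_bias_s),
        ramp_onset_s=float(ramp_onset_s),
        turn_truth=turn,
        responded=responded,
        reaction_time_s=rt,
        trial_amplitude=trial_amp,
        spont_onset_s=spont_onset,
        spont_sign=signs,
        spont_amplitude=spont_amp,
        bout_duration_s=float(bout_duration_s),
        markov_persistence=float(markov_persistence),
        shared_spontaneous=bool(shared_spontaneous),
        total_duration_s=total_s,
        seed=int(seed),
    )


def _movement_events(schedule: TrialSchedule, truth: SyntheticGroundTruth):
    """(time, sign, amplitude, is_trial) for every movement in the session."""
    events = []
    for i in range(schedule.n_trials):
        if truth.responded[i]:
            sign = 1.0 if truth.turn_truth[i] == "left" else -1.0
            events.append((schedule.onset_s[i] + truth.reaction_time_s[i], sign, truth.trial_amplitude[i], True))
    for t, s, a in zip(truth.spont_onset_s, truth.spont_sign, truth.spont_amplitude):
        events.append((float(t), float(s), float(a), False))
    events.sort()
    return events


def _half_sine(t, t0, dur):
    x = (t - t0) / dur
    env = np.sin(np.pi * np.clip(x, 0.0, 1.0))
    env[(x < 0) | (x > 1)] = 0.0
    return env


def _ramp(t, t_move, rise_s, decay_s=0.4):
    pre = np.clip((t - (t_move - rise_s)) / rise_s, 0.0, 1.0)
    post = np.exp(-np.clip(t - t_move, 0.0, None) / decay_s)
    return np.where(t <= t_move, pre, post)


def factor_latents(schedule: TrialSchedule, truth: SyntheticGroundTruth, n_frames: int, frame_rate_hz: float) -> dict:
    """Raw (un-convolved) latent timecourses of the planted shared factors."""
    t = np.arange(n_frames) / frame_rate_hz
    lat = {name: np.zeros(n_frames) for name in truth.factor_names}
    for tm, sign, amp, is_trial in _movement_events(schedule, truth):
        env = amp * _half_sine(t, tm, truth.bout_duration_s)
        lat["vigor"] += env
        r = _ramp(t, tm, truth.ramp_onset_s)
        if is_trial:
            lat["turn_ramp"] += sign * r
            lat["resp_ramp"] += r
        elif truth.shared_spontaneous:
            lat["turn_ramp"] += sign * r
        else:
            lat["spont_ramp"] += sign * r

    def _fit_len(x):
        if x.size >= n_frames:
            return x[:n_frames]
        return np.concatenate([x, np.full(n_frames - x.size, x[-1])])

    lat["turn_bias"] = _fit_len(truth.bias_turn)
    lat["resp_bias"] = _fit_len(truth.bias_resp)
    return lat


def _size_response_shape(rank01: float, t_s: np.ndarray) -> np.ndarray:
    """Within-trial response envelope of a size-selective population.

    Small-stimulus (prey-like) populations respond in a sustained fashion;
    large-stimulus (looming-like) populations respond transiently at
    onset.  ``rank01`` is the size rank in [0 (smallest), 1 (largest)].
    """
    floor = 1.0 - 0.9 * rank01
    tau = 1.5 - 1.1 * rank01
    latency = 0.8 * (1.0 - rank01)
    te = np.clip(t_s - latency, 0.0, None)
    return (floor + (1.0 - floor) * np.exp(-te / tau)) * (t_s >= latency)


def _shape_energy_norms(sizes: np.ndarray, duration_s: float, frame_rate_hz: float) -> np.ndarray:
    """Per-size normalization equalizing the calcium-observable response
    energy: populations differ in dynamics and latency, not in drive
    strength as seen through the indicator."""
    dt = 1.0 / frame_rate_hz
    tt = np.arange(0.0, duration_s, dt)
    kern = make_gcamp_kernel(dt_s=dt)
    ranks = np.linspace(0.0, 1.0, sizes.size) if sizes.size > 1 else np.array([0.5])
    pad = np.zeros(int(round(5.0 * frame_rate_hz)))
    ref = np.sqrt(np.mean(convolve_causal(np.concatenate([np.ones_like(tt), pad]), kern) ** 2))
    norms = np.empty(sizes.size)
    for k in range(sizes.size):
        resp = convolve_causal(np.concatenate([_size_response_shape(ranks[k], tt), pad]), kern)
        norms[k] = np.sqrt(np.mean(resp**2)) / ref
    return np.where(norms > 0, norms, 1.0)


def stimulus_latents(schedule: TrialSchedule, sizes: np.ndarray, n_frames: int, frame_rate_hz: float) -> np.ndarray:
    """Per-size drive latents, negated on the right.

    Each size class drives its own population direction with comparable
    peak amplitude (size-selective populations, not a linear size gain)
    but a size-dependent temporal envelope; side determines the sign,
    matching the left/right antisymmetry of the behavioral response."""
    out = np.zeros((sizes.size, n_frames))
    t = np.arange(n_frames) / frame_rate_hz
    ranks = np.linspace(0.0, 1.0, sizes.size) if sizes.size > 1 else np.array([0.5])
    norms = _shape_energy_norms(sizes, float(np.median(schedule.duration_s)), frame_rate_hz)
    for k, s in enumerate(sizes):
        for i in np.flatnonzero(schedule.size_deg == s):
            i0 = int(round(schedule.onset_s[i] * frame_rate_hz))
            i1 = int(round((schedule.onset_s[i] + schedule.duration_s[i]) * frame_rate_hz))
            sign = 1.0 if schedule.side[i] == "left" else -1.0
            out[k, i0:i1] += (sign / norms[k]) * _size_response_shape(ranks[k], t[i0:i1] - schedule.onset_s[i])
    return out


_REGION_CENTERS = {"Tel": (100.0, 300.0, 80.0), "Tec": (280.0, 300.0, 120.0), "Cer": (430.0, 300.0, 100.0), "Hind": (580.0, 300.0, 80.0)}


def generate_population(
    schedule: TrialSchedule,
    truth: SyntheticGroundTruth,
    n_neurons: int,
    frame_rate_hz: float = 5.0,
    snr: float = 5.0,
    bleach: BleachFit | None = None,
    kernel: Kernel | None = None,
    seed: int = 0,
    amplitudes: dict | None = None,
    baseline: float = 1.0,
    pad_s: float = 20.0,
) -> ActivityMatrix:
    """Render the neurons x time calcium matrix from the planted structure.

    ``snr`` is the ratio of a unit latent amplitude to the i.i.d. noise
    standard deviation along any unit loading direction (``snr=np.inf``
    gives a noise-free matrix).  All drive terms are convolved with the
    calcium kernel and the result is multiplied by the bleaching trend.
    """
    if frame_rate_hz <= 0:
        raise ConfigurationError("frame_rate_hz must be positive")
    if not snr > 0:
        raise ConfigurationError("snr must be positive")
    if truth.n_neurons != n_neurons:
        raise ConfigurationError("n_neurons must match the ground-truth loadings")
    rng = np.random.default_rng(seed)
    fs = float(frame_rate_hz)
    n_frames = int(np.ceil(recording_duration_s(schedule, pad_s) * fs))
    kernel = kernel if kernel is not None else make_gcamp_kernel(dt_s=1.0 / fs)
    bleach = bleach if bleach is not None else BleachFit(a=0.45, b=-1 / 600.0, c=0.55, d=-1 / 6000.0)
    amps = dict(DEFAULT_AMPLITUDES)
    amps.update(amplitudes or {})

    # mass-normalized kernel: a sustained unit latent maps to a unit response
    knorm = Kernel(samples=kernel.samples / kernel.mass, dt_s=kernel.dt_s)
    drive = np.zeros((n_neurons, n_frames))
    stim = stimulus_latents(schedule, truth.sizes_deg, n_frames, fs)
    for k in range(truth.sizes_deg.size):
        drive += amps["stimulus"] * np.outer(truth.size_directions[k], convolve_causal(stim[k], knorm))
    for name, series in factor_latents(schedule, truth, n_frames, fs).items():
        drive += amps[name] * np.outer(truth.loading(name), convolve_causal(series, knorm))

    base = baseline * (1.0 + 0.05 * rng.standard_normal(n_neurons))
    noise_sd = 0.0 if np.isinf(snr) else 1.0 / snr
    noise = noise_sd * rng.standard_normal((n_neurons, n_frames)) if noise_sd else 0.0
    values = (base[:, None] + drive + noise) * bleach.trend(np.arange(n_frames) / fs)[None, :]

    region_idx = rng.integers(0, len(REGIONS), n_neurons)
    regions = np.array(REGIONS)[region_idx]
    centers = np.array([_REGION_CENTERS[r] for r in regions])
    positions = centers + rng.normal(0.0, 40.0, (n_neurons, 3))
    return ActivityMatrix(values=values, frame_rate_hz=fs, positions_um=positions, regions=regions)


def generate_tail_trace(
    schedule: TrialSchedule,
    truth: SyntheticGroundTruth,
    rate_hz: float = 200.0,
    seed: int = 0,
    noise_sd: float = 0.0,
    pad_s: float = 20.0,
):
    """Render the tail-curvature trace (radians; positive = leftward).

    Curvature is zero outside bouts.  Each responsive trial contains one
    half-sine bout starting at onset + reaction time with sign matching the
    planted turn; spontaneous bouts are rendered from the ground-truth
    Markov sequence.  ``noise_sd`` adds sensor noise (default none, so
    behavioral labels are exactly recoverable).
    """
    from .behavior import TailTrace  # local import to avoid a cycle

    if rate_hz < 20:
        raise ConfigurationError("tail sampling rate must be at least 20 Hz")
    rng = np.random.default_rng(seed)
    n = int(np.ceil(recording_duration_s(schedule, pad_s) * rate_hz))
    t = np.arange(n) / rate_hz
    curv = np.zeros(n)
    end = t[-1]
    for tm, sign, amp, is_trial in _movement_events(schedule, truth):
        if tm + truth.bout_duration_s > end:
            log.info("bout at %.1f s truncated at recording end", tm)
        curv += sign * amp * _half_sine(t, tm, truth.bout_duration_s)
    if noise_sd:
        curv = curv + noise_sd * rng.standard_normal(n)
    return TailTrace(time_s=t, curvature=curv, rate_hz=float(rate_hz))
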