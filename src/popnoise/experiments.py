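"""Reference experiment recipes built from the pipeline stages.

These functions wire the library stages into the standard simulation
studies the package is validated on: planted-angle recovery of the
largest noise mode, pre-motor predictability profiles under planted
bias/ramp structure versus a structure-free null, and spontaneous-turn
transfer with shared versus independent circuits.  They are used by the
test suite and by ``scripts/acceptance.py``; all randomness derives from
the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .behavior import compute_sigma_active, extract_bouts, label_trials
from .encoding import build_stimulus_kernel, fit_pls, trial_features
from .geometry import mode_angles, noise_covariance, noise_modes
from .preprocessing import fit_bleach_trend, make_gcamp_kernel, normalize_activity
from .premotor import time_warp, window_classify
from .synthetic import generate_population, generate_tail_trace, generate_trial_schedule, make_ground_truth
from .transfer import TurnModel, evaluate_transfer, select_spontaneous, transfer_predict

#: Amplitudes for the planted-internal-state scenarios (pre-motor
#: profile shape and spontaneous transfer): a clearly decodable slow bias
#: and movement ramps, contrasted against NULL_AMPLITUDES where no
#: internal-state structure reaches the neural data.
SCENARIO_AMPLITUDES = {
    "turn_bias": 0.3,
    "resp_bias": 0.3,
    "turn_ramp": 6.0,
    "resp_ramp": 6.0,
    "spont_ramp": 6.0,
}
NULL_AMPLITUDES = {
    "turn_bias": 0.0,
    "resp_bias": 0.0,
    "turn_ramp": 0.0,
    "resp_ramp": 0.0,
    "spont_ramp": 0.0,
}


def simulate_session(
    seed: int,
    n_trials: int,
    n_neurons: int,
    sizes=(4.0, 11.0, 44.0),
    snr: float = 5.0,
    angle_deg: float = 90.0,
    amplitudes: dict | None = None,
    shared_spontaneous: bool = True,
    frame_rate_hz: float = 5.0,
) -> dict:
    """Generate, preprocess and behaviorally label one synthetic session."""
    schedule = generate_trial_schedule(n_trials, sizes, seed=seed)
    truth = make_ground_truth(
        schedule, n_neurons, angle_deg=angle_deg, shared_spontaneous=shared_spontaneous,
        frame_rate_hz=frame_rate_hz, seed=seed + 1,
    )
    raw = generate_population(
        schedule, truth, n_neurons, frame_rate_hz=frame_rate_hz, snr=snr, seed=seed + 2, amplitudes=amplitudes
    )
    activity = normalize_activity(raw, fit_bleach_trend(raw.values.mean(axis=0), dt_s=1.0 / frame_rate_hz))
    tail = generate_tail_trace(schedule, truth, seed=seed + 3)
    sigma = compute_sigma_active(tail)
    bouts = extract_bouts(tail, sigma)
    labels = label_trials(tail, bouts, schedule, sigma)
    return {
        "schedule": schedule,
        "truth": truth,
        "activity": activity,
        "tail": tail,
        "sigma_active": sigma,
        "bouts": bouts,
        "labels": labels,
    }


def noise_mode_angle(
    seed: int,
    angle_deg: float = 90.0,
    n_neurons: int = 500,
    n_trials: int = 180,
    sizes=(4.0, 11.0, 44.0),
    snr: float = 5.0,
    d_max: int = 6,
    folds: int = 6,
    repeats: int = 1,
) -> dict:
    """Recover the angle between the largest noise mode and w_opt.

    Runs the full chain — schedule, planted ground truth at the requested
    angle, population synthesis, bleach normalization, stimulus-kernel
    PLS, trial features, per-class noise covariance, eigendecomposition —
    and returns the recovered first-mode angle plus diagnostics.
    """
    schedule = generate_trial_schedule(n_trials, sizes, seed=seed)
    truth = make_ground_truth(schedule, n_neurons, angle_deg=angle_deg, seed=seed + 1)
    raw = generate_population(schedule, truth, n_neurons, snr=snr, seed=seed + 2)
    activity = normalize_activity(raw, fit_bleach_trend(raw.values.mean(axis=0), dt_s=1.0 / raw.frame_rate_hz))
    kernel = make_gcamp_kernel(dt_s=1.0 / activity.frame_rate_hz)
    regressor = build_stimulus_kernel(schedule, kernel, activity.frame_rate_hz, activity.n_frames)
    model = fit_pls(activity, regressor, d_max=d_max, folds=folds, repeats=repeats, seed=seed + 3)
    feats = trial_features(activity, schedule)
    geometry = noise_modes(noise_covariance(feats, model), model)
    angles = mode_angles(model.w_opt_latent, geometry)
    e1 = geometry.modes_neurons[:, 0]
    return {
        "theta1_deg": float(angles[0]),
        "angles_deg": angles,
        "d": model.d,
        "var_fraction1": float(geometry.var_fractions[0]),
        "wopt_error_deg": float(np.degrees(np.arccos(min(1.0, abs(model.w_opt @ truth.w_true))))),
        "e1_error_deg": float(np.degrees(np.arccos(min(1.0, abs(e1 @ truth.noise_loadings[0]))))),
        "model": model,
        "geometry": geometry,
        "truth": truth,
    }


def premotor_profile(
    seed: int,
    amplitudes: dict,
    task: str = "turn",
    n_trials: int = 180,
    n_neurons: int = 150,
    n_label_shuffles: int = 3,
    folds: int = 6,
    repeats: int = 2,
    reg_grid=(0.02, 0.2, 2.0),
    start_step: int = 8,
    end_step: int = 2,
):
    """Time-warp one session and sweep classification windows.

    Returns (warped tensor, WindowResult) for the requested task under the
    given planted amplitudes.
    """
    sess = simulate_session(seed, n_trials, n_neurons, amplitudes=amplitudes)
    tensor = time_warp(sess["activity"], sess["schedule"], sess["labels"], seed=seed + 4)
    result = window_classify(
        tensor,
        task,
        folds=folds,
        repeats=repeats,
        reg_grid=reg_grid,
        n_label_shuffles=n_label_shuffles,
        seed=seed + 5,
        min_rt_s=1.0 if task == "turn" else 0.0,
        start_step=start_step,
        end_step=end_step,
    )
    return tensor, result


def transfer_experiment(
    seed: int,
    shared: bool,
    amplitudes: dict | None = None,
    n_trials: int = 240,
    n_neurons: int = 200,
    reg_grid=(0.01, 0.05, 0.2, 1.0),
    window_s: float = 1.0,
) -> dict:
    """Evoked-turn model applied, frozen, to spontaneous pre-motor windows.

    ``shared=True`` plants a single turn circuit driving both evoked and
    spontaneous turns; ``shared=False`` severs the coupling (independent
    spontaneous mechanism), the negative control.
    """
    amplitudes = SCENARIO_AMPLITUDES if amplitudes is None else amplitudes
    sess = simulate_session(seed, n_trials, n_neurons, amplitudes=amplitudes, shared_spontaneous=shared)
    tensor = time_warp(sess["activity"], sess["schedule"], sess["labels"], seed=seed + 4)
    wr = window_classify(
        tensor, "turn", n_label_shuffles=0, seed=seed + 5, min_rt_s=1.0, reg_grid=reg_grid
    )
    model = TurnModel(
        coefs=wr.best_coefs.mean(axis=0),
        intercept=float(wr.best_intercepts.mean()),
        positive_class=str(wr.classes[-1]),
    )
    events = select_spontaneous(sess["bouts"], sess["schedule"], sess["sigma_active"])
    scores, pred, kept = transfer_predict(events, sess["activity"], model, window_s=window_s, all_bouts=sess["bouts"])
    curv = np.array([events[k].mean_curvature for k in kept])
    signs = np.array([events[k].sign for k in kept])
    r, conf, acc = evaluate_transfer(scores, curv, signs, positive_class=model.positive_class)
    return {"r": r, "accuracy": acc, "confusion": conf, "n_events": int(kept.size), "evoked_f": wr.best_f}
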