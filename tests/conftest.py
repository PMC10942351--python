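"""Shared fixtures: a small synthetic session reused across test modules."""

import warnings

import numpy as np
import pytest

from popnoise import (
    compute_sigma_active,
    extract_bouts,
    fit_bleach_trend,
    generate_population,
    generate_tail_trace,
    generate_trial_schedule,
    label_trials,
    make_gcamp_kernel,
    make_ground_truth,
    normalize_activity,
)

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def small_session():
    """A compact session with every planted ingredient present."""
    schedule = generate_trial_schedule(60, (4.0, 11.0, 44.0), seed=101)
    truth = make_ground_truth(schedule, 120, seed=102)
    activity = generate_population(schedule, truth, 120, seed=103)
    tail = generate_tail_trace(schedule, truth, seed=104)
    return {"schedule": schedule, "truth": truth, "raw": activity, "tail": tail}


@pytest.fixture(scope="session")
def normalized_session(small_session):
    raw = small_session["raw"]
    fit = fit_bleach_trend(raw.values.mean(axis=0), dt_s=1.0 / raw.frame_rate_hz)
    out = dict(small_session)
    out["bleach_fit"] = fit
    out["activity"] = normalize_activity(raw, fit)
    return out


@pytest.fixture(scope="session")
def behavior_session(normalized_session):
    tail = normalized_session["tail"]
    sigma = compute_sigma_active(tail)
    bouts = extract_bouts(tail, sigma)
    labels = label_trials(tail, bouts, normalized_session["schedule"], sigma)
    out = dict(normalized_session)
    out.update(sigma_active=sigma, bouts=bouts, labels=labels)
    return out


@pytest.fixture(scope="session")
def frame_kernel():
    return make_gcamp_kernel(dt_s=0.2)
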