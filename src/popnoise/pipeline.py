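"""End-to-end pipeline: simulate -> preprocess -> behavior -> encoding ->
noise geometry -> pre-motor decoding -> spontaneous transfer.

Every stochastic stage draws from a seed recorded in the RunConfig; a
manifest (config hash, package version, per-stage status) is written next
to the results so any output file is traceable to its configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .behavior import compute_sigma_active, extract_bouts, label_trials, vigor_and_direction
from .encoding import build_stimulus_kernel, decode_stimulus, fit_pls, trial_features
from .errors import ConfigurationError
from .geometry import mode_angles, mode_behavior_correlation, noise_covariance, noise_modes, whole_brain_pc1
from .preprocessing import fit_bleach_trend, make_gcamp_kernel, normalize_activity
from .premotor import select_trials, time_warp, window_classify
from .synthetic import generate_population, generate_tail_trace, generate_trial_schedule, make_ground_truth
from .transfer import TurnModel, evaluate_transfer, select_spontaneous, transfer_predict
from . import io as pio

log = logging.getLogger("popnoise.pipeline")


@dataclass
class RunConfig:
    """Seeds, rates, thresholds and sweep grids for a full synthetic run."""

    seed: int = 0
    n_trials: int = 120
    sizes_deg: tuple = (4.0, 11.0, 44.0)
    n_neurons: int = 300
    frame_rate_hz: float = 5.0
    tail_rate_hz: float = 200.0
    snr: float = 5.0
    angle_deg: float = 90.0
    shared_spontaneous: bool = True
    kernel_rise_s: float = 0.3
    kernel_decay_s: float = 3.5
    folds: int = 6
    repeats: int = 3
    d_max: int = 6
    n_shuffles: int = 10
    min_rt_s: float = 1.0
    p_threshold: float = 0.05
    shuffle_sd_rule: float = 3.0
    premotor_tasks: tuple = ("turn", "responsiveness")
    window_start_step: int = 4
    window_end_step: int = 2
    n_label_shuffles: int = 5
    transfer_window_s: float = 1.0
    presession_s: float = 120.0
    n_circular_shifts: int = 200

    def validate(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if self.folds < 2 or self.repeats < 1 or self.n_trials < 1 or self.n_neurons < 12:
            raise ConfigurationError("invalid CV or problem-size configuration")
        if self.snr <= 0 or self.frame_rate_hz <= 0 or self.shuffle_sd_rule <= 0:
            raise ConfigurationError("snr, frame rate and SD rule must be positive")
        for t in self.premotor_tasks:
            if t not in ("turn", "responsiveness", "stimulus"):
                raise ConfigurationError(f"unknown premotor task {t!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("sizes_deg", "premotor_tasks"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["sizes_deg"] = list(self.sizes_deg)
        d["premotor_tasks"] = list(self.premotor_tasks)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    def digest(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True, default=str).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute all stages; write results and a provenance manifest.

    Returns a result bundle (in-memory objects per stage).  On a stage
    failure the manifest records the failing stage and the exception is
    re-raised.
    """
    config.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config_hash": config.digest(),
        "popnoise_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "stages": {},
    }
    config.to_yaml(out / "config.yaml")
    results: dict = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
                manifest["stages"][name] = "ok"
            except Exception as exc:  # noqa: BLE001 - recorded then re-raised
                manifest["stages"][name] = f"failed: {exc}"
                pio.write_json(manifest, out / "manifest.json")
                raise
            return fn

        return deco

    @stage("simulate")
    def _simulate():
        s = config.seed
        schedule = generate_trial_schedule(
            config.n_trials, config.sizes_deg, seed=s, start_s=config.presession_s
        )
        truth = make_ground_truth(
            schedule,
            config.n_neurons,
            frame_rate_hz=config.frame_rate_hz,
            angle_deg=config.angle_deg,
            shared_spontaneous=config.shared_spontaneous,
            seed=s + 1,
        )
        activity = generate_population(
            schedule, truth, config.n_neurons, frame_rate_hz=config.frame_rate_hz, snr=config.snr, seed=s + 2
        )
        tail = generate_tail_trace(schedule, truth, rate_hz=config.tail_rate_hz, seed=s + 3)
        results.update(schedule=schedule, truth=truth, raw_activity=activity, tail=tail)
        pio.write_schedule(schedule, out / "schedule.csv")
        pio.write_activity(activity, out / "activity.h5")
        pio.write_tail(tail, out / "tail.csv")
        pio.write_truth_json(truth, out / "ground_truth.json")

    @stage("preprocess")
    def _preprocess():
        raw = results["raw_activity"]
        fit = fit_bleach_trend(raw.values.mean(axis=0), dt_s=1.0 / raw.frame_rate_hz)
        results["bleach_fit"] = fit
        results["activity"] = normalize_activity(raw, fit)

    @stage("behavior")
    def _behavior():
        tail = results["tail"]
        sigma = compute_sigma_active(tail)
        bouts = extract_bouts(tail, sigma)
        labels = label_trials(tail, bouts, results["schedule"], sigma)
        tail_kernel = make_gcamp_kernel(config.kernel_rise_s, config.kernel_decay_s, 1.0 / tail.rate_hz)
        vigor, direction = vigor_and_direction(
            tail, tail_kernel, config.frame_rate_hz, n_out=results["activity"].n_frames
        )
        results.update(sigma_active=sigma, bouts=bouts, labels=labels, vigor=vigor, direction=direction)
        pio.write_labels(labels, out / "trial_labels.csv")

    @stage("encoding")
    def _encoding():
        act = results["activity"]
        kernel = make_gcamp_kernel(config.kernel_rise_s, config.kernel_decay_s, 1.0 / act.frame_rate_hz)
        regressor = build_stimulus_kernel(results["schedule"], kernel, act.frame_rate_hz, act.n_frames)
        model = fit_pls(act, regressor, d_max=config.d_max, folds=config.folds, repeats=1, seed=config.seed + 10)
        feats = trial_features(act, results["schedule"])
        decoded = decode_stimulus(feats, folds=config.folds, repeats=config.repeats, seed=config.seed + 11)
        results.update(kernel=kernel, regressor=regressor, pls=model, features=feats, decoded=decoded)
        pio.write_json(
            {
                "d": model.d,
                "cv_mse": model.cv_mse,
                "decode_accuracy": decoded.accuracy,
                "decode_classes": decoded.classes,
                "decode_confusion": decoded.confusion,
            },
            out / "encoding.json",
        )

    @stage("geometry")
    def _geometry():
        model = results["pls"]
        geom = noise_modes(noise_covariance(results["features"], model), model)
        angles = mode_angles(model.w_opt_latent, geom)
        geom.angles_deg = angles
        act = results["activity"]
        scores = model.project(act.values.T)
        e1_series = scores @ geom.modes_latent[:, 0]
        r, _, p = mode_behavior_correlation(
            e1_series,
            results["vigor"],
            n_shifts=config.n_circular_shifts,
            seed=config.seed + 20,
            rate_hz=act.frame_rate_hz,
        )
        pc1_series, pc1_loadings = whole_brain_pc1(act, vigor=results["vigor"])
        results.update(geometry=geom, mode_vigor_r=r, mode_vigor_p=p, pc1=(pc1_series, pc1_loadings))
        pio.write_json(
            {
                "eigvals": geom.eigvals,
                "var_fractions": geom.var_fractions,
                "angles_deg": angles,
                "mode1_vigor_r": r,
                "mode1_vigor_p": p,
            },
            out / "geometry.json",
        )

    @stage("premotor")
    def _premotor():
        act = results["activity"]
        labels = results["labels"]
        select_trials(labels, min_rt_s=config.min_rt_s)
        tensor = time_warp(act, results["schedule"], labels, seed=config.seed + 30)
        window_results = {}
        for task in config.premotor_tasks:
            window_results[task] = window_classify(
                tensor,
                task,
                folds=config.folds,
                repeats=config.repeats,
                n_label_shuffles=config.n_label_shuffles,
                seed=config.seed + 31,
                min_rt_s=config.min_rt_s if task == "turn" else 0.0,
                start_step=config.window_start_step,
                end_step=config.window_end_step,
            )
        results.update(warped=tensor, windows=window_results)
        pio.write_json(
            {
                task: {
                    "ends": wr.ends,
                    "profile_f": wr.profile_f,
                    "profile_shuffled_f": wr.profile_shuffled_f,
                    "profile_p": wr.profile_p,
                    "best_window": list(wr.best_window),
                    "best_f": wr.best_f,
                }
                for task, wr in window_results.items()
            },
            out / "premotor.json",
        )

    @stage("transfer")
    def _transfer():
        if "turn" not in results["windows"]:
            manifest["stages"]["transfer"] = "skipped: no turn model"
            return
        wr = results["windows"]["turn"]
        model = TurnModel(
            coefs=wr.best_coefs.mean(axis=0),
            intercept=float(wr.best_intercepts.mean()),
            positive_class=str(wr.classes[-1]),
        )
        events = select_spontaneous(
            results["bouts"], results["schedule"], results["sigma_active"], presession_s=config.presession_s
        )
        if len(events) < 3:
            manifest["stages"]["transfer"] = "skipped: fewer than 3 spontaneous events"
            results["transfer"] = None
            return
        scores, pred, kept = transfer_predict(
            events, results["activity"], model, window_s=config.transfer_window_s, all_bouts=results["bouts"]
        )
        curv = np.array([events[k].mean_curvature for k in kept])
        signs = np.array([events[k].sign for k in kept])
        r, conf, acc = evaluate_transfer(scores, curv, signs, positive_class=model.positive_class)
        results["transfer"] = {"r": r, "confusion": conf, "accuracy": acc, "n_events": int(kept.size)}
        pio.write_json(results["transfer"], out / "transfer.json")

    pio.write_json(manifest, out / "manifest.json")
    results["manifest"] = manifest
    return results
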