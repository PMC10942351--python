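"""Standard-format I/O: HDF5 activity containers and CSV/JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import TailTrace, TrialLabels
from .errors import SchemaError
from .preprocessing import ActivityMatrix
from .synthetic import TrialSchedule


def write_activity(activity: ActivityMatrix, path) -> None:
    """Write the canonical HDF5 layout: /activity, /positions, /regions,
    attrs: frame_rate_hz."""
    with h5py.File(path, "w") as f:
        f.create_dataset("activity", data=activity.values)
        f.create_dataset("positions", data=activity.positions_um)
        f.create_dataset("regions", data=np.asarray(activity.regions, dtype="S8"))
        f.attrs["frame_rate_hz"] = activity.frame_rate_hz


def read_activity(path) -> ActivityMatrix:
    with h5py.File(path, "r") as f:
        for key in ("activity", "positions", "regions"):
            if key not in f:
                raise SchemaError(f"activity file {path} is missing dataset '/{key}'")
        if "frame_rate_hz" not in f.attrs:
            raise SchemaError(f"activity file {path} is missing attribute 'frame_rate_hz'")
        return ActivityMatrix(
            values=f["activity"][()],
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            positions_um=f["positions"][()],
            regions=f["regions"][()].astype("U8"),
        )


def write_schedule(schedule: TrialSchedule, path) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_schedule(path) -> TrialSchedule:
    df = pd.read_csv(path)
    missing = {"trial_id", "size_deg", "side", "onset_s", "duration_s"} - set(df.columns)
    if missing:
        raise SchemaError(f"schedule file {path} is missing columns {sorted(missing)}")
    return TrialSchedule(
        trial_id=df["trial_id"].to_numpy(),
        size_deg=df["size_deg"].to_numpy(),
        side=df["side"].to_numpy(),
        onset_s=df["onset_s"].to_numpy(),
        duration_s=df["duration_s"].to_numpy(),
    )


def write_tail(trace: TailTrace, path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "curvature": trace.curvature}).to_csv(path, index=False)


def read_tail(path, rate_hz: float | None = None) -> TailTrace:
    df = pd.read_csv(path)
    missing = {"time_s", "curvature"} - set(df.columns)
    if missing:
        raise SchemaError(f"tail file {path} is missing columns {sorted(missing)}")
    t = df["time_s"].to_numpy()
    if rate_hz is None:
        rate_hz = 1.0 / float(np.median(np.diff(t)))
    return TailTrace(time_s=t, curvature=df["curvature"].to_numpy(), rate_hz=rate_hz)


def write_labels(labels: TrialLabels, path) -> None:
    pd.DataFrame(
        {
            "trial_id": labels.trial_id,
            "responded": labels.responded,
            "turn": labels.turn,
            "reaction_time_s": labels.reaction_time_s,
            "mean_bout_curvature": labels.mean_bout_curvature,
        }
    ).to_csv(path, index=False)


def write_truth_json(truth, path) -> None:
    """Ground-truth sidecar (loadings and per-trial outcomes) as JSON."""
    payload = {
        "seed": truth.seed,
        "angle_deg": truth.angle_deg,
        "sizes_deg": truth.sizes_deg.tolist(),
        "factor_names": list(truth.factor_names),
        "w_true": truth.w_true.tolist(),
        "noise_loadings": truth.noise_loadings.tolist(),
        "turn_truth": truth.turn_truth.tolist(),
        "responded": truth.responded.astype(bool).tolist(),
        "reaction_time_s": [None if not np.isfinite(v) else float(v) for v in truth.reaction_time_s],
        "spont_onset_s": truth.spont_onset_s.tolist(),
        "spont_sign": truth.spont_sign.tolist(),
        "shared_spontaneous": truth.shared_spontaneous,
    }
    Path(path).write_text(json.dumps(payload))


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
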