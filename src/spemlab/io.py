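"""Plain-text interchange formats.

Traces and stimuli travel as CSV so that sessions recorded or simulated
anywhere can be re-analysed: one trace file per trial
(``time_ms,eye_deg,valid``), one target file per trial
(``time_ms,target_deg,target_vel``), and a session manifest
(``trial_id,task_kind,direction,motion_onset_ms,eligible,ramp_velocity,
reversal_times``).  Feature tables are CSV with empty cells for missing
measures.  Trained models are saved as a joblib blob next to a JSON
metadata twin.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .features import EyeTrace
from .stimulus import TargetTrajectory

__all__ = [
    "write_session",
    "read_session",
    "write_feature_table",
    "read_feature_table",
    "save_model",
    "load_model",
]

FEATURE_COLUMNS = ["subject_id", "group", "gain_pred", "gain_early", "accel", "latency"]


def write_session(session: list[EyeTrace], out_dir: str | Path) -> Path:
    """Write traces, targets and the manifest for one session."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for trace in session:
        trial = trace.trial
        if trial is None:
            raise ValueError("trace without trial metadata cannot be serialized")
        tid = trial.trial_id
        pd.DataFrame(
            {
                "time_ms": trace.times,
                "eye_deg": trace.eye_positions,
                "valid": trace.valid.astype(int),
            }
        ).to_csv(out / f"trace_{tid:03d}.csv", index=False)
        pd.DataFrame(
            {
                "time_ms": trial.times,
                "target_deg": trial.positions,
                "target_vel": trial.velocities,
            }
        ).to_csv(out / f"target_{tid:03d}.csv", index=False)
        rows.append(
            {
                "trial_id": tid,
                "task_kind": trial.task_kind,
                "direction": trial.direction,
                "motion_onset_ms": trial.motion_onset,
                "eligible": int(trial.analysis_eligible),
                "ramp_velocity": trial.ramp_velocity,
                "sampling_rate": trial.sampling_rate,
                "reversal_times": ";".join(f"{t:.6g}" for t in trial.reversal_times),
            }
        )
    manifest = out / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_session(session_dir: str | Path) -> list[EyeTrace]:
    """Load a session written by :func:`write_session`."""
    root = Path(session_dir)
    manifest = pd.read_csv(root / "manifest.csv")
    session: list[EyeTrace] = []
    for row in manifest.itertuples(index=False):
        tid = int(row.trial_id)
        tgt = pd.read_csv(root / f"target_{tid:03d}.csv")
        revs = (
            np.array([float(x) for x in str(row.reversal_times).split(";") if x])
            if isinstance(row.reversal_times, str) or not pd.isna(row.reversal_times)
            else np.empty(0)
        )
        trial = TargetTrajectory(
            times=tgt["time_ms"].to_numpy(float),
            positions=tgt["target_deg"].to_numpy(float),
            velocities=tgt["target_vel"].to_numpy(float),
            motion_onset=float(row.motion_onset_ms),
            direction=int(row.direction),
            task_kind=str(row.task_kind),
            analysis_eligible=bool(row.eligible),
            ramp_velocity=float(row.ramp_velocity),
            sampling_rate=float(row.sampling_rate),
            reversal_times=revs,
            trial_id=tid,
        )
        tr = pd.read_csv(root / f"trace_{tid:03d}.csv")
        session.append(
            EyeTrace(
                times=tr["time_ms"].to_numpy(float),
                eye_positions=tr["eye_deg"].to_numpy(float),
                valid=tr["valid"].to_numpy(bool),
                sampling_rate=float(row.sampling_rate),
                trial=trial,
            )
        )
    return session


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, na_rep="")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def save_model(model, path: str | Path) -> Path:
    """Persist a fitted classifier: joblib blob + JSON metadata twin."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, path)
    meta = {
        "best_config": getattr(model, "best_config_", None),
        "classes": [str(c) for c in getattr(model, "classes_", [])],
        "n_features": int(getattr(model, "n_features_in_", 0)),
        "random_state": getattr(model, "random_state", None),
        "mean_bac": getattr(model, "cv_result_", None)
        and model.cv_result_.mean.balanced_accuracy,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2, default=str))
    return path


def load_model(path: str | Path):
    return joblib.load(path)
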