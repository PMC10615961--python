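"""CSV table schemas and round-trip readers/writers.

All inter-stage artifacts are plain CSV (RFC-4180, header row always
present): the cohort table, gaze streams, EEG signal matrices with a
channel-map, and the attempt-wise feature table.  Readers validate the
schema and report offending columns/rows; unknown extra columns are kept
with a warning for forward compatibility.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .eegnet import CortexMap, EEGRecording
from .gaze import GazeRecording
from .names import ALL_FEATURES, EXPERIENCE_FEATURES, KEY_COLUMNS, SCORE_COLUMN

GAZE_COLUMNS = ("timestamp_s", "eye", "gaze_x_deg", "gaze_y_deg", "pupil_mm", "valid")


# ---------------------------------------------------------------------------
# feature table


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in (*KEY_COLUMNS, SCORE_COLUMN) if c not in table.columns]
    if missing and missing != [SCORE_COLUMN]:
        raise ValueError(f"feature table missing required columns: {missing}")
    table.to_csv(path, index=False)


def read_feature_table(path: str | Path, require_score: bool = True) -> pd.DataFrame:
    """Read and validate an attempt-wise feature table.

    Requires the key columns (participant_id, task, attempt) and, by
    default, the score column; rejects duplicated keys naming the rows.
    """
    table = pd.read_csv(path)
    required = list(KEY_COLUMNS) + ([SCORE_COLUMN] if require_score else [])
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"feature table at {path} is missing columns: {missing}")
    dup = table.duplicated(subset=list(KEY_COLUMNS))
    if dup.any():
        rows = (np.flatnonzero(dup) + 2).tolist()  # 1-based incl. header
        raise ValueError(f"duplicate (participant, task, attempt) keys at rows {rows}")
    known = set(required) | set(ALL_FEATURES) | {"level", "baseline_score", "learning_rate"}
    extra = [c for c in table.columns if c not in known]
    if extra:
        warnings.warn(f"unknown columns preserved: {extra}", stacklevel=2)
    bad_attempt = table[~table["attempt"].astype(float).between(1, 1e6)]
    if len(bad_attempt):
        raise ValueError("attempt numbers must be >= 1")
    return table


# ---------------------------------------------------------------------------
# gaze streams


def write_gaze_csv(recording: GazeRecording, path: str | Path) -> None:
    """Long-format gaze CSV, one row per (sample, eye)."""
    frames = []
    for eye in ("left", "right"):
        frames.append(
            pd.DataFrame(
                {
                    "timestamp_s": recording.timestamps,
                    "eye": eye,
                    "gaze_x_deg": recording.gaze_x[eye],
                    "gaze_y_deg": recording.gaze_y[eye],
                    "pupil_mm": recording.pupil[eye],
                    "valid": recording.valid.astype(int),
                }
            )
        )
    pd.concat(frames).sort_values(["timestamp_s", "eye"]).to_csv(path, index=False)


def read_gaze_csv(
    path: str | Path, dominant_eye: str = "right", sampling_rate: float | None = None
) -> GazeRecording:
    df = pd.read_csv(path)
    missing = [c for c in GAZE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"gaze CSV at {path} is missing columns: {missing}")
    eyes = {}
    for eye in ("left", "right"):
        sub = df[df["eye"] == eye].sort_values("timestamp_s")
        if sub.empty:
            raise ValueError(f"gaze CSV has no rows for the {eye} eye")
        eyes[eye] = sub
    t = eyes["left"]["timestamp_s"].to_numpy(dtype=float)
    if sampling_rate is None:
        sampling_rate = float(1.0 / np.median(np.diff(t))) if t.size > 1 else 50.0
    return GazeRecording(
        timestamps=t,
        gaze_x={e: eyes[e]["gaze_x_deg"].to_numpy(dtype=float) for e in eyes},
        gaze_y={e: eyes[e]["gaze_y_deg"].to_numpy(dtype=float) for e in eyes},
        pupil={e: eyes[e]["pupil_mm"].to_numpy(dtype=float) for e in eyes},
        valid=eyes["left"]["valid"].to_numpy(dtype=float).astype(bool)
        & eyes["right"]["valid"].to_numpy(dtype=float).astype(bool),
        dominant_eye=dominant_eye,
        sampling_rate=sampling_rate,
    )


# ---------------------------------------------------------------------------
# EEG


def write_eeg_csv(recording: EEGRecording, signal_path: str | Path) -> None:
    """Dense channels x samples matrix, one row per channel, first column
    the channel name."""
    df = pd.DataFrame(recording.signal)
    df.insert(0, "channel", recording.channel_names)
    df.to_csv(signal_path, index=False)


def read_eeg_csv(signal_path: str | Path, sampling_rate: float = 500.0) -> EEGRecording:
    df = pd.read_csv(signal_path)
    if "channel" not in df.columns:
        raise ValueError("EEG CSV must have a 'channel' first column")
    names = df["channel"].astype(str).tolist()
    signal = df.drop(columns=["channel"]).to_numpy(dtype=float)
    return EEGRecording(signal, sampling_rate, names)


def write_channel_map(cortex_map: CortexMap, path: str | Path) -> None:
    pd.DataFrame(
        {"channel": list(cortex_map.assignment), "cortex": list(cortex_map.assignment.values())}
    ).to_csv(path, index=False)


def read_channel_map(path: str | Path) -> CortexMap:
    df = pd.read_csv(path)
    for col in ("channel", "cortex"):
        if col not in df.columns:
            raise ValueError(f"channel map missing column {col!r}")
    return CortexMap(dict(zip(df["channel"].astype(str), df["cortex"].astype(str))))


# ---------------------------------------------------------------------------
# cohort and ground truth


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ("participant_id", "level", *EXPERIENCE_FEATURES) if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV missing columns: {missing}")
    return df


def write_ground_truth_json(truth, path: str | Path) -> None:
    payload = {
        "active_features": sorted(truth.active_features),
        "coefficients": truth.coefficients,
        "slope_coefficients": truth.slope_coefficients,
        "intercepts": truth.intercepts,
        "slopes": truth.slopes,
        "base_score": truth.base_score,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
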