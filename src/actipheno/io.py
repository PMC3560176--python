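"""Plain-text file schemas: trajectory TSV, response CSV, cohort CSV, config.

Trajectory files are TSV with columns
``marker_id, frame_index, time_s, x_mm, y_mm, valid`` (valid is 0/1).
Trial/response logs are CSV with columns
``task, trial_index, onset_ms, stimulus_code, is_target, responded, rt_ms,
block, sub_block, isi_ms``.  Cohort tables are CSV with one row per subject.
Study configuration round-trips through a flat YAML mapping with a
top-level master seed.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .motion import Trajectory
from .pipeline import StudyConfig

TRAJECTORY_COLUMNS = ["marker_id", "frame_index", "time_s", "x_mm", "y_mm", "valid"]
RESPONSE_COLUMNS = ["task", "trial_index", "onset_ms", "stimulus_code",
                    "is_target", "responded", "rt_ms", "block", "sub_block",
                    "isi_ms"]


def write_trajectory(traj: Trajectory, path) -> None:
    df = pd.DataFrame({
        "marker_id": traj.marker_id,
        "frame_index": np.arange(traj.n_frames),
        "time_s": traj.time,
        "x_mm": traj.x,
        "y_mm": traj.y,
        "valid": traj.valid.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)


def read_trajectory(path) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file missing columns: {sorted(missing)}")
    marker = str(df["marker_id"].iloc[0])
    return Trajectory(marker, df["time_s"].to_numpy(float),
                      df["x_mm"].to_numpy(float), df["y_mm"].to_numpy(float),
                      df["valid"].to_numpy(int).astype(bool))


def write_responses(responses: pd.DataFrame, path) -> None:
    df = responses.reindex(columns=RESPONSE_COLUMNS)
    df.to_csv(path, index=False)


def read_responses(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(RESPONSE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"response log missing columns: {sorted(missing)}")
    df["is_target"] = df["is_target"].astype(bool)
    df["responded"] = df["responded"].astype(bool)
    return df


def write_config(config: StudyConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


def read_config(path) -> StudyConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in StudyConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return StudyConfig(**data)
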