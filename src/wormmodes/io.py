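"""Track-table format: one delimited-text row per frame, versioned header.

Columns: ``track_id, frame_index, time_s, centroid_x_mm, centroid_y_mm,
state, valid, angle_01 … angle_24``. Angles are radians (|angle| ≤ π),
coordinates mm, time seconds; missing values are empty fields (NaN).
The first line is a version comment so readers can check the schema.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import INVALID, STATE_CODES, STATE_NAMES, PostureSeries, StateLabels, Track

SCHEMA_VERSION = "wormmodes-track-table v1"

ANGLE_COLS = [f"angle_{k:02d}" for k in range(1, 25)]
BASE_COLS = ["track_id", "frame_index", "time_s", "centroid_x_mm",
             "centroid_y_mm", "state", "valid"]


def write_track_table(tracks: list[Track], path,
                      labels: list[StateLabels] | None = None) -> None:
    """Serialize tracks (with posture and states when present) to one file."""
    frames = []
    for i, tr in enumerate(tracks):
        n = tr.n_frames
        df = pd.DataFrame({
            "track_id": np.full(n, tr.track_id, dtype=int),
            "frame_index": np.arange(n),
            "time_s": tr.timestamps,
            "centroid_x_mm": tr.centroid[:, 0],
            "centroid_y_mm": tr.centroid[:, 1],
        })
        if labels is not None and labels[i] is not None:
            df["state"] = labels[i].as_strings()
        elif tr.state_truth is not None:
            df["state"] = tr.state_truth.as_strings()
        else:
            df["state"] = "forward"
        if tr.posture is not None:
            df["valid"] = tr.posture.valid.astype(int)
            for k, col in enumerate(ANGLE_COLS):
                df[col] = tr.posture.angles[:, k]
        else:
            df["valid"] = 1
            for col in ANGLE_COLS:
                df[col] = np.nan
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    buf = _io.StringIO()
    buf.write(f"# {SCHEMA_VERSION}\n")
    table.to_csv(buf, sep="\t", index=False, float_format="%.12g")
    Path(path).write_text(buf.getvalue())


def read_track_table(path) -> list[Track]:
    """Read a track table back into Track objects (lossless to ~1e-12).

    Raises on a schema-version mismatch, missing columns or angle values
    outside ±π (which indicates degrees were stored by mistake).
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if first != f"# {SCHEMA_VERSION}":
        raise ValueError(f"schema mismatch: expected '{SCHEMA_VERSION}', "
                         f"found '{first.lstrip('# ')}'")
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in BASE_COLS + ANGLE_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {', '.join(missing)}")
    ang = df[ANGLE_COLS].to_numpy(dtype=float)
    if np.nanmax(np.abs(ang), initial=0.0) > np.pi:
        raise ValueError("angle unit violation: |angle| > pi (degrees stored?)")
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame_index")
        n = len(g)
        times = g["time_s"].to_numpy()
        if n > 1:
            dt = np.diff(times)
            frame_rate = 1.0 / np.median(dt)
        else:
            frame_rate = 1.0
        angles = g[ANGLE_COLS].to_numpy(dtype=float)
        valid = g["valid"].to_numpy(dtype=bool)
        posture = None
        if np.isfinite(angles).any():
            posture = PostureSeries(angles, frame_rate=frame_rate, valid=valid,
                                    t0=float(times[0]))
        state = np.array([STATE_CODES.get(s, INVALID) for s in g["state"]],
                         dtype=np.int8)
        tracks.append(Track(
            centroid=g[["centroid_x_mm", "centroid_y_mm"]].to_numpy(dtype=float),
            frame_rate=frame_rate,
            posture=posture,
            t0=float(times[0]),
            track_id=int(tid),
            state_truth=StateLabels(state),
        ))
    return tracks


def write_recording(recording, path_prefix) -> tuple[Path, Path]:
    """Serialize a SyntheticRecording: track table + ground-truth side-car."""
    prefix = Path(path_prefix)
    table_path = prefix.with_suffix(".tsv")
    truth_path = prefix.with_suffix(".truth.yaml")
    write_track_table([recording.track], table_path,
                      labels=[recording.truth_labels])
    p = recording.truth_params
    truth = {
        "kinematic_params": {k: getattr(p, k) for k in p.__dataclass_fields__},
        "stimulus": {"kind": recording.stimulus.kind,
                     "breakpoints": [list(b) for b in recording.stimulus.breakpoints]},
        "coupling": {k: getattr(recording.coupling, k)
                     for k in recording.coupling.__dataclass_fields__},
    }
    truth_path.write_text(yaml.safe_dump(truth, sort_keys=True))
    return table_path, truth_path
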