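"""Delimited-text readers and writers for tracks, plates, traces and results.

All formats are plain CSV so that fixtures and outputs stay human-readable:
tracks (frame, time_s, head/tail/centroid x,y in mm), patch polygons as
x_mm,y_mm vertex lists (implicitly closed), plate-count tables, EPG traces
(time_s, voltage) with a sidecar ground-truth event list, and per-worm
kinetic estimate tables.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import Polygon

from .core import TRACK_COLUMNS, ArenaGeometry, TrackRecording
from .epg import EPGTrace


def write_track(track: TrackRecording, path) -> None:
    track.frames.to_csv(path, index=False)


def read_track(path, arena: ArenaGeometry, worm_id: str | None = None) -> TrackRecording:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing track columns {missing}")
    return TrackRecording(df, arena, worm_id or Path(path).stem)


def write_patch(patch: Polygon, path) -> None:
    xy = np.asarray(patch.exterior.coords)[:-1]  # closing vertex implicit
    pd.DataFrame({"x_mm": xy[:, 0], "y_mm": xy[:, 1]}).to_csv(path, index=False)


def read_patch(path) -> Polygon:
    df = pd.read_csv(path)
    poly = Polygon(df[["x_mm", "y_mm"]].to_numpy(float))
    if not poly.is_valid or poly.area <= 0:
        raise ValueError(f"{path}: degenerate patch polygon")
    return poly


PLATE_COLUMNS = ["plate_id", "condition", "od_normal", "od_elongated",
                 "n_normal", "n_elongated"]


def write_plates(plates: pd.DataFrame, path) -> None:
    plates[PLATE_COLUMNS].to_csv(path, index=False)


def read_plates(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing plate columns {missing}")
    return df


def write_epg(trace: EPGTrace, path, truth_times=None) -> None:
    """Write a trace as (time_s, voltage); truth times go to a sidecar file."""
    pd.DataFrame({"time_s": trace.times, "voltage": trace.voltage}).to_csv(
        path, index=False
    )
    if truth_times is not None:
        sidecar = Path(path).with_suffix(".events.csv")
        pd.DataFrame({"time_s": np.asarray(truth_times)}).to_csv(sidecar, index=False)


def read_epg(path, fs: float | None = None, worm_id: str | None = None) -> EPGTrace:
    df = pd.read_csv(path)
    if fs is None:
        dt = np.diff(df["time_s"].to_numpy(float))
        if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=1e-6):
            raise ValueError(f"{path}: non-uniform sampling; pass fs explicitly")
        fs = 1.0 / dt[0]
    return EPGTrace(df["voltage"].to_numpy(float), fs, worm_id or Path(path).stem)


def write_estimates(per_worm: pd.DataFrame, path) -> None:
    per_worm.to_csv(path, index=False)
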