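"""Shared containers: arena geometry, track recordings, dwell intervals, estimates.

Coordinates are in millimetres with the arena (well) centred at the origin;
times are in seconds; rate constants are reported per minute.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.geometry.base import BaseGeometry

#: The three kinetic states: On Food, At Border, Off Food.
STATES = ("F", "B", "O")

#: The four admissible transitions of the linear F-B-O chain.
TRANSITIONS = (("F", "B"), ("B", "O"), ("O", "B"), ("B", "F"))

TRACK_COLUMNS = (
    "frame",
    "time_s",
    "head_x_mm",
    "head_y_mm",
    "tail_x_mm",
    "tail_y_mm",
    "centroid_x_mm",
    "centroid_y_mm",
)


def _default_patch() -> Polygon:
    """Circular food patch of diameter 3.5 mm centred in the well."""
    return Point(0.0, 0.0).buffer(1.75, quad_segs=90)


@dataclass(frozen=True)
class ArenaGeometry:
    """Circular assay well with a central food patch.

    Parameters
    ----------
    well_radius : float
        Radius of the agar-filled well, mm (10 mm diameter wells by default).
    patch : shapely geometry
        Closed polygon tracing the food-patch margin, mm. Defaults to a
        centred circle of diameter 3.5 mm.
    delta : float
        Contact tolerance, mm: a body point within ``delta`` of the patch
        counts as touching food.
    """

    well_radius: float = 5.0
    patch: BaseGeometry = field(default_factory=_default_patch)
    delta: float = 0.0

    def __post_init__(self) -> None:
        if self.well_radius <= 0:
            raise ValueError("well_radius must be positive")
        if self.delta < 0:
            raise ValueError("delta must be non-negative")
        validate_patch(self.patch)
        well = Point(0.0, 0.0).buffer(self.well_radius, quad_segs=90)
        if not (self.patch.within(well) and self.patch.distance(well.exterior) > 0):
            raise ValueError("patch must lie strictly inside the well")

    @property
    def well(self) -> Polygon:
        return Point(0.0, 0.0).buffer(self.well_radius, quad_segs=90)


def validate_patch(patch: BaseGeometry) -> None:
    """Reject degenerate patch outlines (non-polygonal, self-intersecting, flat)."""
    if not isinstance(patch, Polygon):
        raise ValueError("patch must be a simple closed polygon")
    if not patch.is_valid:
        raise ValueError("patch polygon is invalid (self-intersecting?)")
    if patch.area <= 0 or len(patch.exterior.coords) < 4:
        raise ValueError("patch polygon is degenerate")


@dataclass
class TrackRecording:
    """Time-stamped head/tail/centroid positions of one worm plus geometry."""

    frames: pd.DataFrame
    arena: ArenaGeometry
    worm_id: str = "worm"

    def __post_init__(self) -> None:
        missing = [c for c in TRACK_COLUMNS if c not in self.frames.columns]
        if missing:
            raise ValueError(f"track table is missing columns: {missing}")
        t = self.frames["time_s"].to_numpy(float)
        if len(t) == 0:
            raise ValueError("empty track")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("time_s must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return self.frames["time_s"].to_numpy(float)

    @property
    def head(self) -> np.ndarray:
        return self.frames[["head_x_mm", "head_y_mm"]].to_numpy(float)

    @property
    def tail(self) -> np.ndarray:
        return self.frames[["tail_x_mm", "tail_y_mm"]].to_numpy(float)

    @property
    def centroid(self) -> np.ndarray:
        return self.frames[["centroid_x_mm", "centroid_y_mm"]].to_numpy(float)

    @property
    def duration(self) -> float:
        t = self.times
        return float(t[-1] - t[0])


@dataclass(frozen=True)
class DwellInterval:
    """One uninterrupted visit to a kinetic state."""

    state: str
    t_start: float
    t_end: float
    censored_start: bool = False
    censored_end: bool = False

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class StateSegmentation:
    """Per-frame labels plus the dwell intervals they induce."""

    intervals: list[DwellInterval]
    labels: np.ndarray
    timestamps: np.ndarray

    @property
    def total_time(self) -> float:
        return float(sum(iv.duration for iv in self.intervals))

    def occupancy(self) -> dict[str, float]:
        """Seconds spent in each state."""
        occ = {s: 0.0 for s in STATES}
        for iv in self.intervals:
            occ[iv.state] += iv.duration
        return occ

    def transition_counts(self) -> dict[tuple[str, str], int]:
        """Counts of the four admissible transitions at interval junctions."""
        counts = {tr: 0 for tr in TRANSITIONS}
        for a, b in zip(self.intervals[:-1], self.intervals[1:]):
            key = (a.state, b.state)
            if key not in counts:
                raise ValueError(
                    f"illegal adjacency {a.state}->{b.state}; run segment_states "
                    "with repair=True"
                )
            counts[key] += 1
        return counts

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state": [iv.state for iv in self.intervals],
                "t_start": [iv.t_start for iv in self.intervals],
                "t_end": [iv.t_end for iv in self.intervals],
                "censored_start": [iv.censored_start for iv in self.intervals],
                "censored_end": [iv.censored_end for iv in self.intervals],
            }
        )


@dataclass(frozen=True)
class KineticEstimates:
    """State probabilities, rate constants and their sufficient statistics.

    ``P_s`` is the fraction of observation time in state ``s``; ``k_XY`` is
    the number of X->Y transitions divided by the total time in X, reported
    per minute.  A rate whose origin state was never visited is NaN.
    """

    P_F: float
    P_B: float
    P_O: float
    k_FB: float
    k_BO: float
    k_OB: float
    k_BF: float
    N_FB: int
    N_BO: int
    N_OB: int
    N_BF: int
    T_F: float
    T_B: float
    T_O: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.__dict__)


@dataclass(frozen=True)
class SpeedSummary:
    """Mean centroid speeds on food (state F) and off food (state O), mm/s."""

    speed_on: float
    speed_off: float
    n_on: int
    n_off: int


def states_at(intervals: Sequence, times: np.ndarray) -> np.ndarray:
    """State of an interval sequence at each query time.

    A time falling exactly on a boundary between two intervals belongs to the
    earlier interval; times beyond the last interval take its state.
    """
    ends = np.array([iv.t_end for iv in intervals], float)
    idx = np.minimum(np.searchsorted(ends, np.asarray(times, float), side="left"),
                     len(intervals) - 1)
    states = np.array([iv.state for iv in intervals])
    return states[idx]
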