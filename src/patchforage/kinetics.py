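"""Three-state patch-leaving kinetics: classification, segmentation, estimation.

Each video frame is classified by zone occupancy of the worm's two body
points: F (On Food, both head and tail in contact with the patch), B (At
Border, exactly one in contact), O (Off Food, neither).  Runs of equal labels
become dwell intervals; state probabilities are occupancy-time fractions and
rate constants are transition counts divided by time in the state of origin.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point
from shapely.geometry.base import BaseGeometry

from .core import (
    STATES,
    DwellInterval,
    KineticEstimates,
    SpeedSummary,
    StateSegmentation,
    TrackRecording,
    validate_patch,
)

__all__ = [
    "classify_frame",
    "classify_frames",
    "segment_states",
    "estimate_kinetics",
    "compute_speeds",
    "interpolate_gaps",
    "PatchKineticsModel",
    "PatchKineticsResults",
]


# ---------------------------------------------------------------------------
# Frame classification
# ---------------------------------------------------------------------------

def classify_frame(head, tail, patch: BaseGeometry, delta: float = 0.0) -> str:
    """Classify one frame from head and tail positions.

    A body point is "in contact" when it lies within ``delta`` mm of the
    patch (inside or on the boundary counts as distance zero).
    """
    head = np.asarray(head, float)
    tail = np.asarray(tail, float)
    if not (np.all(np.isfinite(head)) and np.all(np.isfinite(tail))):
        raise ValueError("head/tail coordinates must be finite")
    validate_patch(patch)
    n_contact = int(patch.distance(Point(head)) <= delta) + int(
        patch.distance(Point(tail)) <= delta
    )
    return ("O", "B", "F")[n_contact]


def classify_frames(track: TrackRecording, patch=None, delta=None) -> np.ndarray:
    """Vectorised per-frame state labels for a whole track."""
    patch = track.arena.patch if patch is None else patch
    delta = track.arena.delta if delta is None else delta
    validate_patch(patch)
    head_pts = shapely.points(track.head)
    tail_pts = shapely.points(track.tail)
    contact = (shapely.distance(patch, head_pts) <= delta).astype(int) + (
        shapely.distance(patch, tail_pts) <= delta
    ).astype(int)
    return np.array(["O", "B", "F"])[contact]


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def _run_lengths(labels: np.ndarray) -> list[tuple[str, int, int]]:
    """(state, first_index, last_index) for each maximal run of equal labels."""
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((str(labels[start]), start, i - 1))
            start = i
    return runs


def segment_states(
    labels,
    timestamps,
    debounce: int = 1,
    repair: bool = True,
) -> StateSegmentation:
    """Turn per-frame labels into dwell intervals.

    Interval boundaries fall at the midpoint between the two frames flanking
    each label change.  Runs shorter than ``debounce`` frames flanked by a
    single state are merged into it (default 1, i.e. off).  With ``repair``,
    any direct F->O or O->F adjacency — physically impossible, since the
    border zone must be crossed — gets a bridging B interval one inter-frame
    period long, taken symmetrically from its neighbours.  The first and last
    intervals are flagged as censored at the recording edges.
    """
    labels = np.asarray(labels)
    t = np.asarray(timestamps, float)
    if len(labels) == 0:
        raise ValueError("empty input")
    if len(labels) != len(t):
        raise ValueError("labels and timestamps differ in length")
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError("timestamps must be strictly increasing")
    bad = set(np.unique(labels)) - set(STATES)
    if bad:
        raise ValueError(f"unknown state labels: {sorted(bad)}")

    seq = list(labels)
    if debounce > 1:
        changed = True
        while changed:
            changed = False
            runs = _run_lengths(np.array(seq))
            for r, (state, i0, i1) in enumerate(runs):
                n = i1 - i0 + 1
                if n < debounce and 0 < r < len(runs) - 1:
                    prev_s, next_s = runs[r - 1][0], runs[r + 1][0]
                    if prev_s == next_s:  # blip inside one state
                        for j in range(i0, i1 + 1):
                            seq[j] = prev_s
                        changed = True
                        break

    runs = _run_lengths(np.array(seq))
    intervals: list[DwellInterval] = []
    for r, (state, i0, i1) in enumerate(runs):
        t0 = t[0] if r == 0 else 0.5 * (t[i0 - 1] + t[i0])
        t1 = t[-1] if r == len(runs) - 1 else 0.5 * (t[i1] + t[i1 + 1])
        intervals.append(
            DwellInterval(state, t0, t1, censored_start=r == 0,
                          censored_end=r == len(runs) - 1)
        )

    if repair:
        dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
        repaired: list[DwellInterval] = []
        for iv in intervals:
            if repaired and {repaired[-1].state, iv.state} == {"F", "O"}:
                prev = repaired[-1]
                tb = prev.t_end
                half = min(dt / 2.0, prev.duration / 2.0, iv.duration / 2.0)
                repaired[-1] = DwellInterval(
                    prev.state, prev.t_start, tb - half,
                    prev.censored_start, False,
                )
                repaired.append(DwellInterval("B", tb - half, tb + half))
                iv = DwellInterval(iv.state, tb + half, iv.t_end,
                                   False, iv.censored_end)
            repaired.append(iv)
        intervals = repaired

    return StateSegmentation(intervals, np.array(seq), t)


# ---------------------------------------------------------------------------
# Estimation
# ---------------------------------------------------------------------------

def estimate_kinetics(seg: StateSegmentation) -> KineticEstimates:
    """State probabilities and rate constants from a segmentation.

    P_s = T_s / sum(T); k_XY = N_XY / T_X, reported per minute.  Censored
    edge intervals contribute occupancy time, but the truncated recording
    edge contributes no transition (standard censored-likelihood treatment;
    interior junctions each count one transition).  A rate whose origin
    state has zero occupancy is NaN, not zero.
    """
    occ = seg.occupancy()
    total = sum(occ.values())
    if total <= 0:
        raise ValueError("total observation time must be positive")
    counts = seg.transition_counts()

    def rate(x: str, y: str) -> float:
        if occ[x] == 0.0:
            return float("nan")
        return 60.0 * counts[(x, y)] / occ[x]

    return KineticEstimates(
        P_F=occ["F"] / total,
        P_B=occ["B"] / total,
        P_O=occ["O"] / total,
        k_FB=rate("F", "B"),
        k_BO=rate("B", "O"),
        k_OB=rate("O", "B"),
        k_BF=rate("B", "F"),
        N_FB=counts[("F", "B")],
        N_BO=counts[("B", "O")],
        N_OB=counts[("O", "B")],
        N_BF=counts[("B", "F")],
        T_F=occ["F"],
        T_B=occ["B"],
        T_O=occ["O"],
    )


def pooled_kinetics(estimates: list[KineticEstimates]) -> KineticEstimates:
    """Cohort-pooled estimates: sum of transition counts over sum of times."""
    if not estimates:
        raise ValueError("empty cohort")
    T = {s: sum(getattr(e, f"T_{s}") for e in estimates) for s in STATES}
    N = {
        tr: sum(getattr(e, f"N_{tr}") for e in estimates)
        for tr in ("FB", "BO", "OB", "BF")
    }
    total = sum(T.values())

    def rate(tr: str) -> float:
        t_origin = T[tr[0]]
        return 60.0 * N[tr] / t_origin if t_origin > 0 else float("nan")

    return KineticEstimates(
        P_F=T["F"] / total, P_B=T["B"] / total, P_O=T["O"] / total,
        k_FB=rate("FB"), k_BO=rate("BO"), k_OB=rate("OB"), k_BF=rate("BF"),
        N_FB=N["FB"], N_BO=N["BO"], N_OB=N["OB"], N_BF=N["BF"],
        T_F=T["F"], T_B=T["B"], T_O=T["O"],
    )


def compute_speeds(track: TrackRecording, labels) -> SpeedSummary:
    """Mean centroid speed on food (F frames) and off food (O frames), mm/s.

    Frame-to-frame centroid displacement over the frame interval; a step is
    assigned to a state only when both flanking frames carry that label, so
    that state-change frames do not contaminate either mean.  B frames are
    excluded: "on or off food" is binary and the border is neither.
    """
    labels = np.asarray(labels)
    if len(track) < 2:
        raise ValueError("need at least two frames to compute speed")
    xy = track.centroid
    dt = np.diff(track.times)
    speed = np.linalg.norm(np.diff(xy, axis=0), axis=1) / dt
    same = labels[:-1] == labels[1:]
    on = same & (labels[:-1] == "F")
    off = same & (labels[:-1] == "O")
    return SpeedSummary(
        speed_on=float(speed[on].mean()) if on.any() else float("nan"),
        speed_off=float(speed[off].mean()) if off.any() else float("nan"),
        n_on=int(on.sum()),
        n_off=int(off.sum()),
    )


def interpolate_gaps(frames: pd.DataFrame, max_gap_s: float = 2.0) -> list[pd.DataFrame]:
    """Fill tracking dropouts by linear interpolation; split at long gaps.

    Rows whose coordinates are NaN are interpolated linearly in time when the
    surrounding gap does not exceed ``max_gap_s``; longer gaps split the
    recording into independent segments (returned as separate tables).
    """
    coord_cols = [c for c in frames.columns if c.endswith("_mm")]
    df = frames.sort_values("time_s").reset_index(drop=True).copy()
    missing = df[coord_cols].isna().any(axis=1).to_numpy()
    if not missing.any():
        return [df]
    runs = _run_lengths(missing.astype(int).astype(str))
    t = df["time_s"].to_numpy(float)
    segments, split_points = [], []
    for state, i0, i1 in runs:
        if state == "1":
            t_before = t[i0 - 1] if i0 > 0 else None
            t_after = t[i1 + 1] if i1 + 1 < len(t) else None
            gap = (t_after - t_before) if (t_before is not None and t_after is not None) else np.inf
            if gap > max_gap_s:
                split_points.append((i0, i1))
    keep = np.ones(len(df), bool)
    boundaries = [0]
    for i0, i1 in split_points:
        keep[i0 : i1 + 1] = False
        boundaries.append(i1 + 1)
    boundaries.append(len(df))
    for b0, b1 in zip(boundaries[:-1], boundaries[1:]):
        part = df.iloc[b0:b1][keep[b0:b1]].copy()
        if len(part) == 0:
            continue
        part[coord_cols] = (
            part.set_index("time_s")[coord_cols]
            .interpolate(method="index", limit_area="inside")
            .to_numpy()
        )
        part = part.dropna(subset=coord_cols).reset_index(drop=True)
        if len(part):
            segments.append(part)
    return segments


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

PER_WORM_COLUMNS = [
    "worm_id", "P_F", "P_B", "P_O",
    "k_FB", "k_BO", "k_OB", "k_BF",
    "speed_on", "speed_off", "n_frames", "total_time_s",
]


class PatchKineticsModel:
    """Three-state kinetic model of patch leaving, fitted to worm tracks.

    Parameters
    ----------
    tracks : list of TrackRecording
        One recording per worm, each carrying its arena geometry.
    delta : float, optional
        Contact tolerance in mm; overrides each track's arena value.
    debounce : int
        Minimum run length (frames) for a dwell to survive smoothing;
        1 disables smoothing.
    repair : bool
        Bridge physically impossible F<->O adjacencies with a one-frame
        B interval.
    max_gap_s : float
        Tracking dropouts up to this length are interpolated; longer gaps
        split a recording.

    Examples
    --------
    >>> from patchforage import simulate_tracks, PatchKineticsModel
    >>> tracks = simulate_tracks(5, seed=1)
    >>> res = PatchKineticsModel(tracks).fit()
    >>> res.per_worm.shape[0]
    5
    """

    def __init__(
        self,
        tracks: list[TrackRecording],
        *,
        delta: float | None = None,
        debounce: int = 1,
        repair: bool = True,
        max_gap_s: float = 2.0,
    ) -> None:
        if not tracks:
            raise ValueError("need at least one track")
        self.tracks = list(tracks)
        self.delta = delta
        self.debounce = debounce
        self.repair = repair
        self.max_gap_s = max_gap_s

    def fit(self) -> "PatchKineticsResults":
        rows = []
        estimates = []
        segmentations = []
        for track in self.tracks:
            parts = interpolate_gaps(track.frames, self.max_gap_s)
            for p, part in enumerate(parts):
                sub = (
                    track
                    if len(parts) == 1
                    else TrackRecording(part, track.arena, f"{track.worm_id}.{p}")
                )
                labels = classify_frames(sub, delta=self.delta)
                seg = segment_states(labels, sub.times, self.debounce, self.repair)
                est = estimate_kinetics(seg)
                speeds = compute_speeds(sub, labels)
                estimates.append(est)
                segmentations.append((sub.worm_id, seg))
                rows.append(
                    dict(
                        worm_id=sub.worm_id,
                        P_F=est.P_F, P_B=est.P_B, P_O=est.P_O,
                        k_FB=est.k_FB, k_BO=est.k_BO,
                        k_OB=est.k_OB, k_BF=est.k_BF,
                        speed_on=speeds.speed_on, speed_off=speeds.speed_off,
                        n_frames=len(sub), total_time_s=seg.total_time,
                    )
                )
        per_worm = pd.DataFrame(rows, columns=PER_WORM_COLUMNS)
        return PatchKineticsResults(self, per_worm, pooled_kinetics(estimates),
                                    segmentations)


class PatchKineticsResults:
    """Fitted per-worm and cohort-pooled kinetic estimates.

    ``per_worm`` holds one row per worm (state probabilities, rate constants
    per minute, speeds in mm/s) for worm-level statistics; ``pooled`` uses
    cohort sums (sum N / sum T), the maximum-likelihood estimator under
    exponential dwell times.
    """

    def __init__(self, model, per_worm: pd.DataFrame, pooled: KineticEstimates,
                 segmentations=None):
        self.model = model
        self.per_worm = per_worm
        self.pooled = pooled
        self.segmentations = segmentations or []

    @property
    def state_probabilities(self) -> pd.DataFrame:
        return self.per_worm[["worm_id", "P_F", "P_B", "P_O"]]

    def ilr(self) -> pd.DataFrame:
        """Per-worm ILR coordinates of (P_F, P_B, P_O), zeros replaced first.

        The replacement epsilon is half the smallest observable nonzero
        fraction, i.e. half of one frame over the worm's frame count.
        """
        from .stats import ilr_transform, multiplicative_replacement

        rows = []
        for _, row in self.per_worm.iterrows():
            comp = np.array([row.P_F, row.P_B, row.P_O])
            eps = 0.5 / max(row.n_frames, 2)
            comp = multiplicative_replacement(comp, eps)
            z1, z2 = ilr_transform(*comp)
            rows.append({"worm_id": row.worm_id, "z1": z1, "z2": z2})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text report of cohort means and pooled estimates."""
        p = self.pooled
        lines = [
            "Three-state patch-leaving kinetics",
            "==================================",
            f"worms: {len(self.per_worm)}    "
            f"total observation: {self.per_worm.total_time_s.sum():.0f} s",
            "",
            "Pooled (sum N / sum T):",
            f"  P_F={p.P_F:.4f}  P_B={p.P_B:.4f}  P_O={p.P_O:.4f}",
            f"  k_FB={p.k_FB:.4f}  k_BO={p.k_BO:.4f}  "
            f"k_OB={p.k_OB:.4f}  k_BF={p.k_BF:.4f}  (per min)",
            "",
            "Per-worm means (SD):",
        ]
        for col in ["P_F", "P_B", "P_O", "k_FB", "k_BO", "k_OB", "k_BF",
                    "speed_on", "speed_off"]:
            v = self.per_worm[col]
            lines.append(f"  {col:<9} {v.mean():8.4f} ({v.std(ddof=1):.4f})")
        return "\n".join(lines)

    def plot_track(self, index: int = 0, ax=None):
        """Plot one track coloured by state over the arena geometry."""
        from .plotting import plot_track

        track = self.model.tracks[index]
        labels = classify_frames(track, delta=self.model.delta)
        return plot_track(track, labels, ax=ax)
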