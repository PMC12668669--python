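"""Generative twins of the three assay data types.

* Patch-leaving tracks: a continuous-time Markov chain over the states
  F (On Food), B (At Border), O (Off Food) rendered into head/tail/centroid
  coordinates inside a circular well with a central food patch.
* T-maze plate counts: binomial worm counts at a specified true probability
  of choosing the normal-bacteria arm.
* Electropharyngeograms: rhythmic (jittered-regular) biphasic pump
  transients embedded in Gaussian noise, with ground-truth event times.

All generators take an explicit seed (default 0) and are bit-reproducible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .core import ArenaGeometry, DwellInterval, TrackRecording, states_at
from .epg import EPGTrace


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateSet:
    """Rate constants of the linear F-B-O chain, per minute.

    The four admissible transitions are F->B, B->O, O->B and B->F.  Defaults
    respect the qualitative ordering seen in patch-leaving assays on normal
    food: entry rates exceed the matching exit rates (k_BF > k_FB,
    k_OB > k_BO), i.e. worms are far more inclined to enter a patch than to
    leave it.
    """

    k_FB: float = 0.2
    k_BO: float = 0.5
    k_OB: float = 1.5
    k_BF: float = 2.0

    def __post_init__(self) -> None:
        for name in ("k_FB", "k_BO", "k_OB", "k_BF"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def exit_rate(self, state: str) -> float:
        """Total exit rate from a state, per minute."""
        return {"F": self.k_FB, "B": self.k_BF + self.k_BO, "O": self.k_OB}[state]

    def stationary(self) -> np.ndarray:
        """Stationary occupancy (pi_F, pi_B, pi_O) by detailed balance.

        For the linear chain, pi_F k_FB = pi_B k_BF and pi_B k_BO = pi_O k_OB,
        which determines the distribution up to normalisation.  Requires both
        entry rates to be strictly positive.
        """
        if self.k_BF <= 0 or self.k_OB <= 0:
            raise ValueError("stationary distribution needs k_BF > 0 and k_OB > 0")
        pi_F = 1.0
        pi_B = pi_F * self.k_FB / self.k_BF
        pi_O = pi_B * self.k_BO / self.k_OB
        pi = np.array([pi_F, pi_B, pi_O])
        return pi / pi.sum()


@dataclass(frozen=True)
class SimWormParams:
    """Locomotion and recording parameters for one simulated worm.

    Speeds are state-conditioned mean centroid speeds (mm/s); ``body_length``
    is the head-tail separation.  15-min recordings at 2 frames/s mirror the
    patch-leaving assay.
    """

    rates: RateSet = field(default_factory=RateSet)
    speed_on: float = 0.05
    speed_off: float = 0.15
    body_length: float = 1.0
    fps: float = 2.0
    duration: float = 900.0

    def __post_init__(self) -> None:
        if self.speed_on < 0 or self.speed_off < 0:
            raise ValueError("speeds must be non-negative")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")


@dataclass(frozen=True)
class TmazeSimSpec:
    """Binomial generative model of a T-maze choice assay."""

    p_normal: float = 0.55
    n_worms: int = 30
    n_plates: int = 100
    od_normal: float = 1.0
    od_elongated: float = 1.0
    condition: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_normal <= 1.0:
            raise ValueError("p_normal must be in [0, 1]")
        if self.n_worms < 1 or self.n_plates < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class EPGSimSpec:
    """Jittered-regular pump train embedded in Gaussian noise.

    ``jitter`` is the fraction of the mean inter-pump interval by which each
    event time is uniformly perturbed; 0 gives a strictly rhythmic train.
    """

    rate_hz: float = 4.0
    duration: float = 300.0
    fs: float = 1000.0
    amplitude: float = 1.0
    width_ms: float = 20.0
    biphasic: bool = True
    noise_sd: float = 0.2
    jitter: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz < 0:
            raise ValueError("rate must be non-negative")
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and sampling rate must be positive")
        if not 0.0 <= self.jitter < 1.0:
            raise ValueError("jitter fraction must be in [0, 1)")
        # spike bandwidth ~ 1/width; require comfortable oversampling
        if self.fs <= 2.0 * (2000.0 / self.width_ms):
            raise ValueError("sampling rate below twice the spike bandwidth")
        if self.rate_hz > 0 and self.width_ms / 1000.0 >= 1.0 / self.rate_hz:
            raise ValueError("spike width exceeds the mean inter-pump interval")


# ---------------------------------------------------------------------------
# CTMC state sequences
# ---------------------------------------------------------------------------

def simulate_state_sequence(
    rates: RateSet,
    duration: float,
    initial: str = "F",
    seed: int | np.random.Generator = 0,
) -> list[DwellInterval]:
    """Gillespie simulation of the F-B-O chain over ``[0, duration]`` seconds.

    Dwell times are exponential with the state's total exit rate; from B the
    chain exits to F with probability k_BF / (k_BF + k_BO).  Intervals tile
    the duration exactly; the final interval is right-censored.  A reachable
    state with zero exit rate simply yields one censored interval.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if initial not in ("F", "B", "O"):
        raise ValueError(f"unknown initial state {initial!r}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    intervals: list[DwellInterval] = []
    t, state = 0.0, initial
    while t < duration:
        exit_per_s = rates.exit_rate(state) / 60.0
        if exit_per_s == 0.0:
            intervals.append(DwellInterval(state, t, duration, t == 0.0, True))
            return intervals
        dwell = rng.exponential(1.0 / exit_per_s)
        t_end = min(t + dwell, duration)
        censored_end = t_end == duration
        intervals.append(DwellInterval(state, t, t_end, t == 0.0, censored_end))
        if censored_end:
            break
        if state == "F":
            state = "B"
        elif state == "O":
            state = "B"
        else:
            p_to_F = rates.k_BF / (rates.k_BF + rates.k_BO)
            state = "F" if rng.random() < p_to_F else "O"
        t = t_end
    return intervals


# ---------------------------------------------------------------------------
# Track rendering
# ---------------------------------------------------------------------------

def _random_point_in(region, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample a point uniformly from a shapely region."""
    minx, miny, maxx, maxy = region.bounds
    for _ in range(10_000):
        p = np.array([rng.uniform(minx, maxx), rng.uniform(miny, maxy)])
        if region.contains(Point(p)):
            return p
    raise RuntimeError("could not sample a point in region")


def _step_in_region(pos, heading, step, region, rng):
    """Advance ``pos`` by ``step`` along a persistent heading, staying inside."""
    heading = heading + rng.normal(0.0, 0.6)
    for _ in range(25):
        cand = pos + step * np.array([math.cos(heading), math.sin(heading)])
        if region.contains(Point(cand)):
            return cand, heading
        heading = rng.uniform(-math.pi, math.pi)
    return pos, heading  # cornered: stall this frame


def render_track(
    state_sequence: list[DwellInterval],
    arena: ArenaGeometry,
    params: SimWormParams,
    seed: int | np.random.Generator = 0,
    worm_id: str = "sim",
) -> TrackRecording:
    """Render a state sequence into frame-by-frame head/tail coordinates.

    The rendering inverts the zone-classification rule: in F both body points
    lie inside the patch, in B exactly one does (which one alternates between
    visits), and in O neither does.  Within F and O the body midpoint performs
    a persistent random walk at the state's mean speed inside the admissible
    region; in B the contact point slides along the patch boundary.  Worms may
    reposition discontinuously at state changes; realistic body kinematics are
    out of scope.
    """
    if not state_sequence:
        raise ValueError("empty state sequence")
    if params.body_length >= 2 * arena.well_radius:
        raise ValueError("body length must be smaller than the well diameter")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    duration = state_sequence[-1].t_end
    n_frames = int(round(duration * params.fps)) + 1
    times = np.arange(n_frames) / params.fps
    frame_states = states_at(state_sequence, times)

    L = params.body_length
    half = L / 2.0
    margin = 0.05
    well_inner = arena.well.buffer(-(half + margin))
    f_region = arena.patch.buffer(-(half + margin))
    if f_region.is_empty:
        raise ValueError("patch too small to hold the worm body; shorten body_length")
    o_region = well_inner.difference(arena.patch.buffer(half + arena.delta + margin))
    if o_region.is_empty:
        raise ValueError("well too small for an off-food zone")
    boundary = arena.patch.exterior
    perim = boundary.length
    patch_anchor = np.array(arena.patch.representative_point().coords[0])
    speed_b = 0.5 * (params.speed_on + params.speed_off)
    dt = 1.0 / params.fps

    head = np.empty((n_frames, 2))
    tail = np.empty((n_frames, 2))

    pos = heading = None
    s_along = 0.0
    orient = rng.uniform(-math.pi, math.pi)
    head_inside = True  # which end straddles into the patch during B; flips per visit
    prev_state = None

    def _border_points(s: float) -> tuple[np.ndarray, np.ndarray]:
        """(inside, outside) body points straddling the boundary at arclength s."""
        p = np.array(boundary.interpolate(s % perim).coords[0])
        n_hat = patch_anchor - p
        n_hat = n_hat / np.linalg.norm(n_hat)
        inside = None
        for g in (0.15, 0.08, 0.3, 0.04, 0.5):
            cand = p + g * n_hat
            if arena.patch.contains(Point(cand)):
                inside = cand
                break
        if inside is None:
            inside = patch_anchor
        g_out = arena.delta + 0.15
        outside = p - g_out * n_hat
        # keep the outside point clear of the patch and inside the well
        for _ in range(10):
            ok = (arena.patch.distance(Point(outside)) > arena.delta
                  and arena.well.contains(Point(outside)))
            if ok:
                break
            g_out *= 0.5 if not arena.well.contains(Point(outside)) else 2.0
            outside = p - g_out * n_hat
        return inside, outside

    for i, st in enumerate(frame_states):
        entering = st != prev_state
        if st in ("F", "O"):
            region = f_region if st == "F" else o_region
            speed = params.speed_on if st == "F" else params.speed_off
            if entering or pos is None or not region.contains(Point(pos)):
                pos = _random_point_in(region, rng)
                heading = rng.uniform(-math.pi, math.pi)
            else:
                pos, heading = _step_in_region(pos, heading, speed * dt, region, rng)
            orient += rng.normal(0.0, 0.3)
            u = np.array([math.cos(orient), math.sin(orient)])
            head[i] = pos + half * u
            tail[i] = pos - half * u
        else:  # B: straddle the boundary
            if entering:
                s_along = rng.uniform(0.0, perim)
                head_inside = not head_inside
            else:
                s_along += speed_b * dt
            inside, outside = _border_points(s_along)
            if head_inside:
                head[i], tail[i] = inside, outside
            else:
                head[i], tail[i] = outside, inside
            pos = None  # force re-placement on next F/O visit
        prev_state = st

    centroid = 0.5 * (head + tail)
    frames = pd.DataFrame(
        {
            "frame": np.arange(n_frames),
            "time_s": times,
            "head_x_mm": head[:, 0],
            "head_y_mm": head[:, 1],
            "tail_x_mm": tail[:, 0],
            "tail_y_mm": tail[:, 1],
            "centroid_x_mm": centroid[:, 0],
            "centroid_y_mm": centroid[:, 1],
        }
    )
    return TrackRecording(frames, arena, worm_id)


def simulate_tracks(
    n_worms: int,
    arena: ArenaGeometry | None = None,
    params: SimWormParams | None = None,
    seed: int = 0,
) -> list[TrackRecording]:
    """Simulate a cohort of patch-leaving recordings (one worm per well)."""
    arena = arena or ArenaGeometry()
    params = params or SimWormParams()
    rng = np.random.default_rng(seed)
    tracks = []
    for w in range(n_worms):
        seq = simulate_state_sequence(params.rates, params.duration, "F", rng)
        tracks.append(render_track(seq, arena, params, rng, worm_id=f"worm{w:03d}"))
    return tracks


# ---------------------------------------------------------------------------
# T-maze plate counts
# ---------------------------------------------------------------------------

def simulate_tmaze_counts(spec: TmazeSimSpec) -> pd.DataFrame:
    """Binomial plate counts: n_normal ~ Binom(n_worms, p_normal) per plate.

    Returns the plate-count table with columns plate_id, condition,
    od_normal, od_elongated, n_normal, n_elongated.
    """
    rng = np.random.default_rng(spec.seed)
    n_normal = rng.binomial(spec.n_worms, spec.p_normal, size=spec.n_plates)
    return pd.DataFrame(
        {
            "plate_id": [f"plate{i:04d}" for i in range(spec.n_plates)],
            "condition": spec.condition,
            "od_normal": spec.od_normal,
            "od_elongated": spec.od_elongated,
            "n_normal": n_normal,
            "n_elongated": spec.n_worms - n_normal,
        }
    )


# ---------------------------------------------------------------------------
# EPG traces
# ---------------------------------------------------------------------------

def _spike_template(spec: EPGSimSpec) -> np.ndarray:
    """Stereotyped pump transient: biphasic (Gaussian derivative) or monophasic."""
    tau = spec.width_ms / 1000.0 / 6.0
    t = np.arange(-3 * tau, 3 * tau + 1.0 / spec.fs, 1.0 / spec.fs)
    if spec.biphasic:
        shape = -t * np.exp(-(t ** 2) / (2 * tau ** 2))
    else:
        shape = np.exp(-(t ** 2) / (2 * tau ** 2))
    return spec.amplitude * shape / np.abs(shape).max()


def simulate_epg_trace(spec: EPGSimSpec) -> tuple[EPGTrace, np.ndarray]:
    """Simulate an EPG trace; returns (trace, ground-truth event times).

    Event times are quasi-periodic: the k-th pump sits at ``(k + 1/2) / rate``
    plus a uniform perturbation of ±``jitter``/2 of the inter-pump interval.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    trace = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else np.zeros(n)
    if spec.rate_hz > 0:
        ipi = 1.0 / spec.rate_hz
        k = np.arange(int(math.floor(spec.duration * spec.rate_hz)))
        events = (k + 0.5) * ipi
        if spec.jitter > 0:
            events = events + rng.uniform(-0.5, 0.5, len(events)) * spec.jitter * ipi
            events = np.sort(events)
        events = events[(events > 0) & (events < spec.duration)]
        template = _spike_template(spec)
        half_len = len(template) // 2
        for t_ev in events:
            c = int(round(t_ev * spec.fs))
            lo, hi = c - half_len, c - half_len + len(template)
            t_lo, t_hi = max(lo, 0), min(hi, n)
            trace[t_lo:t_hi] += template[t_lo - lo : t_hi - lo]
    else:
        events = np.array([])
    return EPGTrace(trace, spec.fs, "sim"), events
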