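"""Electropharyngeogram (EPG) pump detection and pumping-frequency summaries.

An EPG is an extracellular voltage recording of the pharynx; each pharyngeal
pump appears as a stereotyped biphasic transient.  Detection is amplitude
threshold-based: band-pass filter, rectify, threshold at a multiple of the
robust noise level, then pick local maxima separated by a refractory period.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal


@dataclass
class EPGTrace:
    """Uniformly sampled voltage trace from one worm.

    Parameters
    ----------
    voltage : array
        Voltage samples, arbitrary units.
    fs : float
        Sampling rate, Hz.
    worm_id : str
        Identifier of the recorded worm.
    """

    voltage: np.ndarray
    fs: float
    worm_id: str = "worm"

    def __post_init__(self) -> None:
        self.voltage = np.asarray(self.voltage, float)
        if self.voltage.ndim != 1 or len(self.voltage) == 0:
            raise ValueError("voltage must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return len(self.voltage) / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.voltage)) / self.fs


@dataclass(frozen=True)
class PumpEvents:
    """Detected (or ground-truth) pump event times for one worm."""

    times: np.ndarray
    duration: float
    worm_id: str = "worm"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        object.__setattr__(self, "times", t)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.times)

    @property
    def frequency(self) -> float:
        """Mean pump frequency, Hz (event count over recording duration)."""
        return self.n_events / self.duration


def detect_pumps(
    trace: EPGTrace,
    *,
    band: tuple[float, float] = (1.0, 100.0),
    threshold_mult: float = 5.0,
    refractory_s: float = 0.1,
    peak_floor_frac: float = 0.3,
) -> PumpEvents:
    """Detect pharyngeal pump events in an EPG trace.

    Pipeline: zero-phase Butterworth band-pass over ``band``; rectify;
    threshold at ``threshold_mult`` times the robust (MAD-based) noise sigma
    of the filtered trace; local maxima closer than ``refractory_s`` are
    merged, keeping the largest.  The threshold also never drops below
    ``peak_floor_frac`` of the largest rectified excursion, so that a
    noise-free trace (robust sigma ~ 0) does not trigger on filter ripple.
    Both threshold terms scale linearly with the trace, making the detected
    count invariant to amplitude scaling.

    Parameters
    ----------
    trace : EPGTrace
        At least one second of signal.
    band : (low, high)
        Pass band in Hz; the sampling rate must exceed twice the upper edge.
    threshold_mult : float
        Multiplier on the MAD-derived noise sigma (default 5).
    refractory_s : float
        Minimum inter-event interval, s; a physiological bound on the pump
        rhythm (maximum plausible rate ~ 5-6 Hz).

    Returns
    -------
    PumpEvents
        Event times in seconds, strictly increasing.
    """
    if trace.duration < 1.0:
        raise ValueError("need at least 1 s of signal")
    low, high = band
    if not 0 < low < high:
        raise ValueError("band edges must satisfy 0 < low < high")
    if trace.fs <= 2.0 * high:
        raise ValueError(
            f"sampling rate {trace.fs} Hz too low for band upper edge {high} Hz"
        )
    sos = signal.butter(2, [low, high], btype="bandpass", fs=trace.fs, output="sos")
    # even padding avoids the high-pass edge transients of the default
    # odd-reflection padding, which otherwise masquerade as events
    filtered = signal.sosfiltfilt(sos, trace.voltage, padtype="even")
    envelope = np.abs(filtered)
    # 1.4826 * MAD estimates sigma for Gaussian noise, insensitive to sparse spikes
    sigma = 1.4826 * np.median(np.abs(filtered - np.median(filtered)))
    threshold = max(threshold_mult * sigma, peak_floor_frac * envelope.max())
    if threshold <= 0:  # identically zero trace
        return PumpEvents(np.array([]), trace.duration, trace.worm_id)
    distance = max(1, int(round(refractory_s * trace.fs)))
    peaks, _ = signal.find_peaks(envelope, height=threshold, distance=distance)
    return PumpEvents(peaks / trace.fs, trace.duration, trace.worm_id)


def mean_pump_frequency(events: Sequence[PumpEvents]) -> tuple[np.ndarray, float]:
    """Per-worm pump frequencies and their unweighted cohort mean.

    Each worm's frequency is its event count divided by its recording
    duration; worms with zero events contribute 0 Hz and remain in the mean.
    """
    if len(events) == 0:
        raise ValueError("empty cohort")
    per_worm = np.array([ev.frequency for ev in events])
    return per_worm, float(per_worm.mean())


def match_events(
    detected: np.ndarray, truth: np.ndarray, tolerance: float
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected to ground-truth event times.

    Returns (true positives, false positives, false negatives); a detection
    matches at most one truth event within ``tolerance`` seconds.
    """
    detected = np.asarray(detected, float)
    truth = np.asarray(truth, float)
    used = np.zeros(len(truth), bool)
    tp = 0
    for t in detected:
        if len(truth) == 0:
            continue
        j = int(np.argmin(np.where(used, np.inf, np.abs(truth - t))))
        if not used[j] and abs(truth[j] - t) <= tolerance:
            used[j] = True
            tp += 1
    return tp, len(detected) - tp, len(truth) - tp
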