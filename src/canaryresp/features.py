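"""Feature extraction for expiratory pressure-like traces.

The four canary pressure-pattern classes are defined by shape: P0 is a long
expiratory gesture with a brief leading peak, an interior minimum and a long
slowly-decaying lobe; P1 is a near-harmonic oscillation; P2 pulses are about
twice as long as P1 cycles with a relative minimum inside each pulse; the
pulsatile pattern is a small ripple riding on a sustained expiration.  The
operators here quantify those shapes for simulated (or recorded, normalised)
traces: prominence-filtered extrema, supra-threshold pulse segmentation,
dominant oscillation period, RA amplitude trend, and a rule-based classifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .simulate import Trajectory

__all__ = [
    "Extremum",
    "FeatureReport",
    "find_local_extrema",
    "segment_pulses",
    "dominant_period",
    "ra_amplitude_trend",
    "sustained_window",
    "classify_pattern",
    "extract_features",
    "DEFAULT_PROMINENCE",
    "DEFAULT_THRESHOLD_FRAC",
    "MIN_PULSE_MS",
]

#: default extremum prominence (activity units); suppresses grid-level ripple
DEFAULT_PROMINENCE = 0.02
#: phonation threshold as a fraction of the trace's global maximum
DEFAULT_THRESHOLD_FRAC = 0.10
#: supra-threshold runs shorter than this (ms) are discarded
MIN_PULSE_MS = 2.0


@dataclass(frozen=True)
class Extremum:
    time: float
    value: float
    kind: Literal["max", "min"]


@dataclass
class FeatureReport:
    """Summary of one trace: extrema, pulse count, period, trend, label."""

    extrema: list[Extremum]
    n_pulses: int
    pulses: list[tuple[float, float]]
    dominant_period: Optional[float]
    ra_amplitude_trend: Optional[str]
    label: str
    threshold: float

    def to_dict(self) -> dict:
        return {
            "n_extrema": len(self.extrema),
            "n_pulses": self.n_pulses,
            "dominant_period_ms": self.dominant_period,
            "ra_amplitude_trend": self.ra_amplitude_trend,
            "label": self.label,
            "threshold": self.threshold,
        }

    def to_text(self) -> str:
        lines = [f"{k}\t{v}" for k, v in self.to_dict().items()]
        lines += [
            f"extremum\t{e.kind}\t{e.time:.6g}\t{e.value:.6g}" for e in self.extrema
        ]
        lines += [f"pulse\t{a:.6g}\t{b:.6g}" for a, b in self.pulses]
        return "\n".join(lines) + "\n"


def _as_series(series: Sequence[float]) -> np.ndarray:
    y = np.asarray(series, dtype=float)
    if y.ndim != 1 or y.size < 3:
        raise ValueError("series must be 1-D with at least 3 samples")
    if not np.all(np.isfinite(y)):
        raise ValueError("series must be finite")
    return y


def find_local_extrema(
    series: Sequence[float],
    prominence: float = DEFAULT_PROMINENCE,
    dt: float = 1.0,
    t0: float = 0.0,
) -> list[Extremum]:
    """Prominence-filtered interior extrema of a uniformly sampled trace.

    Maxima and minima are detected independently (prominence measured on the
    trace and its negation) and merged in time order; where two extrema of
    the same kind end up adjacent, only the more extreme one is kept, so the
    returned list alternates max/min.  Endpoints are never reported.
    """
    y = _as_series(series)
    if prominence <= 0:
        raise ValueError("prominence must be > 0")
    imax, _ = find_peaks(y, prominence=prominence)
    imin, _ = find_peaks(-y, prominence=prominence)
    merged = sorted(
        [(i, "max") for i in imax] + [(i, "min") for i in imin], key=lambda p: p[0]
    )
    # enforce alternation: among consecutive same-kind extrema keep the extreme one
    cleaned: list[tuple[int, str]] = []
    for i, kind in merged:
        if cleaned and cleaned[-1][1] == kind:
            j, _ = cleaned[-1]
            better = (y[i] > y[j]) if kind == "max" else (y[i] < y[j])
            if better:
                cleaned[-1] = (i, kind)
        else:
            cleaned.append((i, kind))
    return [Extremum(t0 + dt * i, float(y[i]), kind) for i, kind in cleaned]


def segment_pulses(
    series: Sequence[float],
    threshold: float,
    dt: float = 1.0,
    t0: float = 0.0,
    min_duration: float = MIN_PULSE_MS,
) -> list[tuple[float, float]]:
    """Half-open time intervals where the trace stays at or above threshold.

    Maximal contiguous supra-threshold runs are reported as
    ``(start_ms, end_ms)``; runs shorter than ``min_duration`` are dropped
    (they are integration-grid ripple, not pressure pulses).
    """
    y = _as_series(series)
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    above = y >= threshold
    step = np.diff(above.astype(np.int8))
    starts = list(np.flatnonzero(step == 1) + 1)
    ends = list(np.flatnonzero(step == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(y))
    out = []
    for a, b in zip(starts, ends):
        t_start, t_end = t0 + dt * a, t0 + dt * b
        if t_end - t_start >= min_duration:
            out.append((t_start, t_end))
    return out


def dominant_period(
    series: Sequence[float],
    dt: float = 1.0,
    t0: float = 0.0,
    window: Optional[tuple[float, float]] = None,
    prominence: float = DEFAULT_PROMINENCE,
) -> Optional[float]:
    """Median interval between successive maxima inside ``window`` (ms).

    Returns ``None`` when fewer than two maxima are found (no oscillation).
    """
    y = _as_series(series)
    t = t0 + dt * np.arange(len(y))
    if window is not None:
        a, b = window
        if not (a < b) or a < t[0] - dt / 2 or b > t[-1] + dt / 2:
            raise ValueError(f"window ({a}, {b}) not within the trace")
        sel = (t >= a) & (t <= b)
        y, t = y[sel], t[sel]
        if y.size < 3:
            raise ValueError("window contains fewer than 3 samples")
    maxima = [e for e in find_local_extrema(y, prominence, dt, t[0]) if e.kind == "max"]
    if len(maxima) < 2:
        return None
    return float(np.median(np.diff([e.time for e in maxima])))


#: |slope| (activity units per ms) below which the RA amplitude counts as
#: constant, for both peak-height fits and level fits
TREND_SLOPE_TOL = 2e-4


def sustained_window(trajectory: Trajectory) -> Optional[tuple[float, float]]:
    """Self-sustained segment of a simulated run: after the HVC burst (last
    ``Fd`` pulse) ends, until the terminating ``Fd2`` burst (or trace end).

    Returns ``None`` when the trajectory carries no drive metadata or the
    window would be degenerate.
    """
    drives = trajectory.meta.get("drives")
    if not drives or not drives.get("Fd"):
        return None
    fd_end = max(onset + width for onset, width, _ in drives["Fd"])
    if drives.get("Fd2"):
        stop = min(onset for onset, _, _ in drives["Fd2"])
    else:
        stop = float(trajectory.times[-1])
    if stop - fd_end < 3 * trajectory.dt:
        return None
    return (fd_end, stop)


def ra_amplitude_trend(
    trajectory: Trajectory,
    window: Optional[tuple[float, float]] = None,
    prominence: float = DEFAULT_PROMINENCE,
    slope_tol: float = TREND_SLOPE_TOL,
) -> str:
    """Trend of RA excitatory activity over the sustained segment.

    When the e_ra trace oscillates (>= 3 prominent peaks in the window), the
    trend is the sign of the least-squares slope of successive peak heights
    against peak time.  Otherwise — the RA subsystem of this circuit is
    bistable and typically climbs monotonically onto its "on" state rather
    than oscillating — the trend is the slope of the e_ra level itself,
    which captures the slow on-manifold ramp of the pulsatile pattern versus
    the saturated constant level of P1.  |slope| below ``slope_tol`` counts
    as ``constant``.

    ``window`` defaults to the drive-derived sustained segment (see
    :func:`sustained_window`), falling back to the whole trace.
    """
    y = trajectory.e_ra
    t = trajectory.times
    if window is None:
        window = sustained_window(trajectory)
    if window is not None:
        sel = (t >= window[0]) & (t <= window[1])
        y, t = y[sel], t[sel]
        if y.size < 3:
            raise ValueError("window contains fewer than 3 samples")
    maxima = [
        e
        for e in find_local_extrema(y, prominence, trajectory.dt, float(t[0]))
        if e.kind == "max"
    ]
    if len(maxima) >= 3:
        times = np.array([e.time for e in maxima])
        heights = np.array([e.value for e in maxima])
        slope = np.polyfit(times, heights, 1)[0]
    else:
        slope = np.polyfit(t, y, 1)[0]
    if abs(slope) < slope_tol:
        return "constant"
    return "increasing" if slope > 0 else "decreasing"


# ---------------------------------------------------------------------------
# rule-based pattern classifier
#
# All thresholds are fixed constants, chosen from the pattern definitions
# (see docs/methods.md) and committed with the test suite, not fitted.

#: traces whose global maximum stays below this are background, not a gesture
_SILENCE_LEVEL = 0.05
#: maxima intervals with coefficient of variation below this count as periodic
_PERIOD_CV_TOL = 0.35
#: peak-to-trough ripple (relative to peak height) separating the pulsatile
#: ripple-on-plateau (measured ~0.65) from full-depth P1 cycles (~0.84)
_RIPPLE_SPLIT = 0.75
#: relative interior-minimum depth (min / smaller lobe max) separating the
#: deep P0 notch (~0.25) from P2's shallow modulation (~0.88)
_NOTCH_DEPTH_SPLIT = 0.5


def classify_pattern(
    trajectory: Trajectory,
    prominence: float = DEFAULT_PROMINENCE,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> str:
    """Heuristic pattern label for a simulated trace.

    Decision rules, applied to the e_er (pressure proxy) trace:

    * >= 3 maxima at near-constant period -> oscillatory; a moderate ripple
      riding on a sustained expiration is ``pulsatile``, near-full-depth
      cycles are ``P1``;
    * a single supra-threshold pulse with two lobe maxima and one interior
      minimum -> ``P0`` when the minimum cuts deep (below half the smaller
      lobe), ``P2`` when it is a shallow modulation;
    * anything else (including silent traces) -> ``unknown``.

    The split constants are fixed, documented values, not fitted.
    """
    y = trajectory.e_er
    dt, t0 = trajectory.dt, trajectory.t0
    peak = float(y.max())
    if peak < _SILENCE_LEVEL:
        return "unknown"
    extrema = find_local_extrema(y, prominence, dt, t0)
    maxima = [e for e in extrema if e.kind == "max"]
    minima = [e for e in extrema if e.kind == "min"]
    pulses = segment_pulses(y, threshold_frac * peak, dt, t0)

    if len(maxima) >= 3:
        tmax = np.array([e.time for e in maxima])
        intervals = np.diff(tmax)
        if intervals.size >= 2 and np.std(intervals) / np.mean(intervals) < _PERIOD_CV_TOL:
            heights = np.array([e.value for e in maxima])
            troughs = [e.value for e in minima if tmax[0] < e.time < tmax[-1]]
            if troughs:
                ripple = (np.mean(heights) - np.mean(troughs)) / np.mean(heights)
                return "pulsatile" if ripple < _RIPPLE_SPLIT else "P1"
            return "pulsatile"

    if len(pulses) == 1 and len(maxima) == 2 and len(minima) >= 1:
        interior = [e for e in minima if maxima[0].time < e.time < maxima[1].time]
        if len(interior) == 1:
            depth = interior[0].value / min(m.value for m in maxima)
            return "P0" if depth < _NOTCH_DEPTH_SPLIT else "P2"
    return "unknown"


def extract_features(
    trajectory: Trajectory,
    prominence: float = DEFAULT_PROMINENCE,
    threshold_frac: float = DEFAULT_THRESHOLD_FRAC,
) -> FeatureReport:
    """Full feature report for one simulated trajectory."""
    y = trajectory.e_er
    dt, t0 = trajectory.dt, trajectory.t0
    threshold = threshold_frac * float(y.max())
    extrema = find_local_extrema(y, prominence, dt, t0)
    pulses = segment_pulses(y, threshold, dt, t0)
    period = dominant_period(y, dt, t0, prominence=prominence)
    trend = ra_amplitude_trend(trajectory)
    label = classify_pattern(trajectory, prominence, threshold_frac)
    return FeatureReport(
        extrema=extrema,
        n_pulses=len(pulses),
        pulses=pulses,
        dominant_period=period,
        ra_amplitude_trend=trend,
        label=label,
        threshold=threshold,
    )
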