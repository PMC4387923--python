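"""Square-pulse drive signals for the respiratory circuit.

Three signals force the network: ``F``, the burst emitted by the brainstem
initiating area (input to the ER excitatory population), and ``Fd`` /
``Fd2`` (``F_delayed``, ``F_delayed2``), the copies of that burst that reach
RA after telencephalic processing — in the model, HVC bursts relayed with a
thalamic delay.  Bursts are idealised as square pulses; the pulse height is
10 (arb. units) for every simulated pattern.

Pulses use a half-open support [onset, onset + width): the value at the
rising edge belongs to the pulse, the value at the falling edge does not, so
abutting pulses never double count.  Edge comparisons carry a 1e-9 ms
tolerance to absorb floating-point jitter in integrator stage times.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import isfinite
from typing import Iterable, Sequence

__all__ = [
    "SquarePulse",
    "DriveSet",
    "evaluate_drive",
    "build_drives",
    "apply_cooling",
    "PATTERN_NAMES",
]

PATTERN_NAMES = ("P0", "pulsatile", "P2", "P1")

#: tolerance for deciding whether a time lies on a pulse edge (ms)
EDGE_TOL = 1e-9


@dataclass(frozen=True)
class SquarePulse:
    """One square pulse: ``amplitude`` on [onset, onset + width), else 0."""

    onset: float
    width: float
    amplitude: float = 10.0

    def __post_init__(self) -> None:
        if not all(isfinite(v) for v in (self.onset, self.width, self.amplitude)):
            raise ValueError("SquarePulse: onset, width, amplitude must be finite")
        if self.width <= 0:
            raise ValueError(f"SquarePulse: width must be > 0, got {self.width}")
        if self.amplitude < 0:
            raise ValueError(f"SquarePulse: amplitude must be >= 0, got {self.amplitude}")

    @property
    def end(self) -> float:
        return self.onset + self.width

    def value(self, t: float) -> float:
        """Right-continuous evaluation (the half-open convention)."""
        if t - self.onset >= -EDGE_TOL and t - self.end < -EDGE_TOL:
            return self.amplitude
        return 0.0

    def value_left(self, t: float) -> float:
        """Left-sided limit, used by the integrator at the end of a step."""
        if t - self.onset > EDGE_TOL and t - self.end <= EDGE_TOL:
            return self.amplitude
        return 0.0

    def shifted(self, delta: float) -> "SquarePulse":
        return replace(self, onset=self.onset + delta)


def _validated(pulses: Iterable[SquarePulse], name: str) -> tuple[SquarePulse, ...]:
    ordered = tuple(sorted(pulses, key=lambda p: p.onset))
    for a, b in zip(ordered, ordered[1:]):
        if a.end > b.onset + EDGE_TOL:
            raise ValueError(
                f"DriveSet.{name}: overlapping pulses "
                f"([{a.onset}, {a.end}) and [{b.onset}, {b.end}))"
            )
    return ordered


def evaluate_drive(signal: Sequence[SquarePulse], t: float) -> float:
    """Value of a pulse train at time ``t`` (sum of active pulses)."""
    if not isfinite(t):
        raise ValueError("evaluate_drive: time must be finite")
    return sum(p.value(t) for p in signal)


@dataclass(frozen=True)
class DriveSet:
    """The three drive signals, each a sorted, non-overlapping pulse train."""

    F: tuple[SquarePulse, ...] = ()
    Fd: tuple[SquarePulse, ...] = ()
    Fd2: tuple[SquarePulse, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "F", _validated(self.F, "F"))
        object.__setattr__(self, "Fd", _validated(self.Fd, "Fd"))
        object.__setattr__(self, "Fd2", _validated(self.Fd2, "Fd2"))

    def values_at(self, t: float) -> tuple[float, float, float]:
        return (
            sum(p.value(t) for p in self.F),
            sum(p.value(t) for p in self.Fd),
            sum(p.value(t) for p in self.Fd2),
        )

    def values_left(self, t: float) -> tuple[float, float, float]:
        return (
            sum(p.value_left(t) for p in self.F),
            sum(p.value_left(t) for p in self.Fd),
            sum(p.value_left(t) for p in self.Fd2),
        )

    def shifted(self, delta: float) -> "DriveSet":
        return DriveSet(
            F=tuple(p.shifted(delta) for p in self.F),
            Fd=tuple(p.shifted(delta) for p in self.Fd),
            Fd2=tuple(p.shifted(delta) for p in self.Fd2),
        )

    def to_meta(self) -> dict:
        """JSON-serialisable summary: {signal: [[onset, width, amplitude]]}."""
        return {
            name: [[p.onset, p.width, p.amplitude] for p in getattr(self, name)]
            for name in ("F", "Fd", "Fd2")
        }


# Published pulse widths (ms) per pattern: (F, Fd, Fd2); None = signal unused.
# The Fd width is only printed for P0 (the 10 ms HVC burst) and P1 (140 ms);
# for pulsatile and P2 it is a documented default (see docs/methods.md).
_WIDTHS = {
    "P0": (20.0, 10.0, None),
    "pulsatile": (50.0, 20.0, 20.0),
    "P2": (20.0, 10.0, None),
    "P1": (40.0, 140.0, 100.0),
}

#: default lumped IA -> RA-input delay (ms).  For P2 the printed interval is
#: 22 ms.  For P0 only the HVC->RA leg (10 ms) is published; the default
#: total of 35 ms places the interior minimum of the pattern just above the
#: phonation threshold, the regime the cooling experiment probes.
_DEFAULT_DELAY = {"P0": 35.0, "pulsatile": 10.0, "P2": 22.0, "P1": 10.0}

#: default interval (ms) between Fd and Fd2 onsets for the oscillating
#: patterns; long enough for several ER cycles (~37 ms period for the
#: pulsatile preset, ~75 ms for P1)
_DEFAULT_SEGMENT = {"pulsatile": 300.0, "P1": 450.0}


def build_drives(
    pattern: str,
    *,
    f_onset: float = 50.0,
    d_total: float | None = None,
    segment_duration: float | None = None,
    fd_width: float | None = None,
    fd2_width: float | None = None,
    amplitude: float = 10.0,
) -> DriveSet:
    """Build the drive schedule for one of the named pressure patterns.

    Parameters
    ----------
    pattern : {"P0", "pulsatile", "P2", "P1"}
    f_onset : float
        Onset of the initiating-area pulse F (ms); the default leaves a
        50 ms resting baseline before the gesture.
    d_total : float, optional
        Lumped delay from the IA burst to the RA input ``Fd`` (IA -> thalamus
        -> HVC -> RA).  Per-pattern defaults: 35 ms for P0, 22 ms for P2 (the
        published interval between the direct and telencephalic inputs),
        10 ms otherwise.
    segment_duration : float, optional
        Interval between the onsets of ``Fd`` and ``Fd2`` for the pulsatile
        and P1 patterns; sets the length of the oscillating segment
        (defaults 300 ms / 450 ms respectively).
    fd_width, fd2_width : float, optional
        Override the per-pattern pulse widths.
    amplitude : float
        Pulse height, identical for all signals (published value 10).
    """
    if pattern not in _WIDTHS:
        raise ValueError(f"unknown pattern {pattern!r}; expected one of {PATTERN_NAMES}")
    if d_total is None:
        d_total = _DEFAULT_DELAY[pattern]
    if segment_duration is None:
        segment_duration = _DEFAULT_SEGMENT.get(pattern, 300.0)
    if d_total < 0:
        raise ValueError("d_total must be >= 0")
    if segment_duration < 0:
        raise ValueError("segment_duration must be >= 0")

    w_f, w_fd, w_fd2 = _WIDTHS[pattern]
    w_fd = fd_width if fd_width is not None else w_fd
    w_fd2 = fd2_width if fd2_width is not None else w_fd2

    F = (SquarePulse(f_onset, w_f, amplitude),)
    fd_onset = f_onset + d_total
    Fd = (SquarePulse(fd_onset, w_fd, amplitude),)
    if pattern in ("pulsatile", "P1"):
        Fd2 = (SquarePulse(fd_onset + segment_duration, w_fd2, amplitude),)
    else:
        Fd2 = ()
    return DriveSet(F=F, Fd=Fd, Fd2=Fd2)


def apply_cooling(
    drives: DriveSet,
    stretch: float,
    extra_delay: float = 0.0,
    mode: str = "both",
) -> DriveSet:
    """Transform a drive schedule as mild HVC cooling would.

    Cooling slows HVC's internal dynamics (each HVC-derived burst becomes
    ``stretch`` ms longer) and slows the thalamic relay into HVC (each burst
    starts ``extra_delay`` ms later).  Only ``Fd`` and ``Fd2`` are affected;
    the brainstem pulse ``F`` is returned untouched.  ``mode="stretch_only"``
    applies the widening without the onset delay.
    """
    if mode not in ("both", "stretch_only"):
        raise ValueError(f"apply_cooling: unknown mode {mode!r}")
    if stretch < 0 or extra_delay < 0:
        raise ValueError("apply_cooling: stretch and extra_delay must be >= 0")
    delay = extra_delay if mode == "both" else 0.0

    def cooled(p: SquarePulse) -> SquarePulse:
        return replace(p, onset=p.onset + delay, width=p.width + stretch)

    return DriveSet(
        F=drives.F,
        Fd=tuple(cooled(p) for p in drives.Fd),
        Fd2=tuple(cooled(p) for p in drives.Fd2),
    )
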