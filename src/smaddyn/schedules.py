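"""Piecewise ligand presentation schedules.

A :class:`LigandSchedule` describes the extracellular ligand concentration a
culture sees over time as an ordered list of contiguous segments.  Steps,
staircase ramps (ligand raised in small equal increments by media changes) and
pulse trains are all expressed in this one representation, so every simulator
in :mod:`smaddyn.models` accepts any protocol.

Times are in hours, concentrations in ng/ml.  Evaluation is right-continuous
at discontinuities (the instant of a media change the cell already sees the
new concentration) and zero outside the covered span.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Segment",
    "LigandSchedule",
    "ScheduleError",
    "make_step",
    "make_ramp",
    "make_pulse_train",
]


class ScheduleError(ValueError):
    """Raised for ill-formed schedule definitions (overlap, gaps, bad doses)."""


@dataclass(frozen=True)
class Segment:
    """One homogeneous stretch of a ligand schedule."""

    t_start: float
    t_end: float
    c_start: float
    c_end: float
    interpolation: Literal["constant", "linear"] = "constant"

    def __post_init__(self) -> None:
        if not np.isfinite([self.t_start, self.t_end, self.c_start, self.c_end]).all():
            raise ScheduleError("segment bounds and doses must be finite")
        if self.t_end <= self.t_start:
            raise ScheduleError(
                f"segment must have t_end > t_start, got [{self.t_start}, {self.t_end}]"
            )
        if self.c_start < 0 or self.c_end < 0:
            raise ScheduleError("ligand concentrations must be non-negative")
        if self.interpolation not in ("constant", "linear"):
            raise ScheduleError(f"unknown interpolation {self.interpolation!r}")

    def value(self, t: np.ndarray) -> np.ndarray:
        if self.interpolation == "constant":
            return np.full_like(t, self.c_start, dtype=float)
        frac = (t - self.t_start) / (self.t_end - self.t_start)
        return self.c_start + frac * (self.c_end - self.c_start)


@dataclass(frozen=True)
class LigandSchedule:
    """Piecewise ligand concentration vs time.

    Segments must be contiguous and non-overlapping; construction fails
    otherwise, so evaluation never has to disambiguate.
    """

    segments: tuple[Segment, ...]
    name: str = "schedule"

    def __post_init__(self) -> None:
        segs = tuple(sorted(self.segments, key=lambda s: s.t_start))
        object.__setattr__(self, "segments", segs)
        if not segs:
            raise ScheduleError("schedule needs at least one segment")
        for a, b in zip(segs, segs[1:]):
            if b.t_start < a.t_end - 1e-12:
                raise ScheduleError(
                    f"overlapping segments: [{a.t_start},{a.t_end}] and [{b.t_start},{b.t_end}]"
                )
            if b.t_start > a.t_end + 1e-9:
                raise ScheduleError(
                    f"gap between segments at t={a.t_end} and t={b.t_start}; "
                    "insert an explicit zero-dose segment"
                )

    # -- evaluation ---------------------------------------------------------

    def __call__(self, t):
        """Concentration at time(s) ``t`` (ng/ml); 0 outside the covered span."""
        t_arr = np.asarray(t, dtype=float)
        if not np.isfinite(t_arr).all():
            raise ScheduleError("schedule evaluated at non-finite time")
        out = np.zeros_like(t_arr)
        for seg in self.segments:
            # right-continuous: a point on a boundary belongs to the later segment
            mask = (t_arr >= seg.t_start) & (t_arr < seg.t_end)
            if mask.any():
                out[mask] = seg.value(t_arr[mask])
        # close the very end of the span
        last = self.segments[-1]
        at_end = t_arr == last.t_end
        if at_end.any():
            out[at_end] = last.value(t_arr[at_end])
        return out if out.ndim else float(out)

    @property
    def t_start(self) -> float:
        return self.segments[0].t_start

    @property
    def t_end(self) -> float:
        return self.segments[-1].t_end

    def breakpoints(self) -> np.ndarray:
        """Sorted unique segment boundaries (integration restart points)."""
        pts = {s.t_start for s in self.segments} | {s.t_end for s in self.segments}
        return np.array(sorted(pts))

    def integral(self) -> float:
        """Integrated ligand exposure (ng/ml · hr) over the covered span."""
        total = 0.0
        for s in self.segments:
            total += 0.5 * (s.c_start + s.c_end) * (s.t_end - s.t_start)
        return total

    def with_breakpoints(self, times: Iterable[float]) -> "LigandSchedule":
        """Insert media-change breakpoints that do not alter the concentration.

        Used to model dummy media changes: the solver restarts there and, in
        ligand-depletion models, the ligand is replenished to nominal.
        """
        cut = sorted(set(float(t) for t in times))
        segs: list[Segment] = []
        for s in self.segments:
            inner = [t for t in cut if s.t_start < t < s.t_end]
            lo = s.t_start
            for t in [*inner, s.t_end]:
                c_lo = float(s.value(np.array(lo)))
                c_hi = float(s.value(np.array(t)))
                segs.append(Segment(lo, t, c_lo, c_hi, s.interpolation))
                lo = t
        return LigandSchedule(tuple(segs), name=self.name)


# -- constructors -----------------------------------------------------------


def make_step(
    dose: float, t_on: float = 0.0, t_off: float = 48.0, name: str | None = None
) -> LigandSchedule:
    """A sudden step to ``dose`` ng/ml held from ``t_on`` to ``t_off``."""
    if dose < 0:
        raise ScheduleError("dose must be non-negative")
    if name is None:
        name = f"step_{dose:g}"
    return LigandSchedule((Segment(t_on, t_off, dose, dose),), name=name)


def make_ramp(
    final_dose: float, duration: float, n_steps: int, t_on: float = 0.0,
    hold_until: float | None = None, name: str | None = None,
) -> LigandSchedule:
    """Staircase ramp: ``n_steps`` equal increments reaching ``final_dose``.

    Experimentally a slow ramp is realized by hourly media changes, so the
    concentration is a staircase, each stair ``duration / n_steps`` long.
    With ``n_steps == 1`` this degenerates to a delayed step at the full dose.
    """
    if final_dose <= 0 or duration <= 0:
        raise ScheduleError("final_dose and duration must be positive")
    if n_steps < 1:
        raise ScheduleError("n_steps must be >= 1")
    dt = duration / n_steps
    segs = []
    for i in range(n_steps):
        c = final_dose * (i + 1) / n_steps
        segs.append(Segment(t_on + i * dt, t_on + (i + 1) * dt, c, c))
    if hold_until is not None and hold_until > t_on + duration:
        segs.append(Segment(t_on + duration, hold_until, final_dose, final_dose))
    if name is None:
        name = f"ramp_{final_dose:g}_{n_steps}steps"
    return LigandSchedule(tuple(segs), name=name)


def make_pulse_train(
    high: float,
    pulse_lengths: Sequence[float] = (6.0, 10.0, 8.0),
    gap: float = 5.0,
    low: float = 0.0,
    t_on: float = 0.0,
    name: str = "pulse_train",
) -> LigandSchedule:
    """Pulses of ``high`` ng/ml separated by ``gap`` hours at ``low`` ng/ml.

    Defaults follow the experimental protocol: three pulses of 6, 10 and 8 hr
    with 5 hr between pulses to let the pathway relax.
    """
    if high < 0 or low < 0:
        raise ScheduleError("doses must be non-negative")
    if gap < 0:
        raise ScheduleError("gap must be non-negative")
    segs = []
    t = t_on
    for i, dur in enumerate(pulse_lengths):
        segs.append(Segment(t, t + dur, high, high))
        t += dur
        if i < len(pulse_lengths) - 1 and gap > 0:
            segs.append(Segment(t, t + gap, low, low))
            t += gap
    return LigandSchedule(tuple(segs), name=name)
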