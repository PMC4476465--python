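"""Light schedules and Zeitgeber-time bookkeeping.

Zeitgeber time (ZT) is measured in hours since lights-on: ZT0 = light onset,
ZT12 = dark onset in a 12:12 cycle. A :class:`LightSchedule` maps recording
time (hours since the recording started) to light state and to ZT via
``zt0_offset_h`` (the ZT of recording hour 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["LightSchedule", "ScheduleError"]

LIGHT = "light"
DARK = "dark"


class ScheduleError(ValueError):
    """Raised for malformed or gappy light schedules."""


@dataclass(frozen=True)
class LightSchedule:
    """An ordered, contiguous list of (start_h, end_h, state) intervals.

    Parameters
    ----------
    intervals
        Tuples ``(start_h, end_h, state)`` with ``state`` in ``{"light",
        "dark"}``. Must be contiguous, non-overlapping and start at 0.
    zt0_offset_h
        ZT of recording hour 0 (e.g. a recording that starts one hour after
        lights-on has offset 1).
    """

    intervals: tuple[tuple[float, float, str], ...]
    zt0_offset_h: float = 0.0

    def __post_init__(self) -> None:
        ivs = tuple((float(a), float(b), str(s)) for a, b, s in self.intervals)
        if not ivs:
            raise ScheduleError("schedule has no intervals")
        if ivs[0][0] != 0.0:
            raise ScheduleError("schedule must start at hour 0")
        prev_end = 0.0
        for a, b, s in ivs:
            if s not in (LIGHT, DARK):
                raise ScheduleError(f"unknown light state {s!r}")
            if a != prev_end:
                raise ScheduleError(f"gap or overlap at hour {a:g}")
            if b <= a:
                raise ScheduleError(f"empty interval at hour {a:g}")
            prev_end = b
        object.__setattr__(self, "intervals", ivs)

    # -- constructors -----------------------------------------------------

    @classmethod
    def ld_cycle(
        cls,
        duration_h: float,
        light_h: float = 12.0,
        dark_h: float = 12.0,
        zt0_offset_h: float = 0.0,
        lights_on_first: bool = True,
    ) -> "LightSchedule":
        """A repeating light:dark cycle covering ``duration_h`` hours."""
        ivs: list[tuple[float, float, str]] = []
        t = 0.0
        states = (
            [(light_h, LIGHT), (dark_h, DARK)]
            if lights_on_first
            else [(dark_h, DARK), (light_h, LIGHT)]
        )
        while t < duration_h:
            for length, state in states:
                if t >= duration_h:
                    break
                end = min(t + length, duration_h)
                ivs.append((t, end, state))
                t = end
        return cls(tuple(ivs), zt0_offset_h)

    @classmethod
    def constant(
        cls, duration_h: float, state: str, zt0_offset_h: float = 0.0
    ) -> "LightSchedule":
        """Constant light (LL) or constant dark (DD) over the recording."""
        return cls(((0.0, float(duration_h), state),), zt0_offset_h)

    @classmethod
    def with_pulse(
        cls,
        base: "LightSchedule",
        start_h: float,
        length_h: float,
        state: str,
    ) -> "LightSchedule":
        """Overlay a light or dark pulse on an existing schedule."""
        end_h = start_h + length_h
        ivs: list[tuple[float, float, str]] = []
        for a, b, s in base.intervals:
            segs = [(a, b, s)]
            out: list[tuple[float, float, str]] = []
            for sa, sb, ss in segs:
                lo, hi = max(sa, start_h), min(sb, end_h)
                if lo >= hi:
                    out.append((sa, sb, ss))
                    continue
                if sa < lo:
                    out.append((sa, lo, ss))
                out.append((lo, hi, state))
                if hi < sb:
                    out.append((hi, sb, ss))
            ivs.extend(out)
        # merge adjacent same-state intervals
        merged: list[tuple[float, float, str]] = []
        for a, b, s in ivs:
            if merged and merged[-1][2] == s and merged[-1][1] == a:
                merged[-1] = (merged[-1][0], b, s)
            else:
                merged.append((a, b, s))
        return cls(tuple(merged), base.zt0_offset_h)

    # -- queries ----------------------------------------------------------

    @property
    def duration_h(self) -> float:
        return self.intervals[-1][1]

    def state_at(self, t_h: float) -> str:
        """Light state at recording hour ``t_h`` (half-open intervals)."""
        if not 0.0 <= t_h < self.duration_h:
            raise ScheduleError(f"hour {t_h:g} outside schedule [0, {self.duration_h:g})")
        for a, b, s in self.intervals:
            if a <= t_h < b:
                return s
        raise ScheduleError(f"schedule gap at hour {t_h:g}")  # pragma: no cover

    def is_dark(self, t_h: float) -> bool:
        return self.state_at(t_h) == DARK

    def zt(self, t_h: float) -> float:
        """Zeitgeber time of recording hour ``t_h``, in [0, 24)."""
        return (t_h + self.zt0_offset_h) % 24.0

    def dark_hours(self, duration_h: float | None = None) -> list[int]:
        """Indices of hourly bins whose start lies in a dark interval."""
        d = self.duration_h if duration_h is None else duration_h
        if d > self.duration_h:
            raise ScheduleError("schedule shorter than requested duration")
        return [h for h in range(int(d)) if self.is_dark(h)]
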