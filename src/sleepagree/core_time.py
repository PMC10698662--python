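"""Wall-clock arithmetic on a wrapping 24-hour dial.

Night-time sleep episodes straddle midnight, so naive differences and
arithmetic means of clock times are wrong whenever a set of times
crosses 00:00.  This module provides a :class:`ClockTime` value type,
wrap-aware elapsed time, and anchored (circular) means computed
relative to a reference instant chosen to be far from the times being
averaged — noon, for times clustered around midnight.

Durations are plain integers of seconds throughout the package
(``DurationSec``); conversion to printed ``h:min:s`` strings happens
only at report time, so no cumulative float error accrues.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

SECONDS_PER_DAY = 86_400
HALF_DAY = 43_200

#: Alias documenting intent: signed or unsigned integer seconds.
DurationSec = int


class ClockParseError(ValueError):
    """A clock string or button pair could not be interpreted."""


class DegenerateIntervalError(ValueError):
    """Start and end of a sleep span coincide; a zero-length sleep is never valid."""


class AnchorBoundaryError(ValueError):
    """A time falls exactly on the anchor, so its night is ambiguous."""


@dataclass(frozen=True, order=True)
class ClockTime:
    """An instant of wall-clock time, seconds since midnight in [0, 86399]."""

    seconds_since_midnight: int

    def __post_init__(self) -> None:
        s = self.seconds_since_midnight
        if not isinstance(s, int):
            raise TypeError(f"seconds_since_midnight must be int, got {type(s).__name__}")
        if not 0 <= s < SECONDS_PER_DAY:
            raise ValueError(f"seconds_since_midnight out of range [0, 86399]: {s}")

    @classmethod
    def from_hms(cls, hour: int, minute: int, second: int = 0) -> "ClockTime":
        if not (0 <= hour < 24 and 0 <= minute < 60 and 0 <= second < 60):
            raise ValueError(f"invalid h:m:s {hour}:{minute}:{second}")
        return cls(hour * 3600 + minute * 60 + second)

    @property
    def hour(self) -> int:
        return self.seconds_since_midnight // 3600

    @property
    def minute(self) -> int:
        return (self.seconds_since_midnight // 60) % 60

    @property
    def second(self) -> int:
        return self.seconds_since_midnight % 60

    def isoformat(self) -> str:
        return f"{self.hour:02d}:{self.minute:02d}:{self.second:02d}"

    def shifted(self, seconds: int) -> "ClockTime":
        """This instant shifted by *seconds*, wrapping on the 24 h dial."""
        return ClockTime((self.seconds_since_midnight + seconds) % SECONDS_PER_DAY)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.isoformat()


NOON = ClockTime(HALF_DAY)

_CLOCK_RE = re.compile(
    r"^\s*(\d{1,2}):(\d{2})(?::(\d{2}))?\s*([AaPp])\.?[Mm]\.?\s*$|"
    r"^\s*(\d{1,2}):(\d{2})(?::(\d{2}))?\s*$"
)

CHAT_MINUTE_GRID = frozenset(range(0, 60, 5))


def parse_clock(text: str, dialect: str = "device") -> ClockTime:
    """Parse a clock string into a :class:`ClockTime`.

    Accepted forms: 24-hour ``H:MM[:SS]`` (hour 0–24, where ``24:00``
    wraps to midnight) and 12-hour ``H:MM[:SS] AM/PM``.  With
    ``dialect="chat"`` the minute must lie on the 5-minute button grid
    and seconds are not accepted.
    """
    if dialect not in ("device", "chat"):
        raise ValueError(f"unknown dialect {dialect!r}")
    m = _CLOCK_RE.match(text)
    if m is None:
        raise ClockParseError(f"malformed clock string: {text!r}")
    if m.group(4) is not None:  # 12-hour form
        hour, minute = int(m.group(1)), int(m.group(2))
        second = int(m.group(3) or 0)
        if not 1 <= hour <= 12:
            raise ClockParseError(f"hour out of range 1..12 in {text!r}")
        ampm = m.group(4).lower()
        if ampm == "a":
            hour = 0 if hour == 12 else hour
        else:
            hour = 12 if hour == 12 else hour + 12
    else:
        hour, minute = int(m.group(5)), int(m.group(6))
        second = int(m.group(7) or 0)
        if not 0 <= hour <= 24:
            raise ClockParseError(f"hour out of range 0..24 in {text!r}")
        if hour == 24:
            if minute != 0 or second != 0:
                raise ClockParseError(f"hour 24 only valid as 24:00 in {text!r}")
            hour = 0
    if not 0 <= minute < 60:
        raise ClockParseError(f"minute out of range in {text!r}")
    if not 0 <= second < 60:
        raise ClockParseError(f"second out of range in {text!r}")
    if dialect == "chat":
        if m.group(3) or m.group(7):
            raise ClockParseError(f"seconds not allowed in chat dialect: {text!r}")
        if minute not in CHAT_MINUTE_GRID:
            raise ClockParseError(f"minute {minute} off the 5-minute button grid in {text!r}")
    return ClockTime.from_hms(hour, minute, second)


def from_chat_buttons(hour_button: int, minute_button: int) -> ClockTime:
    """Convert an (hour, minute) button pair to a :class:`ClockTime`.

    Hour buttons run 1..24 (24 wraps to midnight); minute buttons are
    0, 5, ..., 55.
    """
    if not 1 <= hour_button <= 24:
        raise ClockParseError(f"hour button out of range 1..24: {hour_button}")
    if minute_button not in CHAT_MINUTE_GRID:
        raise ClockParseError(f"minute button off the 5-minute grid: {minute_button}")
    return ClockTime.from_hms(hour_button % 24, minute_button)


def elapsed_wrap(start: ClockTime, end: ClockTime) -> DurationSec:
    """Elapsed seconds from *start* to *end* going forward on the dial.

    Strictly in (0, 86400); a zero-length interval raises
    :class:`DegenerateIntervalError`.
    """
    if start == end:
        raise DegenerateIntervalError(f"degenerate interval at {start.isoformat()}")
    return (end.seconds_since_midnight - start.seconds_since_midnight) % SECONDS_PER_DAY


def signed_diff(a: ClockTime, b: ClockTime) -> DurationSec:
    """Minimal signed circular difference a − b, in (−43200, +43200]."""
    d = (a.seconds_since_midnight - b.seconds_since_midnight) % SECONDS_PER_DAY
    if d > HALF_DAY:
        d -= SECONDS_PER_DAY
    return d


def to_anchored(t: ClockTime, anchor: ClockTime = NOON, strict: bool = True) -> int:
    """Map *t* onto a signed seconds axis centred half a day after *anchor*.

    With the default noon anchor, evening times (12:00–24:00) map to
    negative seconds and morning times (00:00–12:00) to positive ones,
    so a night's times are contiguous.  A time exactly on the anchor is
    ambiguous and raises unless ``strict=False`` (it then maps to
    −43200).
    """
    rel = (t.seconds_since_midnight - anchor.seconds_since_midnight) % SECONDS_PER_DAY
    if rel == 0 and strict:
        raise AnchorBoundaryError(f"time {t.isoformat()} lies exactly on the anchor")
    return rel - HALF_DAY


def from_anchored(anchored_seconds: float, anchor: ClockTime = NOON) -> ClockTime:
    """Inverse of :func:`to_anchored`; fractional seconds round to nearest."""
    s = int(round(anchored_seconds))
    return ClockTime((s + HALF_DAY + anchor.seconds_since_midnight) % SECONDS_PER_DAY)


def mean_clock(times: Sequence[ClockTime] | Iterable[ClockTime], anchor: ClockTime = NOON) -> ClockTime:
    """Arithmetic mean of clock times on the anchored axis.

    Equivalent to the naive trick of adding 24 h to the morning times of
    a night before averaging, then reducing modulo 24 h.  Requires all
    times to fall strictly inside the anchor window.
    """
    anchored = [to_anchored(t, anchor) for t in times]
    if not anchored:
        raise ValueError("mean_clock of an empty set is undefined")
    return from_anchored(sum(anchored) / len(anchored), anchor)


def format_duration(seconds: int, with_seconds: bool = True) -> str:
    """Render a signed duration as ``[-]h:mm[:ss]``."""
    sign = "-" if seconds < 0 else ""
    s = abs(int(seconds))
    h, rem = divmod(s, 3600)
    m, sec = divmod(rem, 60)
    return f"{sign}{h}:{m:02d}:{sec:02d}" if with_seconds else f"{sign}{h}:{m:02d}"
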