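"""Rounding-tendency (heaping) profiles and threshold-coverage statistics.

Self-reported times cluster on :00/:30 minute values; device times do
not.  ``minute_profile`` histograms the minute-of-hour of a variable on
the 5-minute grid and reports the share of observations on the half-hour
grid.  ``coverage`` counts the nights whose device-vs-diary difference
falls inside a threshold, optionally after subtracting the full-sample
mean difference or per-quality-stratum mean differences.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Dict, List, Optional, Sequence

import numpy as np

from .core_time import ClockTime
from .derive_agreement import NightVariables, qos_is_good
from .records_io import ChatSleepRecord, FitbitSleepRecord, PsqiRecord

SOURCES = ("psqi", "chat", "fitbit")
VARIABLES = ("bed_time", "fall_asleep", "wake", "ast")
GRID_BINS = tuple(range(0, 60, 5))
CORRECTIONS = ("none", "global_mean", "by_qos")
PAIRS = ("tst_vs_tst", "ast_vs_tstwaso")


def round_half_away(value: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention used in printed tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def percent_1dp(count: int, total: int) -> float:
    """100 * count/total, rounded half-away-from-zero to one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round_half_away(100.0 * count / total, 1)


def snap_to_5min_seconds(seconds: int) -> int:
    """Nearest 5-minute grid in seconds; exact half-grid ties round down."""
    return ((seconds + 149) // 300) * 300


@dataclass(frozen=True)
class RoundingHistogram:
    source: str
    variable: str
    counts: Dict[int, int]  # minute bin (0, 5, ..., 55) -> count
    n: int

    @property
    def grid_fraction(self) -> float:
        """Share of observations with minute-of-hour in {0, 30}."""
        return (self.counts.get(0, 0) + self.counts.get(30, 0)) / self.n

    @property
    def grid_percent(self) -> float:
        return percent_1dp(self.counts.get(0, 0) + self.counts.get(30, 0), self.n)


def _minutes_chat(records: Sequence[ChatSleepRecord], variable: str) -> List[int]:
    if variable == "ast":
        return [r.ast_minutes % 60 for r in records]
    attr = {"bed_time": "bed_time", "fall_asleep": "asleep_time", "wake": "wake_time"}[variable]
    return [getattr(r, attr).minute for r in records]


def _minutes_psqi(records: Sequence[PsqiRecord], variable: str) -> List[int]:
    if variable == "bed_time":
        return [r.bed_time.minute for r in records]
    if variable == "fall_asleep":
        # the survey asks for bedtime and latency; fall-asleep time is their sum
        out = []
        for r in records:
            sec = (r.bed_time.seconds_since_midnight + r.sol_minutes * 60) % 86_400
            out.append((snap_to_5min_seconds(sec) // 60) % 60)
        return out
    if variable == "wake":
        return [r.wake_time.minute for r in records]
    if variable == "ast":
        return [(snap_to_5min_seconds(int(round(r.reported_sleep_h * 3600))) // 60) % 60
                for r in records]
    raise ValueError(f"unknown variable {variable!r}")


def _minutes_fitbit(records: Sequence[FitbitSleepRecord], variable: str) -> List[int]:
    if variable == "bed_time":
        raise ValueError("the device stream has no bed time")
    out = []
    for r in records:
        if variable == "fall_asleep":
            sec = r.start_clock.seconds_since_midnight
        elif variable == "wake":
            sec = r.end_clock.seconds_since_midnight
        elif variable == "ast":
            sec = r.span_seconds - r.minutes_awake * 60
        else:
            raise ValueError(f"unknown variable {variable!r}")
        out.append((snap_to_5min_seconds(sec) // 60) % 60)
    return out


def minute_profile(records: Sequence, source: str, variable: str) -> RoundingHistogram:
    """Histogram the minute-of-hour of one variable on the 5-minute grid.

    Diary values already lie on the button grid; survey and device
    values are snapped to the nearest 5-minute bin first (survey
    fall-asleep time is derived as bed time + latency before snapping,
    device sleep amount as span - awake minutes).
    """
    if source not in SOURCES:
        raise ValueError(f"unknown source {source!r}")
    if variable not in VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    if not records:
        raise ValueError("empty input")
    minutes = {"chat": _minutes_chat, "psqi": _minutes_psqi, "fitbit": _minutes_fitbit}[source](records, variable)
    counts = {b: 0 for b in GRID_BINS}
    for m in minutes:
        if m not in counts:
            raise ValueError(f"minute value {m} off the 5-minute grid")
        counts[m] += 1
    return RoundingHistogram(source, variable, counts, len(minutes))


@dataclass(frozen=True)
class CoverageResult:
    threshold_minutes: float
    correction: str
    n_within: int
    n_total: int

    @property
    def percent(self) -> float:
        return percent_1dp(self.n_within, self.n_total)


def coverage_from_diffs(
    diffs_seconds: Sequence[float],
    threshold_minutes: float,
    correction: str = "none",
    qos: Optional[Sequence[str]] = None,
    inclusive: bool = True,
) -> CoverageResult:
    """Count differences within +/- threshold under a bias-correction mode.

    ``global_mean`` subtracts the full-sample mean difference from every
    night; ``by_qos`` subtracts the mean difference of the night's
    quality stratum (good/poor).  ``inclusive`` controls whether a
    difference exactly on the threshold counts as within.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction mode {correction!r}")
    arr = np.asarray(list(diffs_seconds), dtype=float)
    if arr.size == 0:
        raise ValueError("empty night set")
    if correction == "global_mean":
        arr = arr - arr.mean()
    elif correction == "by_qos":
        if qos is None or len(qos) != arr.size:
            raise ValueError("by_qos correction needs one qos label per night")
        good = np.array([qos_is_good(q) for q in qos], dtype=bool)
        for mask in (good, ~good):
            if mask.any():
                arr[mask] = arr[mask] - arr[mask].mean()
    thr = threshold_minutes * 60.0
    within = np.abs(arr) <= thr if inclusive else np.abs(arr) < thr
    return CoverageResult(threshold_minutes, correction, int(within.sum()), int(arr.size))


def coverage(
    nights: Sequence[NightVariables],
    pair: str = "ast_vs_tstwaso",
    threshold_minutes: float = 30.0,
    correction: str = "none",
    inclusive: bool = True,
) -> CoverageResult:
    """Threshold coverage of per-night differences for one variable pair."""
    if pair not in PAIRS:
        raise ValueError(f"unknown pair {pair!r}")
    variable = "tst" if pair == "tst_vs_tst" else "ast"
    diffs = [n.diff(variable) for n in nights]
    qos = [n.qos for n in nights] if correction == "by_qos" else None
    return coverage_from_diffs(diffs, threshold_minutes, correction, qos, inclusive)
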