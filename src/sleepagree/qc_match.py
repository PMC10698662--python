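"""Cleaning, matching, capping and inclusion rules plus compliance summaries.

A night enters the analysis only when the same (participant, date) pair
has both a device main-sleep record and a diary entry, the diary's
bed -> asleep -> wake order is monotone on the night's anchored
timeline, and neither the reported sleep onset nor offset differs from
the device value by more than a configurable bound (default 9 h; a
violation close to a 12 h shift is labelled an AM/PM input error, and
is excluded rather than corrected).  Participants contribute at most the
first ``cap_days`` calendar days of device data and are included only
with at least ``min_days`` valid matched nights.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import date
from typing import Optional, Sequence

from .core_time import ClockTime, signed_diff, to_anchored
from .records_io import ChatSleepRecord, FitbitSleepRecord, RowReject

VALID = "valid"
ORDER_VIOLATION = "order_violation"
AMPM_ERROR = "ampm_error"
OVERLARGE_DIFFERENCE = "overlarge_difference"
QC_STATUSES = (VALID, ORDER_VIOLATION, AMPM_ERROR, OVERLARGE_DIFFERENCE)

#: an overlarge clock difference within this margin of a 12 h shift is
#: attributed to an AM/PM input error rather than generic disagreement
_AMPM_ATTRIBUTION_MARGIN_SEC = 3600

DAY_BUCKETS = ["0", "1-3", "4-6", "7-9", "10", "11", "12", "13", "14", "15", "16-18", "19-21", "22"]
LATENCY_BUCKETS = ["within_3h", "within_6h", "within_9h", "within_12h", "within_15h", "after_15h"]


class MatchInconsistencyError(ValueError):
    """Duplicate records for one (participant, date): the streams are inconsistent."""


@dataclass(frozen=True)
class MatchedNight:
    participant_id: str
    sleep_date: date
    fitbit: FitbitSleepRecord
    chat: ChatSleepRecord
    qc_status: str


@dataclass
class AnalysisSet:
    """Included participants with their valid nights, plus exclusion tallies."""

    participants: dict  # participant_id -> list[MatchedNight] (valid, capped)
    night_exclusions: Counter  # qc reason -> night count
    excluded_participants: list  # ids failing the min_days rule
    per_participant_valid: dict  # participant_id -> valid-night count (pre-inclusion)
    min_days: int
    cap_days: int

    @property
    def n_included(self) -> int:
        return len(self.participants)

    def all_valid_nights(self) -> list:
        return [n for nights in self.participants.values() for n in nights]


def _anchored_loose(t: ClockTime) -> int:
    return to_anchored(t, strict=False)


def _qc_status(fitbit: FitbitSleepRecord, chat: ChatSleepRecord, max_diff_sec: int) -> str:
    bed, asleep, wake = (_anchored_loose(chat.bed_time),
                         _anchored_loose(chat.asleep_time),
                         _anchored_loose(chat.wake_time))
    if not (bed <= asleep < wake):
        return ORDER_VIOLATION
    d_onset = signed_diff(chat.asleep_time, fitbit.start_clock)
    d_offset = signed_diff(chat.wake_time, fitbit.end_clock)
    worst = max(abs(d_onset), abs(d_offset))
    if worst > max_diff_sec:
        # distance of the worst offender from a clean 12 h shift
        if 43200 - worst <= _AMPM_ATTRIBUTION_MARGIN_SEC:
            return AMPM_ERROR
        return OVERLARGE_DIFFERENCE
    return VALID


def validate_and_match(
    fitbit_records: Sequence[FitbitSleepRecord],
    chat_records: Sequence[ChatSleepRecord],
    max_clock_diff_hours: float = 9.0,
) -> list:
    """Join device main sleeps to diary entries per (participant, date) and QC them.

    Only nights present in both streams are returned; each carries a
    ``qc_status``.  Duplicate main sleeps (or diary entries) for one
    (participant, date) raise :class:`MatchInconsistencyError`.
    """
    max_diff_sec = int(round(max_clock_diff_hours * 3600))
    by_key_fitbit: dict = {}
    for rec in fitbit_records:
        if not rec.is_main_sleep:
            continue
        key = (rec.participant_id, rec.sleep_date)
        if key in by_key_fitbit:
            raise MatchInconsistencyError(f"duplicate main sleep for {key}")
        by_key_fitbit[key] = rec
    by_key_chat: dict = {}
    for rec in chat_records:
        key = (rec.participant_id, rec.sleep_date)
        if key in by_key_chat:
            raise MatchInconsistencyError(f"duplicate diary entry for {key}")
        by_key_chat[key] = rec
    matched = []
    for key in sorted(by_key_fitbit.keys() & by_key_chat.keys()):
        fb, ch = by_key_fitbit[key], by_key_chat[key]
        matched.append(MatchedNight(key[0], key[1], fb, ch, _qc_status(fb, ch, max_diff_sec)))
    return matched


def select_analysis_set(
    matched: Sequence[MatchedNight],
    min_days: int = 7,
    cap_days: int = 14,
    fitbit_records: Optional[Sequence[FitbitSleepRecord]] = None,
) -> AnalysisSet:
    """Cap each participant to their first ``cap_days`` device days, then include
    participants with at least ``min_days`` valid matched nights.

    When the raw device stream is supplied, the cap window is the first
    ``cap_days`` distinct main-sleep dates of that stream (device days
    without a diary still consume the window); otherwise the matched
    nights' own dates define it.
    """
    window: dict = {}
    if fitbit_records is not None:
        dates_by_pid: dict = defaultdict(set)
        for rec in fitbit_records:
            if rec.is_main_sleep:
                dates_by_pid[rec.participant_id].add(rec.sleep_date)
        for pid, ds in dates_by_pid.items():
            window[pid] = set(sorted(ds)[:cap_days])
    else:
        dates_by_pid = defaultdict(set)
        for night in matched:
            dates_by_pid[night.participant_id].add(night.sleep_date)
        for pid, ds in dates_by_pid.items():
            window[pid] = set(sorted(ds)[:cap_days])

    night_exclusions: Counter = Counter()
    valid_by_pid: dict = defaultdict(list)
    for night in sorted(matched, key=lambda n: (n.participant_id, n.sleep_date)):
        if night.sleep_date not in window.get(night.participant_id, set()):
            night_exclusions["beyond_cap"] += 1
            continue
        if night.qc_status == VALID:
            valid_by_pid[night.participant_id].append(night)
        else:
            night_exclusions[night.qc_status] += 1

    per_participant_valid = {pid: len(nights) for pid, nights in valid_by_pid.items()}
    included = {pid: nights for pid, nights in valid_by_pid.items() if len(nights) >= min_days}
    excluded = sorted(set(valid_by_pid) - set(included))
    return AnalysisSet(
        participants=dict(sorted(included.items())),
        night_exclusions=night_exclusions,
        excluded_participants=excluded,
        per_participant_valid=per_participant_valid,
        min_days=min_days,
        cap_days=cap_days,
    )


def day_bucket(n_days: int) -> str:
    """Bucket a device-day count into the wear-compliance rows."""
    if n_days < 0:
        raise ValueError("negative day count")
    if n_days == 0:
        return "0"
    if n_days <= 3:
        return "1-3"
    if n_days <= 6:
        return "4-6"
    if n_days <= 9:
        return "7-9"
    if n_days <= 15:
        return str(n_days)
    if n_days <= 18:
        return "16-18"
    if n_days <= 21:
        return "19-21"
    return "22"


def latency_bucket(hours: float) -> str:
    """Half-open latency buckets: [0,3), [3,6), ..., [15, inf)."""
    if hours < 0:
        raise ValueError("negative latency")
    for bound, label in zip((3, 6, 9, 12, 15), LATENCY_BUCKETS):
        if hours < bound:
            return label
    return "after_15h"


@dataclass
class ComplianceReport:
    device_days: dict            # participant_id -> distinct main-sleep day count
    day_bucket_counts: Counter   # bucket label -> participants
    mean_latency_hours: dict     # participant_id -> mean response latency
    latency_bucket_counts: Counter
    latency_cumulative: dict     # bucket label -> cumulative participants
    rejects: list                # RowReject for impossible latencies


def compliance_summary(
    fitbit_records: Sequence[FitbitSleepRecord],
    chat_records: Sequence[ChatSleepRecord],
) -> ComplianceReport:
    """Per-participant wear-day buckets and mean chat-response latency buckets."""
    days: dict = defaultdict(set)
    for rec in fitbit_records:
        if rec.is_main_sleep:
            days[rec.participant_id].add(rec.sleep_date)
    device_days = {pid: len(ds) for pid, ds in days.items()}
    bucket_counts = Counter(day_bucket(n) for n in device_days.values())

    latencies: dict = defaultdict(list)
    rejects: list = []
    for i, rec in enumerate(chat_records):
        delta_h = (rec.response_ts - rec.prompt_ts).total_seconds() / 3600
        if delta_h < 0:
            rejects.append(RowReject(i, "response before prompt", {"participant_id": rec.participant_id}))
            continue
        latencies[rec.participant_id].append(delta_h)
    mean_latency = {pid: sum(v) / len(v) for pid, v in latencies.items()}
    lat_counts = Counter(latency_bucket(h) for h in mean_latency.values())
    cumulative, running = {}, 0
    for label in LATENCY_BUCKETS:
        running += lat_counts.get(label, 0)
        cumulative[label] = running
    return ComplianceReport(device_days, bucket_counts, mean_latency, lat_counts, cumulative, rejects)
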