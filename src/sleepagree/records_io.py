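"""Readers and writers for the three raw record streams and participant profiles.

All streams are UTF-8 comma-separated text with a header row; device
records are additionally accepted as a JSON array mirroring the vendor
API dialect (``startTime`` / ``endTime`` / ``minutesAwake`` /
``isMainSleep`` with ISO 8601 timestamps).  Readers never silently drop
a row: rows failing type or invariant checks come back on a reject list
with machine-readable reason codes, and accepted + rejected always sums
to the file's row count.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

from .core_time import ClockTime, ClockParseError, parse_clock

QOS_LEVELS = ("very_good", "quite_good", "quite_poor", "very_poor")
GENDERS = ("men", "women")

FITBIT_COLUMNS = ["participant_id", "startTime", "endTime", "minutesAwake", "isMainSleep"]
CHAT_COLUMNS = [
    "participant_id", "sleep_date", "bed_time", "asleep_time", "wake_time",
    "n_awakenings", "ast_minutes", "qos", "strenuous_activity",
    "sitting_minutes", "prompt_ts", "response_ts",
]
PSQI_COLUMNS = ["participant_id", "bed_time", "sol_minutes", "wake_time", "reported_sleep_h", "total_score"]
PROFILE_COLUMNS = ["participant_id", "gender", "age_years", "bmi"]


class RecordsIOError(ValueError):
    """Fatal file-level problem (unreadable file, missing column, duplicate key)."""


@dataclass(frozen=True)
class RowReject:
    """One rejected input row: position, machine reason code, raw content."""

    row_number: int
    reason: str
    raw: dict


class ReadResult(NamedTuple):
    records: list
    rejects: list


@dataclass(frozen=True)
class FitbitSleepRecord:
    """One device-detected sleep event.

    ``sleep_date`` is the calendar date on which the sleep ENDS (the
    morning date); both record streams are keyed this way for matching.
    ``minutes_awake`` is stored as the integer minutes the device
    reports and converted to seconds only in derivations.
    """

    participant_id: str
    start: datetime
    end: datetime
    minutes_awake: int
    is_main_sleep: bool

    @property
    def sleep_date(self) -> date:
        return self.end.date()

    @property
    def start_clock(self) -> ClockTime:
        t = self.start.time()
        return ClockTime.from_hms(t.hour, t.minute, t.second)

    @property
    def end_clock(self) -> ClockTime:
        t = self.end.time()
        return ClockTime.from_hms(t.hour, t.minute, t.second)

    @property
    def span_seconds(self) -> int:
        return int((self.end - self.start).total_seconds())


@dataclass(frozen=True)
class ChatSleepRecord:
    """One morning diary entry about the night before.

    Clock fields are constrained to the 5-minute button grid at parse
    time.  ``strenuous_activity`` and ``sitting_minutes`` are carried
    through but never analyzed.
    """

    participant_id: str
    sleep_date: date
    bed_time: ClockTime
    asleep_time: ClockTime
    wake_time: ClockTime
    n_awakenings: int
    ast_minutes: int
    qos: str
    strenuous_activity: bool
    sitting_minutes: int
    prompt_ts: datetime
    response_ts: datetime


@dataclass(frozen=True)
class PsqiRecord:
    participant_id: str
    bed_time: ClockTime
    sol_minutes: int
    wake_time: ClockTime
    reported_sleep_h: float
    total_score: Optional[int]  # None = missing -> "not classified"


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    gender: str
    age_years: int
    bmi: float


@dataclass
class CohortMetadata:
    """PSQI + profile streams joined on participant_id, with availability report."""

    psqi: list = field(default_factory=list)
    profiles: list = field(default_factory=list)
    only_in_psqi: list = field(default_factory=list)
    only_in_profiles: list = field(default_factory=list)


def _parse_bool(text: str) -> bool:
    t = text.strip().lower()
    if t in ("true", "1", "yes"):
        return True
    if t in ("false", "0", "no"):
        return False
    raise ValueError(f"not a boolean: {text!r}")


def _parse_ts(text: str) -> datetime:
    return datetime.fromisoformat(text.strip())


def _require_columns(have, need, path) -> None:
    missing = [c for c in need if c not in have]
    if missing:
        raise RecordsIOError(f"{path}: missing mandatory column(s) {missing}")


# ---------------------------------------------------------------------------
# Fitbit-style device records


def _fitbit_from_fields(row: dict, row_number: int) -> FitbitSleepRecord:
    start = _parse_ts(row["startTime"])
    end = _parse_ts(row["endTime"])
    minutes_awake = int(row["minutesAwake"])
    is_main = _parse_bool(str(row["isMainSleep"]))
    if end <= start:
        raise ValueError("end not after start")
    if minutes_awake < 0:
        raise ValueError("negative minutesAwake")
    span = int((end - start).total_seconds())
    if minutes_awake * 60 >= span:
        raise ValueError("WASO exceeds interval")
    return FitbitSleepRecord(str(row["participant_id"]), start, end, minutes_awake, is_main)


def read_fitbit(path: str | Path) -> ReadResult:
    """Read device sleep records from CSV or a JSON array dialect."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise RecordsIOError(f"cannot read {path}: {exc}") from exc
    records: list[FitbitSleepRecord] = []
    rejects: list[RowReject] = []
    if path.suffix.lower() == ".json":
        try:
            rows = json.loads(text)
        except json.JSONDecodeError as exc:
            raise RecordsIOError(f"{path}: invalid JSON: {exc}") from exc
        if not isinstance(rows, list):
            raise RecordsIOError(f"{path}: expected a JSON array of objects")
        for i, row in enumerate(rows):
            missing = [k for k in FITBIT_COLUMNS if k not in row]
            if missing:
                raise RecordsIOError(f"{path}: object {i} missing key(s) {missing}")
            try:
                records.append(_fitbit_from_fields(row, i))
            except (ValueError, TypeError) as exc:
                rejects.append(RowReject(i, str(exc), dict(row)))
    else:
        reader = csv.DictReader(text.splitlines())
        _require_columns(reader.fieldnames or [], FITBIT_COLUMNS, path)
        for i, row in enumerate(reader):
            try:
                records.append(_fitbit_from_fields(row, i))
            except (ValueError, TypeError) as exc:
                rejects.append(RowReject(i, str(exc), dict(row)))
    return ReadResult(records, rejects)


def write_fitbit(records: Sequence[FitbitSleepRecord], path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        rows = [
            {
                "participant_id": r.participant_id,
                "startTime": r.start.isoformat(),
                "endTime": r.end.isoformat(),
                "minutesAwake": r.minutes_awake,
                "isMainSleep": r.is_main_sleep,
            }
            for r in records
        ]
        path.write_text(json.dumps(rows, indent=1) + "\n", encoding="utf-8")
        return
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(FITBIT_COLUMNS)
        for r in records:
            w.writerow([r.participant_id, r.start.isoformat(), r.end.isoformat(),
                        r.minutes_awake, "true" if r.is_main_sleep else "false"])


# ---------------------------------------------------------------------------
# Chat diary records


def _chat_from_row(row: dict) -> ChatSleepRecord:
    qos = row["qos"].strip()
    if qos not in QOS_LEVELS:
        raise ValueError(f"unknown qos level {qos!r}")
    prompt_ts = _parse_ts(row["prompt_ts"])
    response_ts = _parse_ts(row["response_ts"])
    if response_ts < prompt_ts:
        raise ValueError("response before prompt")
    ast_minutes = int(row["ast_minutes"])
    if ast_minutes <= 0:
        raise ValueError("non-positive actual sleep time")
    n_awakenings = int(row["n_awakenings"])
    if n_awakenings < 0:
        raise ValueError("negative awakening count")
    try:
        bed = parse_clock(row["bed_time"], dialect="chat")
        asleep = parse_clock(row["asleep_time"], dialect="chat")
        wake = parse_clock(row["wake_time"], dialect="chat")
    except ClockParseError as exc:
        if "off the 5-minute" in str(exc):
            raise ValueError(f"off-grid minute: {exc}") from exc
        raise ValueError(str(exc)) from exc
    return ChatSleepRecord(
        participant_id=str(row["participant_id"]),
        sleep_date=date.fromisoformat(row["sleep_date"]),
        bed_time=bed,
        asleep_time=asleep,
        wake_time=wake,
        n_awakenings=n_awakenings,
        ast_minutes=ast_minutes,
        qos=qos,
        strenuous_activity=_parse_bool(row["strenuous_activity"]),
        sitting_minutes=int(row["sitting_minutes"]),
        prompt_ts=prompt_ts,
        response_ts=response_ts,
    )


def read_chat(path: str | Path) -> ReadResult:
    """Read chat diary records; no semantic QC beyond field validity."""
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise RecordsIOError(f"cannot read {path}: {exc}") from exc
    reader = csv.DictReader(text.splitlines())
    _require_columns(reader.fieldnames or [], CHAT_COLUMNS, path)
    records, rejects = [], []
    for i, row in enumerate(reader):
        try:
            records.append(_chat_from_row(row))
        except (ValueError, TypeError) as exc:
            rejects.append(RowReject(i, str(exc), dict(row)))
    return ReadResult(records, rejects)


def _clock_hm(t: ClockTime) -> str:
    return f"{t.hour:02d}:{t.minute:02d}"


def write_chat(records: Sequence[ChatSleepRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(CHAT_COLUMNS)
        for r in records:
            w.writerow([
                r.participant_id, r.sleep_date.isoformat(),
                _clock_hm(r.bed_time), _clock_hm(r.asleep_time), _clock_hm(r.wake_time),
                r.n_awakenings, r.ast_minutes, r.qos,
                "true" if r.strenuous_activity else "false",
                r.sitting_minutes, r.prompt_ts.isoformat(), r.response_ts.isoformat(),
            ])


# ---------------------------------------------------------------------------
# PSQI survey + participant profiles


def _read_csv_rows(path: Path, columns: list[str]) -> list[dict]:
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise RecordsIOError(f"cannot read {path}: {exc}") from exc
    reader = csv.DictReader(text.splitlines())
    _require_columns(reader.fieldnames or [], columns, path)
    return list(reader)


def read_cohort_metadata(psqi_path: str | Path, profile_path: str | Path) -> CohortMetadata:
    """Read PSQI and profile streams; duplicates within a file are fatal.

    Missing total scores are preserved as ``None`` (those participants
    stay in the cohort but cannot be classified into a sleep group).
    """
    psqi_rows = _read_csv_rows(Path(psqi_path), PSQI_COLUMNS)
    profile_rows = _read_csv_rows(Path(profile_path), PROFILE_COLUMNS)
    meta = CohortMetadata()
    seen: set[str] = set()
    for row in psqi_rows:
        pid = str(row["participant_id"])
        if pid in seen:
            raise RecordsIOError(f"duplicate participant_id {pid!r} in {psqi_path}")
        seen.add(pid)
        score_txt = (row.get("total_score") or "").strip()
        score = int(score_txt) if score_txt else None
        if score is not None and not 0 <= score <= 21:
            raise RecordsIOError(f"PSQI total_score out of range for {pid!r}: {score}")
        meta.psqi.append(PsqiRecord(
            participant_id=pid,
            bed_time=parse_clock(row["bed_time"]),
            sol_minutes=int(row["sol_minutes"]),
            wake_time=parse_clock(row["wake_time"]),
            reported_sleep_h=float(row["reported_sleep_h"]),
            total_score=score,
        ))
    seen_prof: set[str] = set()
    for row in profile_rows:
        pid = str(row["participant_id"])
        if pid in seen_prof:
            raise RecordsIOError(f"duplicate participant_id {pid!r} in {profile_path}")
        seen_prof.add(pid)
        gender = row["gender"].strip()
        if gender not in GENDERS:
            raise RecordsIOError(f"unknown gender {gender!r} for {pid!r}")
        bmi = float(row["bmi"])
        if bmi <= 0:
            raise RecordsIOError(f"non-positive bmi for {pid!r}")
        meta.profiles.append(ParticipantProfile(pid, gender, int(row["age_years"]), bmi))
    meta.only_in_psqi = sorted(seen - seen_prof)
    meta.only_in_profiles = sorted(seen_prof - seen)
    return meta


def write_psqi(records: Sequence[PsqiRecord], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PSQI_COLUMNS)
        for r in records:
            w.writerow([
                r.participant_id, _clock_hm(r.bed_time), r.sol_minutes,
                _clock_hm(r.wake_time), f"{r.reported_sleep_h:g}",
                "" if r.total_score is None else r.total_score,
            ])


def write_profiles(records: Sequence[ParticipantProfile], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(PROFILE_COLUMNS)
        for r in records:
            w.writerow([r.participant_id, r.gender, r.age_years, f"{r.bmi:.1f}"])
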