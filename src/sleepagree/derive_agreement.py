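"""Per-night sleep variables, participant means, and Bland-Altman agreement.

Sign convention for every paired difference: device minus diary, so a
positive difference means the device value is later (clock variables)
or longer (durations).  Limits of agreement are the classic
mean +/- 1.96 x SD of the paired differences with the sample (n-1) SD
estimator, and p-values are two-sided one-sample t tests of the
differences against zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
from scipy import stats

from .core_time import ClockTime, elapsed_wrap, mean_clock, signed_diff
from .qc_match import AnalysisSet, MatchedNight, VALID
from .records_io import ParticipantProfile, PsqiRecord

DIFF_VARIABLES = ("onset", "offset", "tst", "ast")

QOS_GOOD = ("very_good", "quite_good")


class DerivationError(ValueError):
    """A derived quantity fell outside its admissible range (QC leak)."""


@dataclass(frozen=True)
class NightVariables:
    """All per-night quantities for one valid matched night (seconds)."""

    participant_id: str
    chat_onset: ClockTime
    chat_offset: ClockTime
    chat_tst: int
    chat_ast: int
    fitbit_onset: ClockTime
    fitbit_offset: ClockTime
    fitbit_tst: int
    fitbit_waso: int
    fitbit_ast: int
    diff_onset: int   # device - diary, signed circular seconds
    diff_offset: int
    diff_tst: int
    diff_ast: int     # fitbit (TST - WASO) - diary AST
    qos: Optional[str] = None

    def diff(self, variable: str) -> int:
        return {"onset": self.diff_onset, "offset": self.diff_offset,
                "tst": self.diff_tst, "ast": self.diff_ast}[variable]


def derive_night(matched: MatchedNight) -> NightVariables:
    """Compute the per-night variable set from one valid matched night."""
    if matched.qc_status != VALID:
        raise DerivationError(f"cannot derive from a night with qc_status={matched.qc_status!r}")
    chat, fb = matched.chat, matched.fitbit
    chat_tst = elapsed_wrap(chat.asleep_time, chat.wake_time)
    chat_ast = chat.ast_minutes * 60
    fitbit_tst = fb.span_seconds
    fitbit_waso = fb.minutes_awake * 60
    fitbit_ast = fitbit_tst - fitbit_waso
    for name, dur in (("chat TST", chat_tst), ("chat AST", chat_ast),
                      ("device TST", fitbit_tst), ("device TST-WASO", fitbit_ast)):
        if not 0 < dur < 86_400:
            raise DerivationError(f"{name} out of (0, 24 h): {dur} s")
    return NightVariables(
        participant_id=matched.participant_id,
        chat_onset=chat.asleep_time,
        chat_offset=chat.wake_time,
        chat_tst=chat_tst,
        chat_ast=chat_ast,
        fitbit_onset=fb.start_clock,
        fitbit_offset=fb.end_clock,
        fitbit_tst=fitbit_tst,
        fitbit_waso=fitbit_waso,
        fitbit_ast=fitbit_ast,
        diff_onset=signed_diff(fb.start_clock, chat.asleep_time),
        diff_offset=signed_diff(fb.end_clock, chat.wake_time),
        diff_tst=fitbit_tst - chat_tst,
        diff_ast=fitbit_ast - chat_ast,
        qos=chat.qos,
    )


@dataclass(frozen=True)
class ParticipantMeans:
    """Per-participant means of the night variables (clock fields circular)."""

    participant_id: str
    n_nights: int
    chat_onset: ClockTime
    chat_offset: ClockTime
    fitbit_onset: ClockTime
    fitbit_offset: ClockTime
    chat_tst: float
    chat_ast: float
    fitbit_tst: float
    fitbit_ast: float
    mean_diffs: Dict[str, float]  # variable -> mean of night diffs (seconds)


def participant_means(participant_id: str, nights: Sequence[NightVariables]) -> ParticipantMeans:
    if not nights:
        raise ValueError("no nights to average")
    return ParticipantMeans(
        participant_id=participant_id,
        n_nights=len(nights),
        chat_onset=mean_clock([n.chat_onset for n in nights]),
        chat_offset=mean_clock([n.chat_offset for n in nights]),
        fitbit_onset=mean_clock([n.fitbit_onset for n in nights]),
        fitbit_offset=mean_clock([n.fitbit_offset for n in nights]),
        chat_tst=float(np.mean([n.chat_tst for n in nights])),
        chat_ast=float(np.mean([n.chat_ast for n in nights])),
        fitbit_tst=float(np.mean([n.fitbit_tst for n in nights])),
        fitbit_ast=float(np.mean([n.fitbit_ast for n in nights])),
        mean_diffs={v: float(np.mean([n.diff(v) for n in nights])) for v in DIFF_VARIABLES},
    )


@dataclass(frozen=True)
class AgreementStats:
    n: int
    mean_diff: float       # seconds
    sd_diff: float         # seconds, sample (n-1) SD
    half_width: float      # 1.96 * sd_diff
    loa_low: float
    loa_high: float
    p_paired_t: float      # nan when the differences have zero variance

    @classmethod
    def from_summary(cls, n: int, mean_diff: float, sd_diff: float,
                     p_paired_t: float = float("nan")) -> "AgreementStats":
        hw = 1.96 * sd_diff
        return cls(n, mean_diff, sd_diff, hw, mean_diff - hw, mean_diff + hw, p_paired_t)


def agreement_stats(diffs: Sequence[float]) -> AgreementStats:
    """Bland-Altman summary of a list of paired differences (seconds)."""
    arr = np.asarray(list(diffs), dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 differences")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    if sd == 0.0:
        p = float("nan")
    else:
        p = float(stats.ttest_1samp(arr, 0.0).pvalue)
    return AgreementStats.from_summary(int(arr.size), mean, sd, p)


# ---------------------------------------------------------------------------
# Group classification

BMI_CLASSES = (
    ("underweight", 0.0, 18.5),
    ("normal", 18.5, 23.0),
    ("preobese", 23.0, 25.0),
    ("obesity_1", 25.0, 30.0),
    ("obesity_2", 30.0, float("inf")),
)


def psqi_group(total_score: Optional[int]) -> str:
    """Good sleep group at 5 points or less; missing scores are unclassified."""
    if total_score is None:
        return "unclassified"
    return "good" if total_score <= 5 else "poor"


def age_decade(age_years: int) -> str:
    if not 10 <= age_years <= 120:
        raise ValueError(f"implausible age {age_years}")
    return f"{(age_years // 10) * 10}s"


def bmi_class(bmi: float) -> str:
    if bmi <= 0:
        raise ValueError(f"non-positive BMI {bmi}")
    for label, lo, hi in BMI_CLASSES:
        if lo <= bmi < hi:
            return label
    raise AssertionError("unreachable")


def qos_is_good(qos: str) -> bool:
    """'Very good' / 'Quite good' nights count as good sleep."""
    return qos in QOS_GOOD


def classify_participant(profile: ParticipantProfile, psqi: Optional[PsqiRecord]) -> Dict[str, str]:
    """Total classification of a participant along every stratification axis."""
    return {
        "psqi": psqi_group(psqi.total_score if psqi is not None else None),
        "gender": profile.gender,
        "age": age_decade(profile.age_years),
        "bmi": bmi_class(profile.bmi),
    }


# ---------------------------------------------------------------------------
# Stratified agreement

PARTICIPANT_STRATA = ("psqi", "gender", "age", "bmi")


@dataclass(frozen=True)
class GroupKey:
    axis: str    # "psqi", "gender", "age", "bmi", or "qos"
    level: str


def nights_by_participant(analysis_set: AnalysisSet) -> Dict[str, List[NightVariables]]:
    return {pid: [derive_night(n) for n in nights]
            for pid, nights in analysis_set.participants.items()}


def stratified_agreement(
    analysis_set: AnalysisSet,
    profiles: Sequence[ParticipantProfile],
    psqi_records: Sequence[PsqiRecord],
    variable: str = "ast",
    axes: Sequence[str] = PARTICIPANT_STRATA + ("qos",),
) -> Dict[GroupKey, Optional[AgreementStats]]:
    """Agreement per stratum.

    Participant-level axes (psqi, gender, age, bmi) average each
    participant's night differences first, then summarize those means
    (equal weight per participant).  The nightly quality-of-sleep axis
    pools per-night differences across participants (weight per night).
    Strata with fewer than 2 observations report ``None``.
    """
    if variable not in DIFF_VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    prof_by_id = {p.participant_id: p for p in profiles}
    psqi_by_id = {p.participant_id: p for p in psqi_records}
    per_pid_nights = nights_by_participant(analysis_set)

    out: Dict[GroupKey, Optional[AgreementStats]] = {}
    groups: Dict[GroupKey, list] = {}
    for pid, nights in per_pid_nights.items():
        if pid not in prof_by_id:
            raise ValueError(f"no profile for included participant {pid!r}")
        labels = classify_participant(prof_by_id[pid], psqi_by_id.get(pid))
        mean_diff = float(np.mean([n.diff(variable) for n in nights]))
        for axis in PARTICIPANT_STRATA:
            if axis in axes:
                groups.setdefault(GroupKey(axis, labels[axis]), []).append(mean_diff)
    if "qos" in axes:
        for nights in per_pid_nights.values():
            for n in nights:
                level = "good" if qos_is_good(n.qos) else "poor"
                groups.setdefault(GroupKey("qos", level), []).append(float(n.diff(variable)))
    for key, diffs in groups.items():
        out[key] = agreement_stats(diffs) if len(diffs) >= 2 else None
    return out


def bland_altman_points(nights: Sequence[NightVariables], variable: str = "ast") -> List[tuple]:
    """(x, y) point set with x = device value and y = device - diary difference."""
    if variable not in DIFF_VARIABLES:
        raise ValueError(f"unknown variable {variable!r}")
    xs = {
        "onset": lambda n: n.fitbit_onset.seconds_since_midnight,
        "offset": lambda n: n.fitbit_offset.seconds_since_midnight,
        "tst": lambda n: n.fitbit_tst,
        "ast": lambda n: n.fitbit_ast,
    }[variable]
    return [(xs(n), n.diff(variable)) for n in nights]
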