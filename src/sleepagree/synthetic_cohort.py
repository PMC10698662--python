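"""Synthetic cohort generator for device + diary + survey sleep streams.

Generates per-night ground truth (onset, offset, WASO), renders it as
device records (truth plus optional zero-mean jitter) and as diary
records (truth plus self-report biases, snapped to the 5-minute button
grid and heaped onto :00/:30), and keeps every draw in a
:class:`TruthLedger` so downstream stages can be tested for exact
recovery.

Randomness uses one seeded stream per generation run with per-participant
sub-streams derived from ``(rng_seed, participant_index)`` seed
sequences, so adding a participant never perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from datetime import date, datetime, time, timedelta
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core_time import ClockTime, SECONDS_PER_DAY, HALF_DAY
from .records_io import (
    ChatSleepRecord, FitbitSleepRecord, ParticipantProfile, PsqiRecord,
    write_chat, write_fitbit, write_profiles, write_psqi,
)

_INJECT_STREAM_KEY = 2_147_483_647  # distinct sub-stream for error injection


@dataclass
class CohortParams:
    """Generator knobs; defaults form the cohort-calibrated parameter set.

    Onset means are minutes relative to midnight (negative = before).
    Report biases follow the diary − device sign convention: a positive
    ``report_bias_good_min`` makes good-night diary sleep amounts run
    long relative to the device.
    """

    n_participants: int = 50
    nights_per_participant: int = 14
    start_date: date = date(2021, 3, 1)
    # Device-truth distributions (between participants, then night to night)
    fitbit_onset_mean_min: float = 19.7
    fitbit_onset_sd_min: float = 69.7
    onset_night_sd_min: float = 40.0
    fitbit_tst_mean_min: float = 427.97
    fitbit_tst_sd_min: float = 52.8
    tst_night_sd_min: float = 45.0
    waso_mean_min: float = 58.0
    waso_sd_min: float = 24.0
    sol_mean_min: float = 15.0
    device_noise_sd_min: float = 0.0
    # Self-report biases (diary minus device, minutes)
    report_bias_good_min: float = 19.2
    report_bias_poor_min: float = -2.5
    report_bias_sd_min: float = 45.9
    report_onset_bias_mean_min: float = 8.65
    report_onset_bias_sd_min: float = 29.6
    report_offset_bias_mean_min: float = -5.63
    report_offset_bias_sd_min: float = 29.1
    participant_bias_sd_min: float = 20.0
    # Response style
    heap_prob_30: float = 0.49
    qos_good_prob: float = 0.70
    qos_latent_strength: float = 1.0
    # Injected errors and missingness
    ampm_error_rate: float = 0.0
    order_error_rate: float = 0.0
    missing_chat_rate: float = 0.0
    missing_fitbit_rate: float = 0.0
    # Survey
    psqi_good_prob: float = 0.586
    psqi_missing_rate: float = 0.018
    rng_seed: int = 0

    def validate(self) -> None:
        probs = {
            "heap_prob_30": self.heap_prob_30,
            "qos_good_prob": self.qos_good_prob,
            "ampm_error_rate": self.ampm_error_rate,
            "order_error_rate": self.order_error_rate,
            "missing_chat_rate": self.missing_chat_rate,
            "missing_fitbit_rate": self.missing_fitbit_rate,
            "psqi_good_prob": self.psqi_good_prob,
            "psqi_missing_rate": self.psqi_missing_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {p}")
        for name, sd in (
            ("fitbit_onset_sd_min", self.fitbit_onset_sd_min),
            ("onset_night_sd_min", self.onset_night_sd_min),
            ("fitbit_tst_sd_min", self.fitbit_tst_sd_min),
            ("tst_night_sd_min", self.tst_night_sd_min),
            ("waso_sd_min", self.waso_sd_min),
            ("report_bias_sd_min", self.report_bias_sd_min),
            ("report_onset_bias_sd_min", self.report_onset_bias_sd_min),
            ("report_offset_bias_sd_min", self.report_offset_bias_sd_min),
            ("participant_bias_sd_min", self.participant_bias_sd_min),
            ("device_noise_sd_min", self.device_noise_sd_min),
        ):
            if sd < 0:
                raise ValueError(f"{name} must be >= 0, got {sd}")
        if self.nights_per_participant < 1:
            raise ValueError("nights_per_participant must be >= 1")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.fitbit_tst_mean_min <= self.waso_mean_min:
            raise ValueError("infeasible params: mean sleep span does not exceed mean WASO")


#: Ledger columns, one row per generated night.
LEDGER_COLUMNS = [
    "participant_id", "sleep_date", "true_onset_sec", "true_offset_sec",
    "true_tst_sec", "true_waso_min", "qos", "latent_quality", "psqi_score",
    "ast_bias_min", "onset_bias_min", "offset_bias_min",
    "chat_bed_sec", "chat_asleep_sec", "chat_wake_sec", "chat_ast_min",
    "fitbit_start", "fitbit_end", "fitbit_waso_min",
    "ampm_swap", "order_violation", "missing_chat", "missing_fitbit",
]


@dataclass
class TruthLedger:
    """Per-night ground truth and injected-error labels, one row per night."""

    frame: pd.DataFrame

    def row_index(self, participant_id: str, sleep_date: date) -> int:
        mask = (self.frame["participant_id"] == participant_id) & (
            self.frame["sleep_date"] == sleep_date.isoformat()
        )
        idx = np.flatnonzero(mask.to_numpy())
        if len(idx) != 1:
            raise KeyError(f"ledger must cover ({participant_id}, {sleep_date}) exactly once")
        return int(idx[0])


@dataclass
class CohortData:
    fitbit: list
    chat: list
    psqi: list
    profiles: list
    ledger: TruthLedger


def _snap5_minutes(minutes: float) -> int:
    """Nearest 5-minute grid value (half-grid ties round to even multiple via bankers on /5)."""
    return int(round(minutes / 5.0)) * 5


def _snap5_clock_sec(sec: float) -> int:
    return (int(round(sec / 300.0)) * 300) % SECONDS_PER_DAY


def _heap_minutes_within_hour(total_minutes: int) -> int:
    """Snap minute-of-hour to the nearest of :00/:30, ties toward the hour."""
    h, m = divmod(total_minutes, 60)
    candidates = (0, 30, 60)
    dists = [abs(m - c) for c in candidates]
    best = min(dists)
    # tie preference: an on-the-hour candidate wins
    choice = next(c for c, d in zip(candidates, dists) if d == best and c % 60 == 0) \
        if any(d == best and c % 60 == 0 for c, d in zip(candidates, dists)) \
        else next(c for c, d in zip(candidates, dists) if d == best)
    return h * 60 + choice


def _heap_clock_sec(sec: int) -> int:
    return (_heap_minutes_within_hour(sec // 60) * 60) % SECONDS_PER_DAY


def _clock_from_sec(sec: int) -> ClockTime:
    return ClockTime(int(sec) % SECONDS_PER_DAY)


def _night_datetime(sleep_date: date, clock_sec: int) -> datetime:
    """Attach a date: times from noon onward belong to the evening before."""
    d = sleep_date - timedelta(days=1) if clock_sec >= HALF_DAY else sleep_date
    return datetime.combine(d, time(clock_sec // 3600, (clock_sec // 60) % 60, clock_sec % 60))


def _qos_label(rng: np.random.Generator, good: bool) -> str:
    if good:
        return "very_good" if rng.random() < 0.3 else "quite_good"
    return "very_poor" if rng.random() < 0.3 else "quite_poor"


def generate_cohort(params: CohortParams) -> CohortData:
    """Generate the four record streams plus the ground-truth ledger.

    Deterministic given ``params.rng_seed``; regenerating with the same
    params yields byte-identical files from :func:`write_cohort`.
    """
    params.validate()
    logit = lambda p: np.log(p / (1 - p)) if 0 < p < 1 else (np.inf if p >= 1 else -np.inf)
    expit = lambda x: 1.0 / (1.0 + np.exp(-x))

    fitbit: list[FitbitSleepRecord] = []
    chat: list[ChatSleepRecord] = []
    psqi: list[PsqiRecord] = []
    profiles: list[ParticipantProfile] = []
    rows: list[dict] = []

    n_nights = params.nights_per_participant
    for i in range(params.n_participants):
        pid = f"P{i:04d}"
        rng = np.random.default_rng(np.random.SeedSequence([params.rng_seed, i]))
        u = rng.normal()  # latent sleep-quality trait
        onset_mu = params.fitbit_onset_mean_min + rng.normal(0, params.fitbit_onset_sd_min)
        tst_mu = max(240.0, params.fitbit_tst_mean_min + rng.normal(0, params.fitbit_tst_sd_min))
        intercept = rng.normal(0, params.participant_bias_sd_min)

        # survey + profile
        p_psqi_good = float(expit(logit(params.psqi_good_prob) + params.qos_latent_strength * u))
        psqi_good = rng.random() < p_psqi_good
        psqi_missing = rng.random() < params.psqi_missing_rate
        psqi_score = None if psqi_missing else int(rng.integers(0, 6) if psqi_good else rng.integers(6, 16))
        gender = "women" if rng.random() < 0.715 else "men"
        age = int(rng.integers(30, 60))
        bmi = float(np.clip(rng.normal(23.5, 3.3), 16.0, 40.0))
        profiles.append(ParticipantProfile(pid, gender, age, round(bmi, 1)))

        bed_sec_survey = _snap5_clock_sec((onset_mu - params.sol_mean_min) * 60 % SECONDS_PER_DAY)
        wake_sec_survey = _snap5_clock_sec((onset_mu + tst_mu) * 60 % SECONDS_PER_DAY)
        if rng.random() < params.heap_prob_30:
            bed_sec_survey = _heap_clock_sec(bed_sec_survey)
        if rng.random() < params.heap_prob_30:
            wake_sec_survey = _heap_clock_sec(wake_sec_survey)
        psqi.append(PsqiRecord(
            participant_id=pid,
            bed_time=_clock_from_sec(bed_sec_survey),
            sol_minutes=_snap5_minutes(max(0.0, rng.normal(params.sol_mean_min, 10.0))),
            wake_time=_clock_from_sec(wake_sec_survey),
            reported_sleep_h=round((tst_mu - params.waso_mean_min) / 60 * 2) / 2,
            total_score=psqi_score,
        ))

        # nightly truth
        onset_min = onset_mu + rng.normal(0, params.onset_night_sd_min, n_nights)
        tst_min = np.clip(tst_mu + rng.normal(0, params.tst_night_sd_min, n_nights), 60.0, 1200.0)
        # keep sleep offset before mid-morning so anchored (noon-to-noon)
        # ordering holds even after report bias and heaping
        onset_min = np.clip(onset_min, -400.0, 600.0 - tst_min)
        waso_min = np.clip(rng.normal(params.waso_mean_min, params.waso_sd_min, n_nights), 0.0, None)
        waso_min = np.minimum(waso_min, tst_min - 1.0)
        p_qos_good = float(expit(logit(params.qos_good_prob) + params.qos_latent_strength * u))
        qos_good = rng.random(n_nights) < p_qos_good
        ast_bias = np.where(qos_good, params.report_bias_good_min, params.report_bias_poor_min) \
            + intercept + rng.normal(0, params.report_bias_sd_min, n_nights)
        onset_bias = rng.normal(params.report_onset_bias_mean_min, params.report_onset_bias_sd_min, n_nights)
        offset_bias = rng.normal(params.report_offset_bias_mean_min, params.report_offset_bias_sd_min, n_nights)
        sol = np.clip(rng.normal(params.sol_mean_min, 10.0, n_nights), 0.0, 120.0)
        dev_noise_on = rng.normal(0, params.device_noise_sd_min, n_nights) if params.device_noise_sd_min else np.zeros(n_nights)
        dev_noise_off = rng.normal(0, params.device_noise_sd_min, n_nights) if params.device_noise_sd_min else np.zeros(n_nights)
        miss_chat = rng.random(n_nights) < params.missing_chat_rate
        miss_fitbit = rng.random(n_nights) < params.missing_fitbit_rate
        heap_draws = rng.random((n_nights, 4)) < params.heap_prob_30
        latency_sec = rng.exponential(3 * 3600, n_nights)
        n_awak = np.maximum(1, rng.poisson(2.0, n_nights))
        strenuous = rng.random(n_nights) < 0.3
        sitting = np.clip(rng.normal(420, 120, n_nights), 0, None).astype(int)
        qos_labels = [_qos_label(rng, bool(g)) for g in qos_good]

        for k in range(n_nights):
            sleep_date = params.start_date + timedelta(days=k)
            true_onset_sec = int(round(onset_min[k] * 60)) % SECONDS_PER_DAY
            true_tst_sec = int(round(tst_min[k] * 60))
            true_offset_sec = (true_onset_sec + true_tst_sec) % SECONDS_PER_DAY
            true_waso_min = float(waso_min[k])

            # device rendering
            start_dt = _night_datetime(sleep_date, true_onset_sec) + timedelta(seconds=round(dev_noise_on[k] * 60))
            end_dt = start_dt + timedelta(seconds=true_tst_sec + round((dev_noise_off[k] - dev_noise_on[k]) * 60))
            fb_waso = int(round(true_waso_min))
            fb_waso = min(fb_waso, int((end_dt - start_dt).total_seconds() // 60) - 1)
            fb_waso = max(fb_waso, 0)

            # diary rendering: truth + bias, snapped to 5-min grid, then heaped
            asleep_raw = true_onset_sec + onset_bias[k] * 60
            wake_raw = true_offset_sec + offset_bias[k] * 60
            bed_raw = asleep_raw - sol[k] * 60
            bed_sec = _snap5_clock_sec(bed_raw)
            asleep_sec = _snap5_clock_sec(asleep_raw)
            wake_sec = _snap5_clock_sec(wake_raw)
            ast_m = max(5, _snap5_minutes(tst_min[k] - true_waso_min + ast_bias[k]))
            if heap_draws[k, 0]:
                bed_sec = _heap_clock_sec(bed_sec)
            if heap_draws[k, 1]:
                asleep_sec = _heap_clock_sec(asleep_sec)
            if heap_draws[k, 2]:
                wake_sec = _heap_clock_sec(wake_sec)
            if heap_draws[k, 3]:
                ast_m = _heap_minutes_within_hour(ast_m)
            # keep the diary internally ordered; injections break order on purpose later
            if (bed_sec - asleep_sec) % SECONDS_PER_DAY < HALF_DAY and bed_sec != asleep_sec:
                bed_sec = asleep_sec
            span = (wake_sec - asleep_sec) % SECONDS_PER_DAY
            if span == 0 or span > 18 * 3600:
                wake_sec = (asleep_sec + true_tst_sec) % SECONDS_PER_DAY

            if not miss_fitbit[k]:
                fitbit.append(FitbitSleepRecord(pid, start_dt, end_dt, fb_waso, True))
            if not miss_chat[k]:
                prompt = datetime.combine(sleep_date, time(9, 0))
                chat.append(ChatSleepRecord(
                    participant_id=pid, sleep_date=sleep_date,
                    bed_time=_clock_from_sec(bed_sec),
                    asleep_time=_clock_from_sec(asleep_sec),
                    wake_time=_clock_from_sec(wake_sec),
                    n_awakenings=int(n_awak[k]), ast_minutes=int(ast_m),
                    qos=qos_labels[k], strenuous_activity=bool(strenuous[k]),
                    sitting_minutes=int(sitting[k]), prompt_ts=prompt,
                    response_ts=prompt + timedelta(seconds=int(latency_sec[k])),
                ))
            rows.append({
                "participant_id": pid, "sleep_date": sleep_date.isoformat(),
                "true_onset_sec": true_onset_sec, "true_offset_sec": true_offset_sec,
                "true_tst_sec": true_tst_sec, "true_waso_min": true_waso_min,
                "qos": qos_labels[k], "latent_quality": float(u),
                "psqi_score": np.nan if psqi_score is None else psqi_score,
                "ast_bias_min": float(ast_bias[k]),
                "onset_bias_min": float(onset_bias[k]),
                "offset_bias_min": float(offset_bias[k]),
                "chat_bed_sec": int(bed_sec), "chat_asleep_sec": int(asleep_sec),
                "chat_wake_sec": int(wake_sec), "chat_ast_min": int(ast_m),
                "fitbit_start": start_dt.isoformat(), "fitbit_end": end_dt.isoformat(),
                "fitbit_waso_min": fb_waso,
                "ampm_swap": False, "order_violation": False,
                "missing_chat": bool(miss_chat[k]), "missing_fitbit": bool(miss_fitbit[k]),
            })

    ledger = TruthLedger(pd.DataFrame(rows, columns=LEDGER_COLUMNS))
    data = CohortData(fitbit, chat, psqi, profiles, ledger)
    if params.ampm_error_rate > 0 or params.order_error_rate > 0:
        data.chat = inject_errors(data.chat, params, ledger)
    return data


def inject_errors(chat_records: list, params: CohortParams, ledger: TruthLedger) -> list:
    """Inject AM/PM swaps and ordering violations into diary records.

    With probability ``ampm_error_rate`` the bed and fall-asleep times
    are shifted 12 h (an after-midnight onset entered on the wrong half
    of the dial survives the order check and is caught only against the
    device clock; a before-midnight one trips the order check first —
    either way the night is excluded).  With probability
    ``order_error_rate`` the fall-asleep and wake fields are swapped so
    the bed -> asleep -> wake order breaks.  Every injection is flagged
    in the ledger.
    """
    rng = np.random.default_rng(np.random.SeedSequence([params.rng_seed, _INJECT_STREAM_KEY]))
    out = []
    frame = ledger.frame
    for rec in chat_records:
        draw_ampm = rng.random() < params.ampm_error_rate
        draw_order = rng.random() < params.order_error_rate
        if not (draw_ampm or draw_order):
            out.append(rec)
            continue
        idx = ledger.row_index(rec.participant_id, rec.sleep_date)
        new = rec
        if draw_ampm:
            new = replace(new,
                          bed_time=new.bed_time.shifted(HALF_DAY),
                          asleep_time=new.asleep_time.shifted(HALF_DAY))
            frame.loc[idx, "ampm_swap"] = True
        if draw_order:
            new = replace(new, asleep_time=new.wake_time, wake_time=new.asleep_time)
            frame.loc[idx, "order_violation"] = True
        out.append(new)
    return out


def write_cohort(data: CohortData, outdir: str | Path, fitbit_format: str = "csv") -> dict:
    """Write the generated streams in the formats the readers accept."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fitbit": outdir / ("fitbit.json" if fitbit_format == "json" else "fitbit.csv"),
        "chat": outdir / "chat.csv",
        "psqi": outdir / "psqi.csv",
        "profiles": outdir / "profiles.csv",
        "ledger": outdir / "truth_ledger.csv",
    }
    write_fitbit(data.fitbit, paths["fitbit"])
    write_chat(data.chat, paths["chat"])
    write_psqi(data.psqi, paths["psqi"])
    write_profiles(data.profiles, paths["profiles"])
    data.ledger.frame.to_csv(paths["ledger"], index=False)
    return {k: str(v) for k, v in paths.items()}
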