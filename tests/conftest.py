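from datetime import date, datetime, time, timedelta

import pytest

from sleepagree.core_time import ClockTime
from sleepagree.records_io import ChatSleepRecord, FitbitSleepRecord


def make_fitbit(pid="P0001", sleep_date=date(2021, 3, 2), start="23:50:00",
                end="07:10:00", minutes_awake=55, is_main_sleep=True):
    """Device record whose sleep ends on *sleep_date*."""
    sh, sm, ss = (int(x) for x in start.split(":"))
    eh, em, es = (int(x) for x in end.split(":"))
    start_date = sleep_date - timedelta(days=1) if sh >= 12 else sleep_date
    return FitbitSleepRecord(
        participant_id=pid,
        start=datetime.combine(start_date, time(sh, sm, ss)),
        end=datetime.combine(sleep_date, time(eh, em, es)),
        minutes_awake=minutes_awake,
        is_main_sleep=is_main_sleep,
    )


def make_chat(pid="P0001", sleep_date=date(2021, 3, 2), bed="23:30", asleep="23:45",
              wake="07:00", n_awakenings=2, ast_minutes=420, qos="quite_good",
              latency_hours=2.0):
    def clock(txt):
        h, m = (int(x) for x in txt.split(":"))
        return ClockTime.from_hms(h % 24, m)
    prompt = datetime.combine(sleep_date, time(9, 0))
    return ChatSleepRecord(
        participant_id=pid,
        sleep_date=sleep_date,
        bed_time=clock(bed),
        asleep_time=clock(asleep),
        wake_time=clock(wake),
        n_awakenings=n_awakenings,
        ast_minutes=ast_minutes,
        qos=qos,
        strenuous_activity=False,
        sitting_minutes=400,
        prompt_ts=prompt,
        response_ts=prompt + timedelta(hours=latency_hours),
    )


@pytest.fixture
def fitbit_record():
    return make_fitbit()


@pytest.fixture
def chat_record():
    return make_chat()
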