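import datetime as dt

import pytest

from periprompt import (
    EngineConfig,
    MinuteSample,
    ParticipantInfo,
    SymptomReport,
    SYMPTOM_DIMENSIONS,
    WakeWindow,
)

DAY = dt.date(2021, 5, 1)
WAKE = dt.time(8, 0)
BED = dt.time(20, 0)  # 12-hour waking day


@pytest.fixture
def cfg() -> EngineConfig:
    return EngineConfig()


@pytest.fixture
def window() -> WakeWindow:
    return WakeWindow("P1", WAKE, BED, dt.date.min)


@pytest.fixture
def info() -> ParticipantInfo:
    return ParticipantInfo(
        participant_id="P1",
        arm="intervention",
        surgery_date=DAY + dt.timedelta(days=7),
        discharge_date=DAY + dt.timedelta(days=17),
        wake_time=WAKE,
        bed_time=BED,
    )


def day_stream(step_values, day: dt.date = DAY, start: dt.time = WAKE, pid: str = "P1"):
    """Minute samples starting at ``start`` on ``day``, one per step value."""
    t0 = dt.datetime.combine(day, start)
    return [
        MinuteSample(pid, t0 + dt.timedelta(minutes=i), int(s), True)
        for i, s in enumerate(step_values)
    ]


def report(max_severity: int, t: dt.datetime | None = None, pid: str = "P1"):
    """A report whose worst dimension equals ``max_severity`` (rest zero)."""
    sev = {name: 0 for name in SYMPTOM_DIMENSIONS}
    sev["pain"] = max_severity
    return SymptomReport(pid, t or dt.datetime.combine(DAY, dt.time(7, 0)), sev)
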