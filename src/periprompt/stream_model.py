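"""Domain types, invariant checking, and CSV I/O for perioperative activity streams.

Everything downstream (the prompting engine, the adherence/bout metrics, the
cohort simulator) speaks in the types defined here: minute-level step samples,
daily symptom reports, wake windows, device-detected sleep episodes, emitted
prompt events, and per-day summaries.

Conventions
-----------
* Timestamps are timezone-naive local time at minute resolution (seconds and
  finer are rejected); one sample per participant-minute.
* Missing minutes (no row) are legal in the stream; how they are interpreted
  (usually: zero steps, hence sedentary) is a downstream policy.
* The surgery day and the discharge day both belong to the inpatient phase.
"""

from __future__ import annotations

import datetime as dt
import enum
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "SYMPTOM_DIMENSIONS",
    "ValidationError",
    "MinuteSample",
    "SymptomReport",
    "WakeWindow",
    "SleepEpisode",
    "EngineConfig",
    "PromptEvent",
    "Phase",
    "Bout",
    "DailySummary",
    "ParticipantInfo",
    "assign_phase",
    "window_minutes",
    "read_minute_stream",
    "write_minute_stream",
    "read_symptom_reports",
    "write_symptom_reports",
    "read_sleep_episodes",
    "write_sleep_episodes",
    "read_events",
    "write_events",
    "read_participants",
    "write_participants",
]

#: The ten daily symptom dimensions, each rated 0 (not present) to 10
#: (as bad as you can imagine), in canonical CSV column order.
SYMPTOM_DIMENSIONS: tuple[str, ...] = (
    "pain",
    "fatigue",
    "sleep",
    "concentration",
    "sadness",
    "anxiety",
    "dyspnea",
    "numbness",
    "nausea",
    "bowel",
)


class ValidationError(ValueError):
    """An input violated a domain invariant."""


def _check_minute(t: dt.datetime, what: str = "timestamp") -> dt.datetime:
    if not isinstance(t, dt.datetime):
        raise ValidationError(f"{what} must be a datetime, got {type(t).__name__}")
    if t.tzinfo is not None:
        raise ValidationError(f"{what} must be timezone-naive")
    if t.second != 0 or t.microsecond != 0:
        raise ValidationError(f"{what} must be minute-resolution, got {t!r}")
    return t


@dataclass(frozen=True)
class MinuteSample:
    """One participant-minute: step count plus a worn flag."""

    participant_id: str
    t: dt.datetime
    steps: int
    worn: bool

    def __post_init__(self) -> None:
        _check_minute(self.t)
        if self.steps < 0:
            raise ValidationError(f"steps must be >= 0, got {self.steps}")


@dataclass(frozen=True)
class SymptomReport:
    """A timestamped vector of the ten symptom severities (0-10 each)."""

    participant_id: str
    t: dt.datetime
    severities: Mapping[str, int]

    def __post_init__(self) -> None:
        _check_minute(self.t)
        keys = tuple(self.severities)
        if set(keys) != set(SYMPTOM_DIMENSIONS):
            raise ValidationError(
                f"severities must cover exactly {SYMPTOM_DIMENSIONS}, got {keys}"
            )
        for name, value in self.severities.items():
            if not (0 <= int(value) <= 10):
                raise ValidationError(f"severity {name}={value} outside [0, 10]")

    @property
    def max_severity(self) -> int:
        return max(int(v) for v in self.severities.values())


@dataclass(frozen=True)
class WakeWindow:
    """A participant's waking interval, effective from a given date.

    ``bed_time < wake_time`` is legal and means the window crosses midnight.
    Prompts may only be delivered inside this window.
    """

    participant_id: str
    wake_time: dt.time
    bed_time: dt.time
    effective_from: dt.date

    def __post_init__(self) -> None:
        if self.wake_time == self.bed_time:
            raise ValidationError("wake_time and bed_time must differ")

    def bounds(self, day: dt.date) -> tuple[dt.datetime, dt.datetime]:
        """Half-open [wake, bed) datetimes of the waking day anchored at ``day``."""
        start = dt.datetime.combine(day, self.wake_time)
        end = dt.datetime.combine(day, self.bed_time)
        if end <= start:  # crosses midnight
            end += dt.timedelta(days=1)
        return start, end


def window_minutes(window: WakeWindow, day: dt.date) -> int:
    """Number of waking minutes on ``day`` under ``window``."""
    start, end = window.bounds(day)
    return int((end - start).total_seconds() // 60)


@dataclass(frozen=True)
class SleepEpisode:
    """A device-detected sleep interval [start, end); excluded from SB bouts."""

    participant_id: str
    start: dt.datetime
    end: dt.datetime

    def __post_init__(self) -> None:
        _check_minute(self.start, "start")
        _check_minute(self.end, "end")
        if self.end <= self.start:
            raise ValidationError("sleep episode end must be after start")


@dataclass(frozen=True)
class EngineConfig:
    """Tunable policy of the prompting engine.

    Defaults replicate the delivered smartwatch app: a minute with fewer than
    10 steps counts as sedentary; the prompt threshold is 60 consecutive
    sedentary minutes when all symptoms were rated below 7/10 and 120 minutes
    when any symptom was rated 7 or higher (also the conservative default when
    no rating exists); a prompt counts as responded to when 30 or more steps
    are logged within the 15 minutes after it, which triggers feedback.
    """

    sedentary_step_cut: int = 10
    low_threshold: int = 60
    high_threshold: int = 120
    severity_cut: int = 7
    response_window: int = 15
    response_step_goal: int = 30
    default_threshold_when_unrated: int = 120
    prompt_text: str = "Ready for a short walk?"
    feedback_text: str = "Great job being active!"

    def __post_init__(self) -> None:
        if not (0 < self.low_threshold <= self.high_threshold):
            raise ValidationError("need 0 < low_threshold <= high_threshold")
        if self.response_window < 1:
            raise ValidationError("response_window must be >= 1")
        if not (1 <= self.severity_cut <= 10):
            raise ValidationError("severity_cut must be in [1, 10]")
        if self.sedentary_step_cut < 1:
            raise ValidationError("sedentary_step_cut must be >= 1")
        if self.default_threshold_when_unrated not in (
            self.low_threshold,
            self.high_threshold,
        ):
            raise ValidationError(
                "default_threshold_when_unrated must equal low or high threshold"
            )


@dataclass(frozen=True)
class PromptEvent:
    """An emitted activity prompt and the outcome of its response window."""

    participant_id: str
    t: dt.datetime
    threshold_used: int
    responded: bool
    response_steps: int
    feedback_sent: bool

    def __post_init__(self) -> None:
        _check_minute(self.t)
        if self.threshold_used < 1:
            raise ValidationError("threshold_used must be >= 1")
        if self.response_steps < 0:
            raise ValidationError("response_steps must be >= 0")
        if self.feedback_sent and not self.responded:
            raise ValidationError("feedback_sent requires responded")


class Phase(enum.Enum):
    """The three perioperative phases; every study day maps to exactly one."""

    PREOPERATIVE = "preoperative"
    INPATIENT = "inpatient"
    POSTDISCHARGE = "postdischarge"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def assign_phase(
    t: dt.datetime | dt.date,
    surgery_date: dt.date,
    discharge_date: dt.date,
) -> Phase:
    """Map a timestamp or date to its perioperative phase.

    Days strictly before surgery are preoperative; the surgery day through the
    discharge day inclusive are inpatient; later days are postdischarge.
    """
    if discharge_date < surgery_date:
        raise ValidationError("discharge_date before surgery_date")
    day = t.date() if isinstance(t, dt.datetime) else t
    if day < surgery_date:
        return Phase.PREOPERATIVE
    if day <= discharge_date:
        return Phase.INPATIENT
    return Phase.POSTDISCHARGE


@dataclass(frozen=True)
class Bout:
    """A maximal run of consecutive sedentary minutes within the waking day."""

    start: dt.datetime
    duration: int

    def __post_init__(self) -> None:
        _check_minute(self.start, "start")
        if self.duration < 1:
            raise ValidationError("bout duration must be >= 1 minute")


@dataclass
class DailySummary:
    """Per participant-day wear, steps, bouts, prompts, and inclusion flags."""

    participant_id: str
    date: dt.date
    phase: Phase
    wear_minutes: int
    total_steps: int
    bouts: list[Bout]
    max_bout: int
    mean_bout: float
    n_prompts: int
    n_responses: int
    symptom_reported: bool
    included: bool
    min_wear_minutes: int = 480  # the 8-hour wear filter, configurable

    def __post_init__(self) -> None:
        if self.included != (self.wear_minutes >= self.min_wear_minutes):
            raise ValidationError(
                f"included must equal (wear_minutes >= {self.min_wear_minutes})"
            )
        if self.bouts:
            if self.max_bout < self.mean_bout:
                raise ValidationError("max_bout must be >= mean_bout")
        elif self.max_bout != 0 or self.mean_bout != 0:
            raise ValidationError("empty bout list requires max_bout = mean_bout = 0")
        if self.n_responses > self.n_prompts:
            raise ValidationError("n_responses cannot exceed n_prompts")


@dataclass(frozen=True)
class ParticipantInfo:
    """Randomization arm, surgery/discharge dates, and default wake window."""

    participant_id: str
    arm: str  # "intervention" | "monitoring"
    surgery_date: dt.date
    discharge_date: dt.date
    wake_time: dt.time
    bed_time: dt.time

    def __post_init__(self) -> None:
        if self.arm not in ("intervention", "monitoring"):
            raise ValidationError(f"unknown arm {self.arm!r}")
        if self.discharge_date < self.surgery_date:
            raise ValidationError("discharge_date before surgery_date")
        if self.wake_time == self.bed_time:
            raise ValidationError("wake_time and bed_time must differ")

    def wake_window(self) -> WakeWindow:
        return WakeWindow(
            participant_id=self.participant_id,
            wake_time=self.wake_time,
            bed_time=self.bed_time,
            effective_from=dt.date.min,
        )


# ---------------------------------------------------------------------------
# CSV readers / writers
# ---------------------------------------------------------------------------

_MINUTE_COLUMNS = ["participant_id", "timestamp", "steps", "worn"]
_EVENT_COLUMNS = [
    "participant_id",
    "timestamp",
    "threshold_used",
    "responded",
    "response_steps",
    "feedback_sent",
]


def _parse_minute_ts(values: pd.Series, path: Path) -> pd.Series:
    parsed = pd.to_datetime(values, format="ISO8601", errors="coerce")
    bad = parsed.isna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
        raise ValidationError(f"{path}:{line}: unparseable timestamp {values[bad.idxmax()]!r}")
    if ((parsed.dt.second != 0) | (parsed.dt.microsecond != 0)).any():
        raise ValidationError(f"{path}: timestamps must be minute-resolution")
    return parsed


def _read_csv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"participant_id": str})
    except pd.errors.ParserError as exc:  # carries the offending line number
        raise ValidationError(f"{path}: malformed CSV: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    return df


def read_minute_stream(path: str | Path) -> list[MinuteSample]:
    """Read a minute-level step stream CSV.

    Returns samples sorted by (participant, timestamp). Negative steps and
    duplicate participant-minutes are rejected.
    """
    path = Path(path)
    df = _read_csv(path, _MINUTE_COLUMNS)
    if df.empty:
        return []
    df = df.reset_index(drop=True)
    ts = _parse_minute_ts(df["timestamp"], path)
    steps = pd.to_numeric(df["steps"], errors="coerce")
    if steps.isna().any():
        line = int(steps.isna().idxmax()) + 2
        raise ValidationError(f"{path}:{line}: non-numeric step count")
    if (steps < 0).any():
        line = int((steps < 0).idxmax()) + 2
        raise ValidationError(f"{path}:{line}: negative step count")
    worn = df["worn"].map(_parse_bool)
    df = pd.DataFrame(
        {"participant_id": df["participant_id"], "t": ts, "steps": steps.astype(int), "worn": worn}
    ).sort_values(["participant_id", "t"], kind="stable")
    dup = df.duplicated(["participant_id", "t"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate sample for {row.participant_id} at {row.t}"
        )
    return [
        MinuteSample(r.participant_id, r.t.to_pydatetime(), int(r.steps), bool(r.worn))
        for r in df.itertuples(index=False)
    ]


def _parse_bool(v: object) -> bool:
    if isinstance(v, bool):
        return v
    s = str(v).strip().lower()
    if s in ("true", "1", "t", "yes"):
        return True
    if s in ("false", "0", "f", "no"):
        return False
    raise ValidationError(f"cannot parse boolean {v!r}")


def write_minute_stream(samples: Iterable[MinuteSample], path: str | Path) -> None:
    rows = [
        (s.participant_id, s.t.isoformat(timespec="minutes"), s.steps, s.worn)
        for s in samples
    ]
    pd.DataFrame(rows, columns=_MINUTE_COLUMNS).to_csv(path, index=False)


def read_symptom_reports(path: str | Path) -> list[SymptomReport]:
    path = Path(path)
    df = _read_csv(path, ["participant_id", "timestamp", *SYMPTOM_DIMENSIONS])
    if df.empty:
        return []
    ts = _parse_minute_ts(df["timestamp"], path)
    out = []
    for i, row in df.iterrows():
        out.append(
            SymptomReport(
                participant_id=row["participant_id"],
                t=ts[i].to_pydatetime(),
                severities={k: int(row[k]) for k in SYMPTOM_DIMENSIONS},
            )
        )
    out.sort(key=lambda r: (r.participant_id, r.t))
    return out


def write_symptom_reports(reports: Iterable[SymptomReport], path: str | Path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "timestamp": r.t.isoformat(timespec="minutes"),
            **{k: int(r.severities[k]) for k in SYMPTOM_DIMENSIONS},
        }
        for r in reports
    ]
    pd.DataFrame(rows, columns=["participant_id", "timestamp", *SYMPTOM_DIMENSIONS]).to_csv(
        path, index=False
    )


def read_sleep_episodes(path: str | Path) -> list[SleepEpisode]:
    path = Path(path)
    df = _read_csv(path, ["participant_id", "start", "end"])
    if df.empty:
        return []
    start = _parse_minute_ts(df["start"], path)
    end = _parse_minute_ts(df["end"], path)
    episodes = [
        SleepEpisode(pid, s.to_pydatetime(), e.to_pydatetime())
        for pid, s, e in zip(df["participant_id"], start, end)
    ]
    episodes.sort(key=lambda e: (e.participant_id, e.start))
    _check_no_overlap(episodes)
    return episodes


def _check_no_overlap(episodes: Sequence[SleepEpisode]) -> None:
    for prev, cur in zip(episodes, episodes[1:]):
        if cur.participant_id == prev.participant_id and cur.start < prev.end:
            raise ValidationError(
                f"overlapping sleep episodes for {cur.participant_id} at {cur.start}"
            )


def write_sleep_episodes(episodes: Iterable[SleepEpisode], path: str | Path) -> None:
    rows = [
        (
            e.participant_id,
            e.start.isoformat(timespec="minutes"),
            e.end.isoformat(timespec="minutes"),
        )
        for e in episodes
    ]
    pd.DataFrame(rows, columns=["participant_id", "start", "end"]).to_csv(path, index=False)


def write_events(events: Iterable[PromptEvent], path: str | Path) -> None:
    """Write prompt events with a stable column order; round-trip safe."""
    rows = [
        (
            e.participant_id,
            e.t.isoformat(timespec="minutes"),
            e.threshold_used,
            e.responded,
            e.response_steps,
            e.feedback_sent,
        )
        for e in events
    ]
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path: str | Path) -> list[PromptEvent]:
    path = Path(path)
    df = _read_csv(path, _EVENT_COLUMNS)
    if df.empty:
        return []
    ts = _parse_minute_ts(df["timestamp"], path)
    return [
        PromptEvent(
            participant_id=row["participant_id"],
            t=ts[i].to_pydatetime(),
            threshold_used=int(row["threshold_used"]),
            responded=_parse_bool(row["responded"]),
            response_steps=int(row["response_steps"]),
            feedback_sent=_parse_bool(row["feedback_sent"]),
        )
        for i, row in df.iterrows()
    ]


def write_participants(infos: Iterable[ParticipantInfo], path: str | Path) -> None:
    payload = {
        info.participant_id: {
            "arm": info.arm,
            "surgery_date": info.surgery_date.isoformat(),
            "discharge_date": info.discharge_date.isoformat(),
            "wake_time": info.wake_time.isoformat(timespec="minutes"),
            "bed_time": info.bed_time.isoformat(timespec="minutes"),
        }
        for info in infos
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def read_participants(path: str | Path) -> list[ParticipantInfo]:
    payload = yaml.safe_load(Path(path).read_text())
    if not isinstance(payload, dict):
        raise ValidationError(f"{path}: participants file must be a mapping")
    infos = []
    for pid, spec in sorted(payload.items()):
        try:
            infos.append(
                ParticipantInfo(
                    participant_id=str(pid),
                    arm=spec["arm"],
                    surgery_date=dt.date.fromisoformat(spec["surgery_date"]),
                    discharge_date=dt.date.fromisoformat(spec["discharge_date"]),
                    wake_time=dt.time.fromisoformat(spec["wake_time"]),
                    bed_time=dt.time.fromisoformat(spec["bed_time"]),
                )
            )
        except KeyError as exc:
            raise ValidationError(f"{path}: participant {pid} missing field {exc}") from exc
    return infos
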