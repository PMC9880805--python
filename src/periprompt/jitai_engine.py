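"""Real-time sedentary-behavior prompting engine.

Replicates the smartwatch app as a deterministic per-minute state machine:

1. classify each minute as sedentary (fewer than ``sedentary_step_cut`` steps)
   or active;
2. accumulate consecutive sedentary minutes inside the wake window, resetting
   on any active minute, on prompt emission, and at the wake-window open;
3. pick the bout threshold from the most recent symptom report (low threshold
   when all ten severities are below the cut, high threshold when any reaches
   it, and the conservative default when no report exists), re-evaluated every
   minute;
4. emit a prompt the minute the accumulator reaches the active threshold, then
   tally steps over the following response window and mark the prompt
   responded (and feedback sent) when the step goal is met.

Missing minutes inside the wake window are treated as zero-step (sedentary)
minutes: that is what the on-wrist app observes when the device is idle or
not worn. Accumulation does not pause during a response window, and a
threshold change never resets the accumulator.
"""

from __future__ import annotations

import datetime as dt
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .stream_model import (
    EngineConfig,
    MinuteSample,
    ParticipantInfo,
    PromptEvent,
    SleepEpisode,
    SymptomReport,
    ValidationError,
    WakeWindow,
)

__all__ = [
    "EngineState",
    "ParticipantTimeline",
    "classify_minute",
    "current_threshold",
    "step_engine",
    "run_participant",
]


_EPOCH = dt.datetime(1970, 1, 1)


def _epoch_minute(t: dt.datetime) -> int:
    """Minutes since the naive 1970 epoch; matches numpy datetime64[m]."""
    return (t - _EPOCH) // dt.timedelta(minutes=1)


@dataclass
class EngineState:
    """Snapshot of the state machine after a day has been processed."""

    sedentary_accumulator: int
    active_threshold: int
    last_symptom_report: SymptomReport | None
    open_response_windows: list[tuple[dt.datetime, int]] = field(default_factory=list)
    emitted: list[PromptEvent] = field(default_factory=list)


@dataclass
class ParticipantTimeline:
    """All streams for one participant: minutes, reports, sleep, windows."""

    info: ParticipantInfo
    minutes: pd.DataFrame  # columns: t (datetime64[m]), steps, worn
    reports: list[SymptomReport]
    sleep: list[SleepEpisode]
    windows: list[WakeWindow]

    def __post_init__(self) -> None:
        if not self.windows:
            raise ValidationError("timeline needs at least one wake window")
        self.reports = sorted(self.reports, key=lambda r: r.t)
        self.windows = sorted(self.windows, key=lambda w: w.effective_from)
        if not self.minutes.empty:
            t = self.minutes["t"].values.astype("datetime64[m]").astype(np.int64)
            if np.any(np.diff(t) <= 0):
                raise ValidationError(
                    "minute stream must be strictly increasing (overlapping or "
                    "duplicate participant-minutes)"
                )

    @classmethod
    def from_samples(
        cls,
        info: ParticipantInfo,
        samples: Sequence[MinuteSample],
        reports: Sequence[SymptomReport],
        sleep: Sequence[SleepEpisode] = (),
        windows: Sequence[WakeWindow] | None = None,
    ) -> "ParticipantTimeline":
        minutes = pd.DataFrame(
            {
                "t": pd.to_datetime([s.t for s in samples]),
                "steps": np.asarray([s.steps for s in samples], dtype=np.int64),
                "worn": np.asarray([s.worn for s in samples], dtype=bool),
            }
        ).sort_values("t", kind="stable", ignore_index=True)
        return cls(
            info=info,
            minutes=minutes,
            reports=list(reports),
            sleep=list(sleep),
            windows=list(windows) if windows is not None else [info.wake_window()],
        )

    def window_for(self, day: dt.date) -> WakeWindow:
        """Wake window in effect on ``day`` (latest effective_from <= day)."""
        chosen = self.windows[0]
        for w in self.windows:
            if w.effective_from <= day:
                chosen = w
        return chosen

    def dates(self) -> list[dt.date]:
        if self.minutes.empty:
            return []
        first = self.minutes["t"].iloc[0].date()
        last = self.minutes["t"].iloc[-1].date()
        return [first + dt.timedelta(days=i) for i in range((last - first).days + 1)]


def classify_minute(steps: int, cfg: EngineConfig) -> str:
    """Classify one minute as ``"sedentary"`` or ``"active"``."""
    if steps < 0:
        raise ValidationError(f"steps must be >= 0, got {steps}")
    return "sedentary" if steps < cfg.sedentary_step_cut else "active"


def current_threshold(report: SymptomReport | None, cfg: EngineConfig) -> int:
    """Bout threshold implied by the most recent symptom report.

    All severities below the cut select the low (more frequent) threshold;
    any severity at or above it selects the high threshold; with no report the
    configured default applies.
    """
    if report is None:
        return cfg.default_threshold_when_unrated
    if report.max_severity >= cfg.severity_cut:
        return cfg.high_threshold
    return cfg.low_threshold


def _threshold_schedule(
    reports: Sequence[SymptomReport],
    start_minute: int,
    n_minutes: int,
    cfg: EngineConfig,
) -> np.ndarray:
    """Per-minute threshold over ``n_minutes`` starting at epoch-minute ``start_minute``.

    ``reports`` must be sorted by time; the latest report at or before each
    minute governs, and reports carry forward indefinitely across days.
    """
    out = np.empty(n_minutes, dtype=np.int64)
    report_minutes = [_epoch_minute(r.t) for r in reports]
    # value in force entering the window
    idx = bisect_right(report_minutes, start_minute) - 1
    current = current_threshold(reports[idx] if idx >= 0 else None, cfg)
    pos = 0
    for j in range(idx + 1, len(reports)):
        arrival = report_minutes[j] - start_minute
        if arrival >= n_minutes:
            break
        arrival = max(arrival, 0)
        out[pos:arrival] = current
        current = current_threshold(reports[j], cfg)
        pos = arrival
    out[pos:] = current
    return out


def _run_window(
    steps: np.ndarray,
    thresholds: np.ndarray,
    cfg: EngineConfig,
    on_prompt: Callable[[int, np.ndarray], None] | None = None,
) -> tuple[list[int], int]:
    """Core per-minute loop over one waking day.

    ``steps`` covers the W waking minutes plus a ``response_window`` tail (the
    tail can satisfy responses but never hosts a prompt); ``thresholds`` has
    length W. Returns prompt minute offsets and the final accumulator.
    ``on_prompt`` may mutate future entries of ``steps`` (engine-in-the-loop
    simulation of a participant walking after a prompt).
    """
    n = len(thresholds)
    cut = cfg.sedentary_step_cut
    acc = 0
    prompts: list[int] = []
    step_list = steps  # local alias; may be mutated by on_prompt
    for i in range(n):
        if step_list[i] < cut:
            acc += 1
            if acc >= thresholds[i]:
                prompts.append(i)
                if on_prompt is not None:
                    on_prompt(i, step_list)
                acc = 0
        else:
            acc = 0
    return prompts, acc


def _response_outcome(
    steps: np.ndarray, prompt_idx: int, cfg: EngineConfig
) -> tuple[bool, int]:
    """Tally steps in the (t, t + response_window] minutes after a prompt."""
    tail = steps[prompt_idx + 1 : prompt_idx + 1 + cfg.response_window]
    total = int(np.sum(tail))
    return total >= cfg.response_step_goal, total


def step_engine(
    stream: Sequence[MinuteSample],
    reports: Sequence[SymptomReport],
    window: WakeWindow,
    cfg: EngineConfig,
    day: dt.date | None = None,
) -> tuple[list[PromptEvent], EngineState]:
    """Run the engine over one participant-day.

    ``stream`` holds the day's minute samples sorted by time (missing minutes
    are read as zero steps); ``reports`` are all reports available to the app,
    sorted; ``window`` is the wake window anchored at ``day`` (defaults to the
    first sample's date). Returns the emitted prompt events and the final
    engine state.
    """
    if not stream and day is None:
        raise ValidationError("empty stream requires an explicit day")
    ts = [s.t for s in stream]
    if any(b <= a for a, b in zip(ts, ts[1:])):
        raise ValidationError("stream must be strictly increasing in time")
    if any(r2.t < r1.t for r1, r2 in zip(reports, reports[1:])):
        raise ValidationError("reports must be sorted by time")
    if day is None:
        day = stream[0].t.date()

    start, end = window.bounds(day)
    n_win = int((end - start).total_seconds() // 60)
    start_minute = _epoch_minute(start)

    steps = np.zeros(n_win + cfg.response_window, dtype=np.int64)
    for s in stream:
        off = _epoch_minute(s.t) - start_minute
        if 0 <= off < len(steps):
            steps[off] = s.steps

    thresholds = _threshold_schedule(reports, start_minute, n_win, cfg)
    prompt_idx, acc = _run_window(steps, thresholds, cfg)

    pid = window.participant_id
    events = []
    open_windows = []
    for i in prompt_idx:
        responded, total = _response_outcome(steps, i, cfg)
        t = start + dt.timedelta(minutes=i)
        events.append(
            PromptEvent(
                participant_id=pid,
                t=t,
                threshold_used=int(thresholds[i]),
                responded=responded,
                response_steps=total,
                feedback_sent=responded,
            )
        )
        if i + cfg.response_window >= n_win:
            open_windows.append((t, total))

    last_report = None
    end_minute = start_minute + n_win
    for r in reports:
        if _epoch_minute(r.t) <= end_minute:
            last_report = r
    state = EngineState(
        sedentary_accumulator=acc,
        active_threshold=int(thresholds[-1]) if n_win else current_threshold(last_report, cfg),
        last_symptom_report=last_report,
        open_response_windows=open_windows,
        emitted=events,
    )
    return events, state


def run_participant(
    timeline: ParticipantTimeline, cfg: EngineConfig | None = None
) -> list[PromptEvent]:
    """Drive the engine across every day of a participant's timeline.

    The engine state resets at each wake-window open; symptom reports carry
    forward across days. Monitoring-arm participants receive no prompts (the
    engine is not invoked).
    """
    cfg = cfg or EngineConfig()
    if timeline.info.arm != "intervention":
        return []
    if timeline.minutes.empty:
        return []

    minute_idx = timeline.minutes["t"].values.astype("datetime64[m]").astype(np.int64)
    step_vals = timeline.minutes["steps"].to_numpy(dtype=np.int64)
    pid = timeline.info.participant_id

    events: list[PromptEvent] = []
    for day in timeline.dates():
        window = timeline.window_for(day)
        start, end = window.bounds(day)
        n_win = int((end - start).total_seconds() // 60)
        start_minute = _epoch_minute(start)

        steps = np.zeros(n_win + cfg.response_window, dtype=np.int64)
        lo = np.searchsorted(minute_idx, start_minute)
        hi = np.searchsorted(minute_idx, start_minute + len(steps))
        if lo == hi:
            # no device contact anywhere near this day's window: the app was
            # not running, so nothing to impute and nothing to prompt
            continue
        steps[minute_idx[lo:hi] - start_minute] = step_vals[lo:hi]

        thresholds = _threshold_schedule(timeline.reports, start_minute, n_win, cfg)
        prompt_idx, _ = _run_window(steps, thresholds, cfg)
        for i in prompt_idx:
            responded, total = _response_outcome(steps, i, cfg)
            events.append(
                PromptEvent(
                    participant_id=pid,
                    t=start + dt.timedelta(minutes=i),
                    threshold_used=int(thresholds[i]),
                    responded=responded,
                    response_steps=total,
                    feedback_sent=responded,
                )
            )
    return events
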