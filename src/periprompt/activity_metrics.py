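"""Adherence and objective-activity outcome metrics.

Implements the trial's measurement layer: the 8-hour wear-time filter,
symptom-reporting adherence, daily sedentary-bout statistics (maximal runs of
minutes with fewer than 10 steps inside the waking day, with device-detected
sleep excluded), daily step totals, prompts per day, and pooled prompt-response
proportions per perioperative phase.

Bout statistics are computed within the waking day only; a run that would
cross bed time is truncated there. Missing minutes are counted as sedentary by
default (mirroring what the wrist device records when idle or not worn); set
``treat_missing_as_sedentary=False`` for a wear-time sensitivity analysis.
Phase response fractions are pooled ratios of summed counts, not means of
daily ratios.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .jitai_engine import ParticipantTimeline, _epoch_minute
from .stream_model import (
    Bout,
    DailySummary,
    MinuteSample,
    Phase,
    PromptEvent,
    SleepEpisode,
    SymptomReport,
    ValidationError,
    WakeWindow,
    assign_phase,
)
from .trial_stats import proportion_pct, round_half_away

__all__ = [
    "MetricsConfig",
    "PhaseSummary",
    "daily_wear_minutes",
    "extract_bouts",
    "summarize_day",
    "summarize_participant",
    "summarize_phase",
    "adherence_table",
    "summaries_frame",
    "format_adherence",
]


@dataclass(frozen=True)
class MetricsConfig:
    """Measurement policy for the outcome metrics."""

    min_wear_minutes: int = 480
    sedentary_step_cut: int = 10
    treat_missing_as_sedentary: bool = True
    exclude_sleep: bool = True

    def __post_init__(self) -> None:
        if not (1 <= self.min_wear_minutes <= 1440):
            raise ValidationError("min_wear_minutes must be in [1, 1440]")
        if self.sedentary_step_cut < 1:
            raise ValidationError("sedentary_step_cut must be >= 1")


@dataclass
class PhaseSummary:
    """Cohort-level descriptives for one perioperative phase.

    ``response_fraction`` is the pooled ratio of responded prompts to all
    prompts and is ``None`` (flagged, not 0) when no prompts were sent.
    Step and bout means are over wear-filter-included days only.
    """

    phase: Phase
    n_days: int
    n_included_days: int
    mean_steps: float
    mean_of_daily_mean_bout: float
    mean_of_daily_max_bout: float
    prompts_per_day: float
    n_prompts: int
    n_responses: int
    response_fraction: float | None
    symptom_adherence_fraction: float
    wear_adherence_fraction: float

    def __post_init__(self) -> None:
        if self.n_included_days > self.n_days:
            raise ValidationError("n_included_days cannot exceed n_days")
        for name in (
            "response_fraction",
            "symptom_adherence_fraction",
            "wear_adherence_fraction",
        ):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValidationError(f"{name}={v} outside [0, 1]")


def daily_wear_minutes(day_stream: Sequence[MinuteSample] | pd.DataFrame) -> int:
    """Minutes with worn=True in one participant-day (need not be consecutive)."""
    if isinstance(day_stream, pd.DataFrame):
        return int(day_stream["worn"].sum())
    return sum(1 for s in day_stream if s.worn)


def _window_arrays(
    day_stream: Sequence[MinuteSample] | pd.DataFrame,
    window: WakeWindow,
    day: dt.date,
) -> tuple[np.ndarray, np.ndarray, dt.datetime]:
    """(present, steps) arrays over the waking minutes of ``day``."""
    start, end = window.bounds(day)
    n = int((end - start).total_seconds() // 60)
    start_minute = _epoch_minute(start)
    present = np.zeros(n, dtype=bool)
    steps = np.zeros(n, dtype=np.int64)
    if isinstance(day_stream, pd.DataFrame):
        t = day_stream["t"].values.astype("datetime64[m]").astype(np.int64)
        offs = t - start_minute
        keep = (offs >= 0) & (offs < n)
        present[offs[keep]] = True
        steps[offs[keep]] = day_stream["steps"].to_numpy(dtype=np.int64)[keep]
    else:
        for s in day_stream:
            off = _epoch_minute(s.t) - start_minute
            if 0 <= off < n:
                present[off] = True
                steps[off] = s.steps
    return present, steps, start


def _sleep_mask(
    sleep: Sequence[SleepEpisode], start: dt.datetime, n: int
) -> np.ndarray:
    """Boolean mask of waking-window minutes covered by a sleep episode."""
    eps = sorted(sleep, key=lambda e: e.start)
    for prev, cur in zip(eps, eps[1:]):
        if cur.start < prev.end:
            raise ValidationError(
                f"overlapping sleep episodes at {cur.start.isoformat()}"
            )
    mask = np.zeros(n, dtype=bool)
    start_minute = _epoch_minute(start)
    for e in eps:
        lo = max(_epoch_minute(e.start) - start_minute, 0)
        hi = min(_epoch_minute(e.end) - start_minute, n)
        if lo < hi:
            mask[lo:hi] = True
    return mask


def extract_bouts(
    day_stream: Sequence[MinuteSample] | pd.DataFrame,
    window: WakeWindow,
    sleep: Sequence[SleepEpisode],
    cfg: MetricsConfig | None = None,
    day: dt.date | None = None,
) -> list[Bout]:
    """Maximal sedentary runs within the waking day.

    Minutes inside sleep episodes are removed before run-finding (when
    ``exclude_sleep``), so sleep interrupts and splits bouts; so does any
    active minute or (when missing minutes are not imputed sedentary) a gap.
    """
    cfg = cfg or MetricsConfig()
    if day is None:
        if isinstance(day_stream, pd.DataFrame):
            if day_stream.empty:
                raise ValidationError("empty stream requires an explicit day")
            day = day_stream["t"].iloc[0].date()
        else:
            if not day_stream:
                raise ValidationError("empty stream requires an explicit day")
            day = day_stream[0].t.date()

    present, steps, start = _window_arrays(day_stream, window, day)
    n = len(present)
    sedentary = np.where(present, steps < cfg.sedentary_step_cut, cfg.treat_missing_as_sedentary)
    if cfg.exclude_sleep and sleep:
        sedentary &= ~_sleep_mask(sleep, start, n)

    bouts: list[Bout] = []
    run_start = None
    for i in range(n + 1):
        if i < n and sedentary[i]:
            if run_start is None:
                run_start = i
        elif run_start is not None:
            bouts.append(
                Bout(start=start + dt.timedelta(minutes=run_start), duration=i - run_start)
            )
            run_start = None
    return bouts


def summarize_day(
    day_stream: Sequence[MinuteSample] | pd.DataFrame,
    events: Sequence[PromptEvent],
    reports: Sequence[SymptomReport],
    window: WakeWindow,
    sleep: Sequence[SleepEpisode],
    phase: Phase,
    cfg: MetricsConfig | None = None,
    day: dt.date | None = None,
    participant_id: str | None = None,
) -> DailySummary:
    """Populate one participant-day's summary from its streams.

    ``events`` and ``reports`` may span the study; only those dated ``day``
    are counted. ``day_stream`` must belong to the single calendar day (plus,
    for a midnight-crossing window, its spill-over into the next date).
    """
    cfg = cfg or MetricsConfig()
    if isinstance(day_stream, pd.DataFrame):
        n_rows = len(day_stream)
        first_t = day_stream["t"].iloc[0] if n_rows else None
    else:
        n_rows = len(day_stream)
        first_t = day_stream[0].t if n_rows else None
    if day is None:
        if first_t is None:
            raise ValidationError("empty stream requires an explicit day")
        day = first_t.date()

    win_start, win_end = window.bounds(day)
    lo = dt.datetime.combine(day, dt.time.min)
    hi = max(dt.datetime.combine(day + dt.timedelta(days=1), dt.time.min), win_end)
    if isinstance(day_stream, pd.DataFrame):
        times = pd.to_datetime(day_stream["t"])
        if n_rows and ((times < lo) | (times >= hi)).any():
            raise ValidationError(f"stream contains data outside day {day}")
        day_mask = (times >= lo) & (times < lo + dt.timedelta(days=1))
        wear = int(day_stream.loc[day_mask, "worn"].sum())
        total_steps = int(day_stream.loc[day_mask, "steps"].sum())
    else:
        if any(not (lo <= s.t < hi) for s in day_stream):
            raise ValidationError(f"stream contains data outside day {day}")
        in_day = [s for s in day_stream if s.t.date() == day]
        wear = daily_wear_minutes(in_day)
        total_steps = sum(s.steps for s in in_day)

    bouts = extract_bouts(day_stream, window, sleep, cfg, day)
    durations = [b.duration for b in bouts]
    day_events = [e for e in events if e.t.date() == day]
    pid = participant_id or window.participant_id

    return DailySummary(
        participant_id=pid,
        date=day,
        phase=phase,
        wear_minutes=wear,
        total_steps=total_steps,
        bouts=bouts,
        max_bout=max(durations) if durations else 0,
        mean_bout=float(np.mean(durations)) if durations else 0.0,
        n_prompts=len(day_events),
        n_responses=sum(1 for e in day_events if e.responded),
        symptom_reported=any(r.t.date() == day for r in reports),
        included=wear >= cfg.min_wear_minutes,
        min_wear_minutes=cfg.min_wear_minutes,
    )


def summarize_participant(
    timeline: ParticipantTimeline,
    events: Sequence[PromptEvent],
    cfg: MetricsConfig | None = None,
) -> list[DailySummary]:
    """Daily summaries over every calendar day of a participant's timeline."""
    cfg = cfg or MetricsConfig()
    info = timeline.info
    times = pd.to_datetime(timeline.minutes["t"]) if not timeline.minutes.empty else None
    summaries = []
    for day in timeline.dates():
        window = timeline.window_for(day)
        _, win_end = window.bounds(day)
        lo = dt.datetime.combine(day, dt.time.min)
        hi = max(dt.datetime.combine(day + dt.timedelta(days=1), dt.time.min), win_end)
        day_frame = timeline.minutes[(times >= lo) & (times < hi)]
        summaries.append(
            summarize_day(
                day_frame,
                events,
                timeline.reports,
                window,
                timeline.sleep,
                assign_phase(day, info.surgery_date, info.discharge_date),
                cfg,
                day=day,
                participant_id=info.participant_id,
            )
        )
    return summaries


def summarize_phase(
    summaries: Iterable[DailySummary], phase: Phase
) -> PhaseSummary:
    """Pool one phase's daily summaries into cohort-level descriptives."""
    days = [s for s in summaries if s.phase == phase]
    if not days:
        raise ValidationError(f"no summaries in phase {phase}")
    included = [s for s in days if s.included]
    n_prompts = sum(s.n_prompts for s in days)
    n_responses = sum(s.n_responses for s in days)
    return PhaseSummary(
        phase=phase,
        n_days=len(days),
        n_included_days=len(included),
        mean_steps=float(np.mean([s.total_steps for s in included])) if included else float("nan"),
        mean_of_daily_mean_bout=float(np.mean([s.mean_bout for s in included]))
        if included
        else float("nan"),
        mean_of_daily_max_bout=float(np.mean([s.max_bout for s in included]))
        if included
        else float("nan"),
        prompts_per_day=n_prompts / len(days),
        n_prompts=n_prompts,
        n_responses=n_responses,
        response_fraction=(n_responses / n_prompts) if n_prompts else None,
        symptom_adherence_fraction=sum(s.symptom_reported for s in days) / len(days),
        wear_adherence_fraction=len(included) / len(days),
    )


def adherence_table(summaries: Iterable[DailySummary]) -> dict:
    """Cohort adherence report with numerators, denominators, and percentages.

    Reports symptom-rating days, worn days (any wear), days meeting the
    8-hour filter among worn days, and included days overall, plus the
    per-participant minimum and maximum of the rating and inclusion rates.
    """
    days = list(summaries)
    n_total = len(days)

    def entry(num: int, den: int) -> dict:
        if den == 0:
            return {"numerator": num, "denominator": 0, "fraction": None, "percent": None}
        frac, pct = proportion_pct(num, den)
        return {"numerator": num, "denominator": den, "fraction": frac, "percent": pct}

    n_rating = sum(s.symptom_reported for s in days)
    n_worn = sum(s.wear_minutes >= 1 for s in days)
    n_full_among_worn = sum(s.included for s in days if s.wear_minutes >= 1)
    n_included = sum(s.included for s in days)

    per_participant: dict[str, list[DailySummary]] = {}
    for s in days:
        per_participant.setdefault(s.participant_id, []).append(s)
    rating_rates = [
        100.0 * sum(x.symptom_reported for x in ss) / len(ss)
        for ss in per_participant.values()
    ]
    included_rates = [
        100.0 * sum(x.included for x in ss) / len(ss) for ss in per_participant.values()
    ]

    return {
        "symptom_rating_days": entry(n_rating, n_total),
        "worn_days": entry(n_worn, n_total),
        "full_wear_among_worn_days": entry(n_full_among_worn, n_worn),
        "included_days": entry(n_included, n_total),
        "per_participant": {
            "n_participants": len(per_participant),
            "rating_pct_min": round_half_away(min(rating_rates)) if rating_rates else None,
            "rating_pct_max": round_half_away(max(rating_rates)) if rating_rates else None,
            "included_pct_min": round_half_away(min(included_rates))
            if included_rates
            else None,
            "included_pct_max": round_half_away(max(included_rates))
            if included_rates
            else None,
        },
    }


def format_adherence(report: dict) -> str:
    """Human-readable rendering of an adherence report."""
    labels = {
        "symptom_rating_days": "Daily symptom ratings completed",
        "worn_days": "Days device worn at all",
        "full_wear_among_worn_days": ">=8 h of data among worn days",
        "included_days": "Days included in activity analyses",
    }
    lines = []
    for key, label in labels.items():
        e = report[key]
        if e["percent"] is None:
            lines.append(f"{label}: n/a (0 denominator)")
        else:
            lines.append(
                f"{label}: {e['percent']}% ({e['numerator']}/{e['denominator']})"
            )
    pp = report["per_participant"]
    if pp["rating_pct_min"] is not None:
        lines.append(
            "Per-participant rating adherence: "
            f"{pp['rating_pct_min']:.0f}%-{pp['rating_pct_max']:.0f}%"
        )
        lines.append(
            "Per-participant included-day rate: "
            f"{pp['included_pct_min']:.0f}%-{pp['included_pct_max']:.0f}%"
        )
    return "\n".join(lines)


def summaries_frame(summaries: Iterable[DailySummary]) -> pd.DataFrame:
    """Daily summaries as a tidy frame (one row per participant-day)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "participant_id": s.participant_id,
                "date": s.date.isoformat(),
                "phase": s.phase.value,
                "wear_minutes": s.wear_minutes,
                "total_steps": s.total_steps,
                "n_bouts": len(s.bouts),
                "bout_durations": "|".join(str(b.duration) for b in s.bouts),
                "max_bout": s.max_bout,
                "mean_bout": s.mean_bout,
                "n_prompts": s.n_prompts,
                "n_responses": s.n_responses,
                "symptom_reported": s.symptom_reported,
                "included": s.included,
            }
        )
    return pd.DataFrame(rows)
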