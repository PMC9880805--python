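import datetime as dt
import itertools

import numpy as np
import pytest

from periprompt import (
    MetricsConfig,
    MinuteSample,
    Phase,
    PromptEvent,
    SleepEpisode,
    ValidationError,
    adherence_table,
    daily_wear_minutes,
    extract_bouts,
    summarize_day,
    summarize_participant,
    summarize_phase,
)
from periprompt.activity_metrics import summaries_frame, format_adherence
from periprompt.jitai_engine import ParticipantTimeline
from periprompt.stream_model import DailySummary

from conftest import DAY, WAKE, day_stream, report


WAKE_DT = dt.datetime.combine(DAY, WAKE)


def oracle_bouts(step_values, sleep_offsets=(), missing_offsets=(), cut=10):
    """Brute-force run-length oracle over explicit minute labels."""
    labels = []
    for i, s in enumerate(step_values):
        if i in sleep_offsets or i in missing_offsets:
            labels.append("break")
        else:
            labels.append("sed" if s < cut else "act")
    runs = []
    pos = 0
    for label, grp in itertools.groupby(labels):
        n = len(list(grp))
        if label == "sed":
            runs.append((pos, n))
        pos += n
    return runs


class TestDailyWearMinutes:
    def test_480_worn_minutes_included(self):
        stream = day_stream([0] * 480)
        assert daily_wear_minutes(stream) == 480

    def test_479_worn_minutes_excluded(self, window):
        stream = day_stream([0] * 479)
        s = summarize_day(stream, [], [], window, [], Phase.PREOPERATIVE)
        assert s.wear_minutes == 479 and not s.included

    def test_empty_day_is_zero(self):
        assert daily_wear_minutes([]) == 0

    def test_wear_need_not_be_consecutive(self, window):
        samples = [
            MinuteSample("P1", WAKE_DT + dt.timedelta(minutes=2 * i), 0, True)
            for i in range(480)
        ]
        s = summarize_day(samples, [], [], window, [], Phase.PREOPERATIVE)
        assert s.included


class TestExtractBouts:
    def test_runs_split_by_one_active_minute(self, window):
        """30 sedentary, 1 active, 90 sedentary: bouts [30, 90]; max 90, mean 60."""
        steps = [0] * 30 + [50] + [0] * 90 + [50] * (720 - 121)
        bouts = extract_bouts(day_stream(steps), window, [])
        assert [b.duration for b in bouts] == [30, 90]
        assert max(b.duration for b in bouts) == 90
        assert np.mean([b.duration for b in bouts]) == 60

    def test_fully_active_day_has_no_bouts(self, window):
        assert extract_bouts(day_stream([40] * 720), window, []) == []

    def test_sleep_episode_splits_a_bout(self, window):
        """120 sedentary minutes with sleep over minutes 40-79: bouts [40, 40]."""
        sleep = [
            SleepEpisode(
                "P1",
                WAKE_DT + dt.timedelta(minutes=40),
                WAKE_DT + dt.timedelta(minutes=80),
            )
        ]
        steps = [0] * 120 + [50] * 600
        bouts = extract_bouts(day_stream(steps), window, sleep)
        assert [b.duration for b in bouts] == [40, 40]
        assert bouts[1].start == WAKE_DT + dt.timedelta(minutes=80)

    def test_missing_minutes_counted_sedentary_by_default(self, window):
        # only two worn active minutes recorded; the rest of the window is gap
        samples = [
            MinuteSample("P1", WAKE_DT + dt.timedelta(minutes=100), 50, True),
            MinuteSample("P1", WAKE_DT + dt.timedelta(minutes=101), 50, True),
        ]
        bouts = extract_bouts(samples, window, [])
        assert [b.duration for b in bouts] == [100, 720 - 102]

    def test_missing_minutes_break_bouts_when_not_imputed(self, window):
        cfg = MetricsConfig(treat_missing_as_sedentary=False)
        samples = day_stream([0] * 30)  # nothing recorded after minute 29
        bouts = extract_bouts(samples, window, [], cfg)
        assert [b.duration for b in bouts] == [30]

    def test_overlapping_sleep_rejected(self, window):
        sleep = [
            SleepEpisode("P1", WAKE_DT, WAKE_DT + dt.timedelta(minutes=60)),
            SleepEpisode("P1", WAKE_DT + dt.timedelta(minutes=30), WAKE_DT + dt.timedelta(minutes=90)),
        ]
        with pytest.raises(ValidationError, match="overlap"):
            extract_bouts(day_stream([0] * 120), window, sleep)

    def test_agrees_with_run_length_oracle_on_random_days(self, window):
        """Bout extraction equals a brute-force oracle on random day patterns."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            steps = rng.choice([0, 2, 9, 10, 30], size=720)
            sleep_lo = int(rng.integers(0, 600))
            sleep_hi = sleep_lo + int(rng.integers(1, 120))
            sleep = [
                SleepEpisode(
                    "P1",
                    WAKE_DT + dt.timedelta(minutes=sleep_lo),
                    WAKE_DT + dt.timedelta(minutes=sleep_hi),
                )
            ]
            bouts = extract_bouts(day_stream(steps), window, sleep)
            expected = oracle_bouts(steps, sleep_offsets=set(range(sleep_lo, sleep_hi)))
            assert [(int((b.start - WAKE_DT).total_seconds() // 60), b.duration) for b in bouts] == expected

    def test_minute_conservation(self, window):
        """Bout + active + sleep-excluded minutes cover the whole waking day."""
        rng = np.random.default_rng(3)
        steps = rng.choice([0, 40], size=720)
        sleep = [
            SleepEpisode("P1", WAKE_DT + dt.timedelta(minutes=200), WAKE_DT + dt.timedelta(minutes=260))
        ]
        bouts = extract_bouts(day_stream(steps), window, sleep)
        sleep_minutes = 60
        active = int(np.sum(steps[:200] >= 10) + np.sum(steps[260:] >= 10))
        assert sum(b.duration for b in bouts) + active + sleep_minutes == 720


class TestSummarizeDay:
    def test_report_and_wear_flags(self, window):
        s = summarize_day(
            day_stream([0] * 500), [], [report(5, t=WAKE_DT)], window, [], Phase.PREOPERATIVE
        )
        assert s.symptom_reported and s.included

    def test_day_without_prompts(self, window):
        s = summarize_day(day_stream([0] * 500), [], [], window, [], Phase.INPATIENT)
        assert s.n_prompts == 0 and s.n_responses == 0

    def test_summary_matches_per_field_recomputation(self, window):
        """Every populated field equals an independent recomputation."""
        rng = np.random.default_rng(5)
        steps = rng.choice([0, 0, 8, 25], size=720)
        stream = day_stream(steps)
        events = [
            PromptEvent("P1", WAKE_DT + dt.timedelta(minutes=200), 60, True, 45, True),
            PromptEvent("P1", WAKE_DT + dt.timedelta(minutes=400), 120, False, 2, False),
        ]
        s = summarize_day(stream, events, [report(3, t=WAKE_DT)], window, [], Phase.PREOPERATIVE)
        assert s.wear_minutes == 720
        assert s.total_steps == int(np.sum(steps))
        expected = oracle_bouts(steps)
        assert [b.duration for b in s.bouts] == [d for _, d in expected]
        assert s.max_bout == max(d for _, d in expected)
        assert s.mean_bout == pytest.approx(np.mean([d for _, d in expected]))
        assert (s.n_prompts, s.n_responses) == (2, 1)

    def test_cross_day_data_rejected(self, window):
        stream = day_stream([0] * 10) + day_stream([0] * 10, day=DAY + dt.timedelta(days=2))
        with pytest.raises(ValidationError, match="outside day"):
            summarize_day(stream, [], [], window, [], Phase.PREOPERATIVE, day=DAY)


def _mk_summary(pid, date, phase, prompts, responses, reported=True, wear=700, steps=3000):
    return DailySummary(
        participant_id=pid,
        date=date,
        phase=phase,
        wear_minutes=wear,
        total_steps=steps,
        bouts=[],
        max_bout=0,
        mean_bout=0.0,
        n_prompts=prompts,
        n_responses=responses,
        symptom_reported=reported,
        included=wear >= 480,
    )


class TestSummarizePhase:
    def test_pooled_response_fraction_not_mean_of_daily_ratios(self):
        # 10/10 on one day and 0/90 on another pools to 10/100, not 55%
        summaries = [
            _mk_summary("P1", DAY, Phase.PREOPERATIVE, 10, 10),
            _mk_summary("P1", DAY + dt.timedelta(days=1), Phase.PREOPERATIVE, 90, 0),
        ]
        ps = summarize_phase(summaries, Phase.PREOPERATIVE)
        assert ps.response_fraction == pytest.approx(0.1)

    def test_printed_phase_ratios(self):
        """200/407 pools to 49%, 29/462 to 6% at printed rounding."""
        from periprompt.trial_stats import proportion_pct

        assert proportion_pct(200, 407)[1] == 49
        assert proportion_pct(29, 462)[1] == 6
        summaries = [_mk_summary("P1", DAY, Phase.PREOPERATIVE, 407, 200)]
        ps = summarize_phase(summaries, Phase.PREOPERATIVE)
        assert ps.response_fraction == pytest.approx(200 / 407)

    def test_single_day_two_prompts_one_response(self):
        ps = summarize_phase([_mk_summary("P1", DAY, Phase.INPATIENT, 2, 1)], Phase.INPATIENT)
        assert ps.response_fraction == 0.5

    def test_zero_prompts_flagged_not_zero(self):
        ps = summarize_phase([_mk_summary("P1", DAY, Phase.INPATIENT, 0, 0)], Phase.INPATIENT)
        assert ps.response_fraction is None

    def test_means_use_included_days_only(self):
        summaries = [
            _mk_summary("P1", DAY, Phase.INPATIENT, 0, 0, steps=1000, wear=700),
            _mk_summary("P1", DAY + dt.timedelta(days=1), Phase.INPATIENT, 0, 0, steps=9000, wear=100),
        ]
        ps = summarize_phase(summaries, Phase.INPATIENT)
        assert ps.mean_steps == 1000
        assert ps.n_included_days == 1 and ps.n_days == 2


class TestAdherenceTable:
    def test_counts_and_percentages(self):
        # 3 participants x 4 days; wear pattern chosen to exercise every ratio
        summaries = []
        wear_grid = {
            "P1": [700, 700, 0, 100],
            "P2": [500, 0, 0, 0],
            "P3": [700, 700, 700, 700],
        }
        reported_grid = {"P1": [1, 1, 0, 0], "P2": [0, 0, 0, 0], "P3": [1, 1, 1, 1]}
        for pid in wear_grid:
            for i in range(4):
                summaries.append(
                    _mk_summary(
                        pid,
                        DAY + dt.timedelta(days=i),
                        Phase.PREOPERATIVE,
                        0,
                        0,
                        reported=bool(reported_grid[pid][i]),
                        wear=wear_grid[pid][i],
                    )
                )
        table = adherence_table(summaries)
        assert table["symptom_rating_days"] == {
            "numerator": 6, "denominator": 12, "fraction": 0.5, "percent": 50,
        }
        assert table["worn_days"]["numerator"] == 8  # any wear at all
        assert table["full_wear_among_worn_days"]["numerator"] == 7
        assert table["full_wear_among_worn_days"]["denominator"] == 8
        assert table["included_days"]["percent"] == 58  # 7/12 = 58.33
        pp = table["per_participant"]
        assert pp["rating_pct_min"] == 0 and pp["rating_pct_max"] == 100
        text = format_adherence(table)
        assert "58% (7/12)" in text

    def test_zero_numerator_is_zero_percent(self):
        summaries = [
            _mk_summary("P1", DAY + dt.timedelta(days=i), Phase.PREOPERATIVE, 0, 0, reported=False)
            for i in range(10)
        ]
        assert adherence_table(summaries)["symptom_rating_days"]["percent"] == 0

    def test_wear_filter_days_are_independent(self, info):
        """Excluding one day by the wear filter leaves other days' metrics unchanged."""
        samples = day_stream([0] * 720) + day_stream([0] * 100, day=DAY + dt.timedelta(days=1))
        timeline = ParticipantTimeline.from_samples(info, samples, [])
        both = summarize_participant(timeline, [])
        solo_timeline = ParticipantTimeline.from_samples(info, day_stream([0] * 720), [])
        solo = summarize_participant(solo_timeline, [])
        d0_both = next(s for s in both if s.date == DAY)
        assert d0_both.max_bout == solo[0].max_bout
        assert d0_both.total_steps == solo[0].total_steps
        assert d0_both.included and not next(s for s in both if s.date != DAY).included


class TestSummariesFrame:
    def test_one_row_per_day_with_phase_labels(self, info):
        samples = day_stream([0] * 720) + day_stream([20] * 720, day=DAY + dt.timedelta(days=1))
        timeline = ParticipantTimeline.from_samples(info, samples, [report(2, t=WAKE_DT)])
        frame = summaries_frame(summarize_participant(timeline, []))
        assert len(frame) == 2
        assert set(frame["phase"]) == {"preoperative"}
        assert frame.loc[0, "symptom_reported"] and not frame.loc[1, "symptom_reported"]
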