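"""Watch-stage tests: hourly apportioning, the nonactive inference rule,
wear time, day filters and participant summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import hr_frame, step_frame
from wearcpet.watch import (
    hourly_steps,
    infer_motion_context,
    process_watch,
    summarize_days,
    summarize_participants,
    wear_time,
)


# ---------------------------------------------------------------------------
# hourly_steps
# ---------------------------------------------------------------------------

def test_hourly_steps_single_and_split_intervals():
    steps = step_frame([
        ("A", "2019-01-01 10:00", "2019-01-01 10:30", 300),
        ("A", "2019-01-02 10:45", "2019-01-02 11:15", 60),
    ])
    out = hourly_steps(steps, fill="sparse").set_index("hour")["steps"]
    assert out[pd.Timestamp("2019-01-01 10:00")] == 300
    assert out[pd.Timestamp("2019-01-02 10:00")] == 30
    assert out[pd.Timestamp("2019-01-02 11:00")] == 30


def test_hourly_steps_span_fill_includes_empty_hours():
    steps = step_frame([
        ("A", "2019-01-01 08:00", "2019-01-01 09:00", 100),
        ("A", "2019-01-01 11:00", "2019-01-01 12:00", 50),
    ])
    out = hourly_steps(steps, fill="span")
    assert len(out) == 4  # hours 08..11
    assert out.set_index("hour")["steps"][pd.Timestamp("2019-01-01 09:00")] == 0


def test_hourly_steps_rejects_overlaps():
    steps = step_frame([
        ("A", "2019-01-01 10:00", "2019-01-01 11:00", 10),
        ("A", "2019-01-01 10:30", "2019-01-01 11:30", 10),
    ])
    with pytest.raises(ValueError, match="overlap"):
        hourly_steps(steps)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 6000), st.integers(60, 7200),
                          st.integers(0, 2000)),
                min_size=1, max_size=25))
def test_hourly_steps_conserves_totals(intervals):
    """Sum over hours equals the raw record total to within the rounding
    slack of one step per record."""
    base = pd.Timestamp("2019-01-01")
    rows, cursor = [], 0
    for gap, dur, count in intervals:
        start = cursor + gap
        cursor = start + dur
        rows.append(("A", base + pd.Timedelta(seconds=start),
                     base + pd.Timedelta(seconds=cursor), count))
    steps = pd.DataFrame(rows, columns=["participant_id", "start", "end", "steps"])
    out = hourly_steps(steps, fill="sparse")
    assert abs(out["steps"].sum() - steps["steps"].sum()) <= len(steps)


# ---------------------------------------------------------------------------
# motion-context inference
# ---------------------------------------------------------------------------

def test_nonactive_rule_gap_and_step_conditions():
    hr = hr_frame([
        ("A", "2019-01-01 09:00:00", 70, "unknown"),
        ("A", "2019-01-01 09:02:00", 71, "unknown"),   # gap 120 s, 0 steps
        ("A", "2019-01-01 09:02:10", 72, "unknown"),   # gap 10 s -> active
        ("A", "2019-01-01 10:02:10", 73, "unknown"),   # gap 3600 s, 30 steps
    ])
    steps = step_frame([("A", "2019-01-01 10:00", "2019-01-01 11:00", 30)])
    out = infer_motion_context(hr, step_df=steps).set_index("timestamp")
    assert out.loc["2019-01-01 09:02:00", "context_resolved"] == "nonactive"
    assert out.loc["2019-01-01 09:02:10", "context_resolved"] == "active"
    # hourly threshold is strict: exactly 30 steps fails the <30 condition
    assert out.loc["2019-01-01 10:02:10", "context_resolved"] == "active"


def test_first_record_of_day_uses_forward_gap():
    hr = hr_frame([
        ("A", "2019-01-01 08:00:00", 70, "unknown"),
        ("A", "2019-01-01 08:10:00", 70, "unknown"),
        ("B", "2019-01-01 08:00:00", 70, "unknown"),
        ("B", "2019-01-01 08:00:30", 70, "unknown"),
        ("B", "2019-01-01 08:02:30", 70, "unknown"),
    ])
    out = infer_motion_context(hr).set_index(["participant_id", "timestamp"])
    # A's first record: forward gap 600 s, no steps -> nonactive
    assert out.loc[("A", "2019-01-01 08:00:00"), "context_resolved"] == "nonactive"
    # B's first record: forward gap 30 s -> active despite zero steps
    assert out.loc[("B", "2019-01-01 08:00:00"), "context_resolved"] == "active"


def test_device_labels_are_authoritative():
    hr = hr_frame([
        ("A", "2019-01-01 09:00:00", 70, "sedentary"),
        ("A", "2019-01-01 09:00:05", 110, "active"),
        ("A", "2019-01-01 09:05:05", 75, "unknown"),
    ])
    out = infer_motion_context(hr)
    assert list(out["context_resolved"]) == ["sedentary", "active", "nonactive"]
    assert list(out["nonactive"]) == [True, False, True]
    assert len(infer_motion_context(hr.iloc[:0])) == 0


def test_classifier_recovers_ground_truth(small_study):
    """On default synthetic streams the inferred context agrees with the
    planted truth for >=95% of records."""
    labeled, _, _ = process_watch(
        small_study.hr[["participant_id", "timestamp", "hr_bpm", "context"]],
        small_study.steps)
    m = labeled.merge(
        small_study.hr[["participant_id", "timestamp", "true_context"]],
        on=["participant_id", "timestamp"])
    agree = (m["nonactive"] == (m["true_context"] == "sedentary")).mean()
    assert agree >= 0.95


# ---------------------------------------------------------------------------
# wear time and day summaries
# ---------------------------------------------------------------------------

def test_wear_time_counts_distinct_hours():
    hr = hr_frame([
        ("A", "2019-01-01 08:10:00", 70, "unknown"),
        ("A", "2019-01-01 08:50:00", 70, "unknown"),
        ("A", "2019-01-01 09:10:00", 70, "unknown"),
        ("A", "2019-01-01 21:10:00", 70, "unknown"),
    ])
    assert wear_time(hr, None, "A", "2019-01-01") == 3
    assert wear_time(hr, None, "A", "2019-01-02") == 0
    full = hr_frame([("A", f"2019-01-01 {h:02d}:30:00", 70, "unknown")
                     for h in range(24)])
    assert wear_time(full, None, "A", "2019-01-01") == 24


def _day(pid, day, n_hours, steps):
    """One crafted person-day: HR records in n_hours distinct hours and a
    single step record carrying the whole daily total."""
    hr_rows = [(pid, f"2019-01-{day:02d} {8 + h:02d}:00:00", 70, "unknown")
               for h in range(n_hours)]
    step_rows = [(pid, f"2019-01-{day:02d} 08:05", f"2019-01-{day:02d} 08:55",
                  steps)]
    return hr_rows, step_rows


def test_day_validity_boundaries_are_strict_less_than():
    specs = [(1, 5, 1000, True),    # equality passes both thresholds
             (2, 6, 999, False),    # steps below 1000
             (3, 4, 5000, False)]   # wear below 5 hours
    hr_rows, step_rows = [], []
    for day, hours, steps, _ in specs:
        h, s = _day("A", day, hours, steps)
        hr_rows += h
        step_rows += s
    days = summarize_days(hr_frame(hr_rows), step_frame(step_rows))
    got = days.set_index(days["date"].dt.day)["valid_step_day"]
    for day, _, _, expect in specs:
        assert got[day] == expect


def test_ten_day_fixture_counts():
    """Hand-built 10-day fixture with 4 threshold violations -> 6 valid."""
    specs = [(1, 14, 8000), (2, 5, 1000), (3, 10, 2500), (4, 6, 1500),
             (5, 12, 7000), (6, 8, 1200),
             (7, 4, 5000),   # wear too low
             (8, 14, 999),   # steps too low
             (9, 3, 800),    # both too low
             (10, 2, 500)]   # both too low
    hr_rows, step_rows = [], []
    for day, hours, steps in specs:
        h, s = _day("A", day, hours, steps)
        hr_rows += h
        step_rows += s
    days = summarize_days(hr_frame(hr_rows), step_frame(step_rows))
    assert len(days) == 10
    assert int(days["valid_step_day"].sum()) == 6


def test_relaxing_thresholds_is_monotone(small_study):
    hr = small_study.hr[["participant_id", "timestamp", "hr_bpm", "context"]]
    strict = summarize_days(hr, small_study.steps, 5, 1000)
    relaxed_wear = summarize_days(hr, small_study.steps, 4, 1000)
    relaxed_steps = summarize_days(hr, small_study.steps, 5, 500)
    n0 = strict["valid_step_day"].sum()
    assert relaxed_wear["valid_step_day"].sum() >= n0
    assert relaxed_steps["valid_step_day"].sum() >= n0


# ---------------------------------------------------------------------------
# participant summaries
# ---------------------------------------------------------------------------

def test_participant_summary_means_and_inclusion():
    hr_rows, step_rows = [], []
    # participant A: 30 valid days -> included; B: 29 -> excluded
    for pid, n_days in (("A", 30), ("B", 29)):
        for day in range(n_days):
            date = pd.Timestamp("2019-01-01") + pd.Timedelta(days=day)
            for h in range(6):
                hr_rows.append((pid, date + pd.Timedelta(hours=8 + h, minutes=2),
                                70 + (day + h) % 3 * 2, "sedentary"))
            step_rows.append((pid, date + pd.Timedelta(hours=9),
                              date + pd.Timedelta(hours=10), 2000))
    hr = hr_frame(hr_rows)
    steps = step_frame(step_rows)
    labeled = infer_motion_context(hr, step_df=steps)
    days = summarize_days(hr, steps)
    out = summarize_participants(days, labeled).set_index("participant_id")
    assert bool(out.loc["A", "included_primary"])
    assert not bool(out.loc["B", "included_primary"])
    # unweighted mean of nonactive HRs drawn from {70, 72, 74}
    a_records = labeled[(labeled["participant_id"] == "A") & labeled["nonactive"]]
    assert out.loc["A", "nonactive_hr_mean"] == pytest.approx(
        a_records["hr_bpm"].mean())
    assert out.loc["A", "mean_daily_steps"] == 2000


def test_participant_with_no_nonactive_records_is_flagged():
    hr = hr_frame([("A", "2019-01-01 09:00:00", 110, "active"),
                   ("A", "2019-01-01 09:00:10", 112, "active")])
    labeled = infer_motion_context(hr)
    days = summarize_days(hr, None)
    out = summarize_participants(days, labeled).set_index("participant_id")
    assert bool(out.loc["A", "no_nonactive_records"])
    assert np.isnan(out.loc["A", "nonactive_hr_mean"])


def test_null_effect_generator_gives_no_hr_fitness_correlation():
    from wearcpet.synth import CohortParams, generate_cohort
    p = CohortParams(n_participants=400, beta_hr_per_sd_fitness=0.0, seed=17)
    _, gt = generate_cohort(p)
    r = np.corrcoef(gt["latent_fitness"], gt["true_nonactive_hr"])[0, 1]
    assert abs(r) < 3 / np.sqrt(400)
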