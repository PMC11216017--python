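"""Smartwatch stream processing: motion-context inference and summaries.

Turns raw HR records (timestamp, bpm, optional device motion-context label)
and step records (interval, count) into the two participant-level exposures
of the analysis: mean nonactive heart rate and mean daily steps.

The processing rules:

* An HR record without a device label is inferred **nonactive** when both
  (1) the recording interval to the adjacent HR record exceeds 60 seconds
  (strict) and (2) the step total of the clock hour containing the record is
  below 30 (strict).  Device-supplied labels are authoritative.
* Person-days with wear time below 5 hours or daily steps below 1000 are
  excluded from the step analysis (both thresholds strict, so equality
  passes).
* Participants contribute to an analysis only with 30 or more qualifying
  days (inclusive).

All timestamps are naive readings of one configured local civil timezone;
calendar days and clock hours are taken directly from them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import (
    GAP_THRESHOLD_S,
    HOURLY_STEP_THRESHOLD,
    MIN_DAILY_STEPS,
    MIN_DAYS,
    MIN_WEAR_HOURS,
)

NONACTIVE_LABELS = ("sedentary", "nonactive")


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{name} is missing columns {missing}")


# ---------------------------------------------------------------------------
# Hourly step totals
# ---------------------------------------------------------------------------

def _step_hour_overlap(step_df: pd.DataFrame) -> pd.DataFrame:
    """Expand step intervals onto the clock-hour grid.

    Returns one row per (participant, clock hour) a record overlaps, with the
    overlap in seconds and the proportionally apportioned (fractional) step
    count.  Raises on overlapping intervals within a participant.
    """
    _require_columns(step_df, ["participant_id", "start", "end", "steps"], "steps")
    if len(step_df) == 0:
        return pd.DataFrame(columns=["participant_id", "hour", "overlap_s", "steps_frac"])
    df = step_df.sort_values(["participant_id", "start"], kind="stable")
    start = pd.to_datetime(df["start"])
    end = pd.to_datetime(df["end"])
    if (start >= end).any():
        bad = df.loc[start >= end, "participant_id"].iloc[0]
        raise ValueError(f"step record with start >= end for participant {bad}")
    same = df["participant_id"].values[1:] == df["participant_id"].values[:-1]
    overlap = same & (start.values[1:] < end.values[:-1])
    if overlap.any():
        bad = df["participant_id"].values[1:][overlap][0]
        raise ValueError(f"overlapping step intervals for participant {bad}")

    dur = (end - start).dt.total_seconds().values
    h_start = start.dt.floor("h")
    # hour containing the (exclusive) interval end
    h_end = (end - pd.Timedelta(nanoseconds=1)).dt.floor("h")

    single = (h_start == h_end).values
    parts = [pd.DataFrame({
        "participant_id": df["participant_id"].values[single],
        "hour": h_start.values[single],
        "overlap_s": dur[single],
        "steps_frac": df["steps"].values[single].astype(float),
    })]
    # records crossing hour boundaries: proportional apportioning
    for idx in np.flatnonzero(~single):
        row = df.iloc[idx]
        s, e = start.iloc[idx], end.iloc[idx]
        total = dur[idx]
        hours = pd.date_range(h_start.iloc[idx], h_end.iloc[idx], freq="h")
        seg_start = np.maximum(hours.values, s.to_datetime64())
        seg_end = np.minimum((hours + pd.Timedelta(hours=1)).values, e.to_datetime64())
        seg = (seg_end - seg_start) / np.timedelta64(1, "s")
        parts.append(pd.DataFrame({
            "participant_id": row["participant_id"],
            "hour": hours,
            "overlap_s": seg,
            "steps_frac": float(row["steps"]) * seg / total,
        }))
    out = pd.concat(parts, ignore_index=True)
    return (out.groupby(["participant_id", "hour"], as_index=False)
               .agg(overlap_s=("overlap_s", "sum"), steps_frac=("steps_frac", "sum")))


def hourly_steps(step_df: pd.DataFrame, fill: str = "span") -> pd.DataFrame:
    """Per-participant per-clock-hour step totals.

    Intervals crossing hour boundaries are apportioned proportionally to
    their overlap with each hour; hour totals are rounded half-to-even.
    With ``fill="span"`` every clock hour of each participant's observation
    span appears (0 where no record overlaps); ``fill="sparse"`` returns
    only hours with overlapping records.
    """
    expanded = _step_hour_overlap(step_df)
    if len(expanded) == 0:
        return pd.DataFrame(columns=["participant_id", "hour", "steps"])
    out = expanded.copy()
    out["steps"] = np.round(out["steps_frac"]).astype(np.int64)
    out = out[["participant_id", "hour", "steps"]]
    if fill == "sparse":
        return out.reset_index(drop=True)
    filled = []
    for pid, grp in out.groupby("participant_id", sort=True):
        grid = pd.date_range(grp["hour"].min(), grp["hour"].max(), freq="h")
        g = (grp.set_index("hour")["steps"]
                .reindex(grid, fill_value=0).rename_axis("hour").reset_index())
        g.insert(0, "participant_id", pid)
        filled.append(g)
    return pd.concat(filled, ignore_index=True)


# ---------------------------------------------------------------------------
# Motion-context inference
# ---------------------------------------------------------------------------

def infer_motion_context(hr_df: pd.DataFrame,
                         hourly: pd.DataFrame | None = None,
                         step_df: pd.DataFrame | None = None,
                         gap_threshold_s: float = GAP_THRESHOLD_S,
                         hourly_step_threshold: int = HOURLY_STEP_THRESHOLD,
                         ) -> pd.DataFrame:
    """Resolve the motion context of every HR record.

    Device-labeled records keep their label; records with ``unknown``
    context are labeled ``nonactive`` iff the recording interval to the
    adjacent record exceeds ``gap_threshold_s`` (strict) AND the step total
    of the containing clock hour is below ``hourly_step_threshold`` (strict);
    otherwise ``active``.  The interval is the gap to the immediately
    preceding record, except for the first record of a participant-day,
    which uses the gap to the following record.

    Returns a copy of ``hr_df`` sorted by participant and time with added
    columns ``gap_s``, ``hour_steps``, ``context_resolved`` and the boolean
    ``nonactive``.
    """
    cols = ["participant_id", "timestamp", "hr_bpm", "context"]
    if len(hr_df) == 0:
        out = hr_df.copy()
        for c in ("gap_s", "hour_steps", "context_resolved", "nonactive"):
            out[c] = pd.Series(dtype=float if c in ("gap_s", "hour_steps") else object)
        return out
    _require_columns(hr_df, cols, "hr")
    if hourly is None:
        hourly = (hourly_steps(step_df, fill="sparse") if step_df is not None
                  else pd.DataFrame(columns=["participant_id", "hour", "steps"]))

    df = hr_df.copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    df = df.sort_values(["participant_id", "timestamp"], kind="stable")
    df = df.reset_index(drop=True)

    ts = df["timestamp"]
    pid = df["participant_id"]
    same_prev = pid.eq(pid.shift(1))
    same_next = pid.eq(pid.shift(-1))
    gap_prev = (ts - ts.shift(1)).dt.total_seconds().where(same_prev)
    gap_next = (ts.shift(-1) - ts).dt.total_seconds().where(same_next)

    date = ts.dt.normalize()
    first_of_day = ~(same_prev & date.eq(date.shift(1)))
    gap = gap_prev.where(~first_of_day, gap_next)
    gap = gap.fillna(gap_prev).fillna(gap_next).fillna(np.inf)
    df["gap_s"] = gap

    df["hour"] = ts.dt.floor("h")
    hourly = hourly.rename(columns={"steps": "hour_steps"})
    df = df.merge(hourly[["participant_id", "hour", "hour_steps"]],
                  on=["participant_id", "hour"], how="left")
    df["hour_steps"] = (pd.to_numeric(df["hour_steps"], errors="coerce")
                        .fillna(0).astype(np.int64))

    inferred = np.where(
        (df["gap_s"] > gap_threshold_s)
        & (df["hour_steps"] < hourly_step_threshold),
        "nonactive", "active")
    df["context_resolved"] = np.where(df["context"].isin(["active", "sedentary"]),
                                      df["context"], inferred)
    df["nonactive"] = df["context_resolved"].isin(NONACTIVE_LABELS)
    return df.drop(columns=["hour"])


# ---------------------------------------------------------------------------
# Wear time and person-day summaries
# ---------------------------------------------------------------------------

def _worn_hours(hr_df: pd.DataFrame, step_df: pd.DataFrame) -> pd.DataFrame:
    """Distinct (participant, clock hour) pairs containing at least one HR
    record or overlapped by a step interval."""
    parts = []
    if hr_df is not None and len(hr_df):
        h = pd.DataFrame({
            "participant_id": hr_df["participant_id"],
            "hour": pd.to_datetime(hr_df["timestamp"]).dt.floor("h"),
        })
        parts.append(h)
    if step_df is not None and len(step_df):
        ov = _step_hour_overlap(step_df)
        parts.append(ov[["participant_id", "hour"]])
    if not parts:
        return pd.DataFrame(columns=["participant_id", "hour"])
    return pd.concat(parts, ignore_index=True).drop_duplicates()


def wear_time(hr_df: pd.DataFrame, step_df: pd.DataFrame,
              participant_id: str, date) -> int:
    """Wear time for one participant-day: the number of distinct clock hours
    of that calendar day containing at least one HR or step record."""
    worn = _worn_hours(hr_df, step_df)
    if len(worn) == 0:
        return 0
    day = pd.Timestamp(date).normalize()
    sel = (worn["participant_id"] == participant_id) & (
        worn["hour"].dt.normalize() == day)
    return int(sel.sum())


def summarize_days(hr_df: pd.DataFrame, step_df: pd.DataFrame,
                   min_wear_hours: float = MIN_WEAR_HOURS,
                   min_daily_steps: int = MIN_DAILY_STEPS) -> pd.DataFrame:
    """One row per participant-day with any records.

    Columns: wear_hours, daily_steps, n_hr_records, valid_step_day.  A day
    is a valid step day unless wear time is below ``min_wear_hours`` or the
    day's steps are below ``min_daily_steps`` (both strict, so equality
    passes).
    """
    worn = _worn_hours(hr_df, step_df)
    if len(worn) == 0:
        return pd.DataFrame(columns=[
            "participant_id", "date", "wear_hours", "daily_steps",
            "n_hr_records", "valid_step_day"])
    worn = worn.assign(date=worn["hour"].dt.normalize())
    days = (worn.groupby(["participant_id", "date"], as_index=False)
                .agg(wear_hours=("hour", "nunique")))

    hs = hourly_steps(step_df, fill="sparse") if step_df is not None else None
    if hs is not None and len(hs):
        hs = hs.assign(date=hs["hour"].dt.normalize())
        daily = (hs.groupby(["participant_id", "date"], as_index=False)
                   .agg(daily_steps=("steps", "sum")))
        days = days.merge(daily, on=["participant_id", "date"], how="left")
        days["daily_steps"] = days["daily_steps"].fillna(0).astype(np.int64)
    else:
        days["daily_steps"] = 0

    if hr_df is not None and len(hr_df):
        hr_days = pd.DataFrame({
            "participant_id": hr_df["participant_id"],
            "date": pd.to_datetime(hr_df["timestamp"]).dt.normalize(),
        })
        counts = (hr_days.groupby(["participant_id", "date"], as_index=False)
                         .size().rename(columns={"size": "n_hr_records"}))
        days = days.merge(counts, on=["participant_id", "date"], how="left")
        days["n_hr_records"] = days["n_hr_records"].fillna(0).astype(np.int64)
    else:
        days["n_hr_records"] = 0

    days["valid_step_day"] = ((days["wear_hours"] >= min_wear_hours)
                              & (days["daily_steps"] >= min_daily_steps))
    return days.sort_values(["participant_id", "date"]).reset_index(drop=True)


def summarize_participants(day_df: pd.DataFrame, labeled_hr: pd.DataFrame,
                           min_days: int = MIN_DAYS,
                           restrict_hr_to_valid_days: bool = False,
                           ) -> pd.DataFrame:
    """Participant-level watch summaries and inclusion flags.

    ``nonactive_hr_mean`` is the unweighted mean of all nonactive-labeled HR
    values over the whole study period (by default including records on
    invalid step days — the day-validity thresholds belong to the step
    analysis; set ``restrict_hr_to_valid_days`` to change this).
    ``mean_daily_steps`` averages daily totals over valid step days only.
    Inclusion requires ``min_days`` or more contributing days (inclusive),
    separately for the HR analysis (days with HR records), the step analysis
    (valid step days) and the joint primary sample (both).
    """
    hr = labeled_hr
    if restrict_hr_to_valid_days and len(hr) and len(day_df):
        valid = day_df.loc[day_df["valid_step_day"],
                           ["participant_id", "date"]]
        hr = hr.assign(date=pd.to_datetime(hr["timestamp"]).dt.normalize())
        hr = hr.merge(valid, on=["participant_id", "date"], how="inner")

    if len(hr):
        na = hr[hr["nonactive"]]
        hr_stats = (na.groupby("participant_id")
                      .agg(nonactive_hr_mean=("hr_bpm", "mean"),
                           n_nonactive_records=("hr_bpm", "size")))
    else:
        hr_stats = pd.DataFrame(columns=["nonactive_hr_mean", "n_nonactive_records"])

    if len(day_df):
        day_stats = day_df.groupby("participant_id").agg(
            n_hr_days=("n_hr_records", lambda s: int((s > 0).sum())),
            n_step_days=("valid_step_day", "sum"),
            median_wear_hours=("wear_hours", "median"),
        )
        valid_days = day_df[day_df["valid_step_day"]]
        step_means = (valid_days.groupby("participant_id")
                      .agg(mean_daily_steps=("daily_steps", "mean")))
    else:
        day_stats = pd.DataFrame(columns=["n_hr_days", "n_step_days",
                                          "median_wear_hours"])
        step_means = pd.DataFrame(columns=["mean_daily_steps"])

    out = day_stats.join([step_means, hr_stats], how="outer")
    for c in ("n_hr_days", "n_step_days", "n_nonactive_records"):
        out[c] = out[c].fillna(0).astype(np.int64)
    out["no_nonactive_records"] = out["n_nonactive_records"] == 0
    out["included_hr"] = out["n_hr_days"] >= min_days
    out["included_steps"] = out["n_step_days"] >= min_days
    out["included_primary"] = out["included_hr"] & out["included_steps"]
    return out.rename_axis("participant_id").reset_index()


def process_watch(hr_df: pd.DataFrame, step_df: pd.DataFrame,
                  min_wear_hours: float = MIN_WEAR_HOURS,
                  min_daily_steps: int = MIN_DAILY_STEPS,
                  min_days: int = MIN_DAYS,
                  restrict_hr_to_valid_days: bool = False,
                  ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Full watch stage: context inference, day summaries, participant
    summaries.  Returns ``(labeled_hr, day_summaries, participant_summaries)``.
    """
    hourly = hourly_steps(step_df, fill="sparse")
    labeled = infer_motion_context(hr_df, hourly=hourly)
    days = summarize_days(hr_df, step_df, min_wear_hours, min_daily_steps)
    participants = summarize_participants(
        days, labeled, min_days, restrict_hr_to_valid_days)
    return labeled, days, participants
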