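"""Synthetic cohort, smartwatch-stream and CPET-session generator.

Every downstream stage of the pipeline is exercised against data from this
module, which plants a known ground truth: a single latent fitness factor per
participant drives their nonactive heart rate (negatively), their habitual
daily steps (positively) and all six CPET indices, so recovery of the planted
links can be tested end to end.

The smartwatch stream emulates the interval-frequency signature that makes
motion-context inference possible: HR records written while the wearer is
active arrive less than one minute apart ~99% of the time, while sedentary
records arrive more than one minute apart ~99% of the time, and hours
containing activity carry at least 30 steps.  Activity is modelled as a
two-state (active/sedentary) Markov chain on the clock-hour grid inside a
daily wear window, so each clock hour has a single true context — the same
granularity at which the inference rule reads hourly step totals.

The CPET session emulates a cycle-ergometer ramp protocol: 3 minutes of
unloaded pedalling followed by an incremental ramp, with VCO2 piecewise
linear in VO2 and a slope break planted at the true ventilatory anaerobic
threshold (the V-slope geometry).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import GAP_THRESHOLD_S, HOURLY_STEP_THRESHOLD

_EPOCH = pd.Timestamp("2019-01-01 00:00:00")

HR_COLUMNS = ["participant_id", "timestamp", "hr_bpm", "context"]
STEP_COLUMNS = ["participant_id", "start", "end", "steps"]
BREATH_COLUMNS = [
    "participant_id", "time_s", "vo2_mlkgmin", "vco2_mlkgmin",
    "ve_lmin", "hr_bpm", "workload_w", "phase",
]


# ---------------------------------------------------------------------------
# Parameters and validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortParams:
    """Generator settings.  Defaults emulate the source-study marginals
    (age 53 +/- 9 y, nonactive HR 73 +/- 6 bpm, 7269 +/- 2760 steps/day,
    ~14 h/day wear over a 65-227-day follow-up)."""

    n_participants: int = 662
    follow_up_days_range: tuple[int, int] = (65, 227)
    seed: int = 0

    # latent fitness factor and the planted links
    latent_fitness_sd: float = 1.0
    beta_hr_per_sd_fitness: float = -2.4      # bpm per SD fitness
    beta_steps_per_sd_fitness: float = 1000.0  # steps/day per SD fitness

    # smartwatch stream
    hr_mean: float = 73.0                 # population nonactive HR, bpm
    hr_between_sd: float = 5.0            # between-person residual, bpm
    hr_noise_sd: float = 3.0              # per-record noise, bpm
    active_hr_boost: float = 25.0         # mean HR elevation while active
    steps_mean: float = 7269.0
    steps_between_sd: float = 1800.0
    steps_day_sd: float = 1500.0
    active_fraction: float = 0.18         # share of worn hours active
    active_bout_mean_hours: float = 1.0
    wear_hours_mean: float = 14.0
    wear_hours_sd: float = 1.0
    low_wear_day_prob: float = 0.03       # occasional near-empty days
    waking_start_hour: int = 7
    waking_end_hour: int = 22
    active_gap_median_s: float = 45.0
    sedentary_gap_median_s: float = 1500.0
    gap_leakage: float = 0.01             # P(gap on the wrong side of 60 s)
    step_leakage: float = 0.01            # P(hourly steps on the wrong side of 30)
    context_label_fraction: float = 0.31  # records with a device label
    watch_nonuse_fraction: float = 0.05

    # covariates
    age_mean: float = 53.0
    age_sd: float = 9.0
    female_fraction: float = 0.59
    bmi_mean: float = 28.0
    bmi_sd: float = 5.0
    bmi_fitness_slope: float = -1.0       # kg/m2 per SD fitness
    covariate_missing_rate: float = 0.004  # per lab variable

    # CPET session
    cpet_noise_sd: float = 1.0            # mL/kg/min additive noise
    cpet_ramp_rates: tuple[float, ...] = (15.0, 25.0)  # W/min
    breath_dt_s: float = 2.0
    unloaded_duration_s: float = 180.0
    ramp_duration_range_s: tuple[float, float] = (480.0, 600.0)
    ve_vco2_mean: float = 27.0

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError(
                f"n_participants must be >= 1 (got {self.n_participants})")
        for name in ("latent_fitness_sd", "hr_noise_sd", "hr_between_sd",
                     "steps_between_sd", "steps_day_sd", "wear_hours_sd",
                     "age_sd", "bmi_sd", "cpet_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0 (got {getattr(self, name)})")
        for name in ("active_fraction", "gap_leakage", "step_leakage",
                     "context_label_fraction", "watch_nonuse_fraction",
                     "female_fraction", "low_wear_day_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1] (got {v})")
        if self.wear_hours_mean < 0:
            raise ValueError(
                f"wear_hours_mean must be >= 0 (got {self.wear_hours_mean})")
        lo, hi = self.follow_up_days_range
        if lo < 1 or hi < lo:
            raise ValueError(
                f"follow_up_days_range must satisfy 1 <= lo <= hi "
                f"(got {self.follow_up_days_range})")
        if any(r <= 0 for r in self.cpet_ramp_rates):
            raise ValueError(
                f"cpet_ramp_rates must be positive (got {self.cpet_ramp_rates})")
        if self.active_bout_mean_hours < 1.0:
            raise ValueError(
                f"active_bout_mean_hours must be >= 1 hour "
                f"(got {self.active_bout_mean_hours})")


def replace(params: CohortParams, **kwargs) -> CohortParams:
    """Copy *params* with fields overridden (re-validates)."""
    return dataclasses.replace(params, **kwargs)


# ---------------------------------------------------------------------------
# Cohort covariates and ground truth
# ---------------------------------------------------------------------------

def generate_cohort(params: CohortParams,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the covariate table and per-participant ground truth.

    Returns ``(covariates, ground_truth)``.  Covariates cover everything the
    fully adjusted regression model needs; the ground-truth table records
    the latent fitness of each participant and the true values of every
    quantity the pipeline later estimates.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_participants
    pid = np.array([f"P{i:05d}" for i in range(n)])

    fitness = rng.normal(0.0, params.latent_fitness_sd, n)

    female = rng.random(n) < params.female_fraction
    sex = np.where(female, "female", "male")
    age = np.clip(rng.normal(params.age_mean, params.age_sd, n), 25, 85)
    race = rng.choice(["White", "Black", "Asian", "Other"], n,
                      p=[0.91, 0.03, 0.03, 0.03])
    height = np.where(female, rng.normal(161.8, 6.8, n), rng.normal(175.3, 7.1, n))
    bmi = np.clip(
        rng.normal(params.bmi_mean, params.bmi_sd, n)
        + params.bmi_fitness_slope * fitness, 16, 55)
    weight = bmi * (height / 100.0) ** 2

    total_chol = np.clip(rng.normal(190, 35, n), 90, 400)
    hdl = np.clip(np.where(female, rng.normal(65, 16, n), rng.normal(50, 13, n)),
                  20, 130)
    glucose = np.clip(rng.normal(95, 12, n), 60, 250)
    glucose_treated = rng.random(n) < 0.03
    diabetes = (glucose >= 126) | glucose_treated
    resting_sbp = np.clip(rng.normal(120, 14, n) - 1.0 * fitness, 85, 210)
    htn_treatment = rng.random(n) < 0.18
    lipid_treatment = rng.random(n) < 0.20
    hr_lowering_treatment = rng.random(n) < 0.12
    current_smoker = rng.random(n) < 0.07
    prevalent_cvd = rng.random(n) < 0.03
    season = rng.choice(["winter", "spring", "summer", "autumn"], n)
    state = rng.choice(["MA", "NH", "RI", "CT", "NY", "FL"], n,
                       p=[0.82, 0.06, 0.05, 0.04, 0.02, 0.01])

    lo, hi = params.follow_up_days_range
    follow_up_days = rng.integers(lo, hi + 1, n)
    watch_user = rng.random(n) >= params.watch_nonuse_fraction

    # sparse missingness in the lab covariates (exercises complete-case drop)
    def _miss(x):
        x = x.astype(float).copy()
        x[rng.random(n) < params.covariate_missing_rate] = np.nan
        return x

    covariates = pd.DataFrame({
        "participant_id": pid,
        "age": age,
        "sex": sex,
        "race": race,
        "height_cm": height,
        "weight_kg": weight,
        "bmi": bmi,
        "current_smoker": current_smoker.astype(int),
        "total_cholesterol": _miss(total_chol),
        "hdl": _miss(hdl),
        "fasting_glucose": _miss(glucose),
        "diabetes": diabetes.astype(int),
        "resting_sbp": resting_sbp,
        "prevalent_cvd": prevalent_cvd.astype(int),
        "lipid_treatment": lipid_treatment.astype(int),
        "htn_treatment": htn_treatment.astype(int),
        "hr_lowering_treatment": hr_lowering_treatment.astype(int),
        "season": season,
        "state": state,
        "follow_up_days": follow_up_days,
        "watch_user": watch_user.astype(int),
    })

    ln_peak = (np.log(np.where(female, 21.6, 26.6))
               + 0.25 * fitness + rng.normal(0, 0.08, n))
    true_peak_vo2 = np.exp(ln_peak)
    true_vat_vo2 = true_peak_vo2 * rng.uniform(0.45, 0.65, n)
    pred_max_hr = 208.0 - 0.7 * age
    true_peak_hr = pred_max_hr * np.clip(
        0.904 + 0.03 * fitness + rng.normal(0, 0.05, n), 0.6, 1.1)
    ground_truth = pd.DataFrame({
        "participant_id": pid,
        "latent_fitness": fitness,
        "true_nonactive_hr": (params.hr_mean
                              + params.beta_hr_per_sd_fitness * fitness
                              + rng.normal(0, params.hr_between_sd, n)),
        "true_mean_daily_steps": np.clip(
            params.steps_mean + params.beta_steps_per_sd_fitness * fitness
            + rng.normal(0, params.steps_between_sd, n), 500, None),
        "true_peak_vo2": true_peak_vo2,
        "true_vat_vo2": true_vat_vo2,
        "true_peak_hr": true_peak_hr,
        "true_ve_vco2_nadir": np.clip(
            params.ve_vco2_mean - 1.2 * fitness + rng.normal(0, 1.8, n), 20, None),
        "true_sbp_w_slope": np.clip(
            0.34 - 0.05 * fitness + rng.normal(0, 0.09, n), 0.05, 1.0),
    })
    return covariates, ground_truth


# ---------------------------------------------------------------------------
# Smartwatch stream
# ---------------------------------------------------------------------------

def _gap_sigma(median_s: float, leakage: float) -> float:
    """Log-normal sigma putting mass 1-leakage on the correct side of the
    60-s threshold (calibrated exactly from the configured separation)."""
    p = 1.0 - (leakage if leakage > 0 else 0.01)
    return abs(np.log(GAP_THRESHOLD_S) - np.log(median_s)) / stats.norm.ppf(p)


def _draw_gaps(rng: np.random.Generator, size: int, median_s: float,
               leakage: float, side: str) -> np.ndarray:
    """Draw record gaps.  With leakage 0 the distribution is truncated so
    every gap falls strictly on the required side of the 60-s threshold."""
    mu = np.log(median_s)
    sigma = _gap_sigma(median_s, leakage)
    if leakage > 0:
        return rng.lognormal(mu, sigma, size)
    # inverse-CDF sampling from the truncated log-normal; the "above" side
    # is truncated one second past the threshold so that flooring the
    # timestamps to whole seconds cannot pull a gap back onto it
    if side == "below":
        f = stats.norm.cdf((np.log(GAP_THRESHOLD_S) - mu) / sigma)
        u = rng.uniform(0.0, f * (1 - 1e-12), size)
    else:
        f = stats.norm.cdf((np.log(GAP_THRESHOLD_S + 1.0) - mu) / sigma)
        u = rng.uniform(f + (1 - f) * 1e-12, 1.0, size)
    return np.exp(mu + sigma * stats.norm.ppf(u))


def _span_record_offsets(rng: np.random.Generator, span_s: float,
                         median_s: float, leakage: float, side: str,
                         first_offset_floor: float = 0.0) -> np.ndarray:
    """Cumulative record offsets within one contiguous same-state span."""
    est = max(8, int(span_s / median_s * 2) + 8)
    gaps = _draw_gaps(rng, est, median_s, leakage, side)
    while gaps.sum() < span_s:
        gaps = np.concatenate(
            [gaps, _draw_gaps(rng, est, median_s, leakage, side)])
    t = np.cumsum(gaps)
    if first_offset_floor > 0 and t.size and t[0] < first_offset_floor:
        t = t + (first_offset_floor - t[0])
    return t[t < span_s]


def _markov_states(rng: np.random.Generator, n_hours: int,
                   params: CohortParams) -> np.ndarray:
    """Hourly active(1)/sedentary(0) states from a two-state Markov chain
    with stationary active share ``active_fraction`` and the configured mean
    active-bout length."""
    af = params.active_fraction
    if af <= 0 or n_hours == 0:
        return np.zeros(n_hours, dtype=int)
    if af >= 1:
        return np.ones(n_hours, dtype=int)
    p_as = min(1.0, 1.0 / params.active_bout_mean_hours)   # active -> sedentary
    p_sa = min(1.0, af / (1.0 - af) * p_as)                # sedentary -> active
    states = np.empty(n_hours, dtype=int)
    states[0] = int(rng.random() < af)
    u = rng.random(n_hours)
    for h in range(1, n_hours):
        if states[h - 1] == 1:
            states[h] = 0 if u[h] < p_as else 1
        else:
            states[h] = 1 if u[h] < p_sa else 0
    return states


def generate_watch_stream(participant: pd.Series, ground_truth: pd.Series,
                          params: CohortParams, rng: np.random.Generator,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the HR and step streams for one participant.

    Returns ``(hr_records, step_records)``.  The HR frame carries both the
    public ``context`` column (device label present for a configurable
    fraction of records, otherwise ``unknown``) and the private
    ``true_context`` ground truth.  Step records are written per worn clock
    hour.  Non-wear periods contain no records.
    """
    empty_hr = pd.DataFrame(columns=HR_COLUMNS + ["true_context"])
    empty_steps = pd.DataFrame(columns=STEP_COLUMNS)
    n_days = int(participant["follow_up_days"])
    if (not bool(participant.get("watch_user", 1))
            or params.wear_hours_mean == 0 or n_days == 0):
        return empty_hr, empty_steps

    window_len = params.waking_end_hour - params.waking_start_hour
    base_hr = float(ground_truth["true_nonactive_hr"])
    daily_target_mean = float(ground_truth["true_mean_daily_steps"])

    rec_t: list[np.ndarray] = []
    rec_active: list[np.ndarray] = []
    step_rows: list[tuple[int, int, int]] = []   # (hour_epoch_s, end, count)

    for day in range(n_days):
        if rng.random() < params.low_wear_day_prob:
            n_wear = int(rng.integers(0, 5))
        else:
            n_wear = int(round(np.clip(
                rng.normal(params.wear_hours_mean, params.wear_hours_sd),
                0, window_len)))
        if n_wear == 0:
            continue
        day_start = day * 86400 + params.waking_start_hour * 3600
        states = _markov_states(rng, n_wear, params)
        active_hours = np.flatnonzero(states == 1)

        # contiguous same-state spans -> HR records
        bounds = np.flatnonzero(np.diff(states) != 0) + 1
        for a, b in zip(np.r_[0, bounds], np.r_[bounds, n_wear]):
            span_start = day_start + a * 3600
            span_len = (b - a) * 3600.0
            if states[a] == 1:
                # floor the first active record past the 60-s threshold so
                # a preceding lone sedentary record keeps a >1-min gap even
                # after timestamps are floored to whole seconds
                off = _span_record_offsets(
                    rng, span_len, params.active_gap_median_s,
                    params.gap_leakage, "below",
                    first_offset_floor=GAP_THRESHOLD_S + 2.0)
            else:
                off = _span_record_offsets(
                    rng, span_len, params.sedentary_gap_median_s,
                    params.gap_leakage, "above")
            rec_t.append(span_start + off)
            rec_active.append(np.full(off.size, states[a]))

        # step records: one per worn hour
        target = max(0.0, daily_target_mean
                     + rng.normal(0, params.steps_day_sd))
        counts = np.zeros(n_wear, dtype=int)
        if active_hours.size:
            props = rng.dirichlet(np.full(active_hours.size, 8.0))
            counts[active_hours] = np.maximum(
                HOURLY_STEP_THRESHOLD, np.round(target * props).astype(int))
        for h in range(n_wear):
            c = counts[h]
            if states[h] == 1:
                if rng.random() < params.step_leakage:
                    c = int(rng.integers(0, HOURLY_STEP_THRESHOLD))
            else:
                c = int(rng.integers(0, HOURLY_STEP_THRESHOLD))
                if rng.random() < params.step_leakage:
                    c = int(rng.integers(HOURLY_STEP_THRESHOLD, 120))
            step_rows.append((day_start + h * 3600, day_start + (h + 1) * 3600, c))

    if not rec_t:
        return empty_hr, empty_steps
    t = np.concatenate(rec_t)
    active = np.concatenate(rec_active).astype(bool)
    order = np.argsort(t, kind="stable")
    t, active = t[order], active[order]
    t = np.floor(t).astype(np.int64)
    keep = np.r_[True, np.diff(t) > 0]   # second resolution, strictly increasing
    t, active = t[keep], active[keep]

    hr = np.clip(base_hr
                 + np.where(active, params.active_hr_boost, 0.0)
                 + rng.normal(0, params.hr_noise_sd, t.size), 25, 220)
    true_ctx = np.where(active, "active", "sedentary")
    labeled = rng.random(t.size) < params.context_label_fraction
    context = np.where(labeled, true_ctx, "unknown")

    hr_df = pd.DataFrame({
        "participant_id": participant["participant_id"],
        "timestamp": _EPOCH + pd.to_timedelta(t, unit="s"),
        "hr_bpm": np.round(hr).astype(int),
        "context": context,
        "true_context": true_ctx,
    })
    steps_df = pd.DataFrame(step_rows, columns=["start_s", "end_s", "steps"])
    steps_df = pd.DataFrame({
        "participant_id": participant["participant_id"],
        "start": _EPOCH + pd.to_timedelta(steps_df["start_s"], unit="s"),
        "end": _EPOCH + pd.to_timedelta(steps_df["end_s"], unit="s"),
        "steps": steps_df["steps"].astype(int),
    })
    return hr_df, steps_df


# ---------------------------------------------------------------------------
# CPET session
# ---------------------------------------------------------------------------

def generate_cpet_session(participant: pd.Series, ground_truth: pd.Series,
                          params: CohortParams, rng: np.random.Generator,
                          ) -> tuple[pd.DataFrame, dict]:
    """Generate one breath-by-breath gas-exchange session plus blood
    pressures.

    VO2 rises (in expectation) linearly through the ramp to the true peak;
    VCO2 is piecewise linear in VO2 with the slope break planted at the true
    VAT; VE tracks VCO2 at the participant's planted ventilatory-efficiency
    ratio (with a shallow U so the nadir is identified); a short recovery
    phase is appended.  Returns ``(breath_frame, sbp_row)``.
    """
    peak = float(ground_truth["true_peak_vo2"])
    vat = float(ground_truth["true_vat_vo2"])
    if not vat < peak:
        raise ValueError("true_vat_vo2 must be below true_peak_vo2")
    ramp_rate = float(rng.choice(params.cpet_ramp_rates))
    if ramp_rate <= 0:
        raise ValueError(f"ramp rate must be positive (got {ramp_rate})")

    dt = params.breath_dt_s
    t_unloaded = params.unloaded_duration_s
    ramp_dur = rng.uniform(*params.ramp_duration_range_s)
    t_recovery = 60.0
    time = np.arange(0.0, t_unloaded + ramp_dur + t_recovery, dt)
    phase = np.where(time < t_unloaded, "unloaded",
                     np.where(time < t_unloaded + ramp_dur, "ramp", "recovery"))

    vo2_0 = rng.uniform(4.5, 6.0)
    ramp_frac = np.clip((time - t_unloaded) / ramp_dur, 0.0, 1.0)
    vo2 = vo2_0 + (peak - vo2_0) * ramp_frac
    rec = phase == "recovery"
    if rec.any():
        rec_frac = (time[rec] - (t_unloaded + ramp_dur)) / t_recovery
        vo2[rec] = peak - (peak * 0.4) * rec_frac

    s1 = rng.uniform(0.85, 0.95)
    s2 = rng.uniform(1.30, 1.50)
    c0 = (0.85 - s1) * vo2_0
    vco2 = c0 + s1 * vo2 + (s2 - s1) * np.maximum(vo2 - vat, 0.0)

    # ventilatory-efficiency ratio: shallow U with its planted nadir inside
    # the exercise span
    ratio0 = float(ground_truth["true_ve_vco2_nadir"])
    t_end_ex = t_unloaded + ramp_dur
    u = (time - 0.6 * t_end_ex) / t_end_ex
    ratio = ratio0 + 4.0 * u ** 2
    weight = float(participant["weight_kg"])
    ve = ratio * vco2 * weight / 1000.0

    hr_rest = float(ground_truth["true_nonactive_hr"]) + 15.0
    hr = hr_rest + (float(ground_truth["true_peak_hr"]) - hr_rest) * ramp_frac
    if rec.any():
        hr[rec] = hr[rec] - 20.0 * rec_frac

    workload = np.where(phase == "ramp",
                        ramp_rate * (time - t_unloaded) / 60.0, 0.0)
    peak_workload = ramp_rate * ramp_dur / 60.0

    ns = params.cpet_noise_sd
    vo2 = np.clip(vo2 + rng.normal(0, ns, time.size), 0.5, None)
    vco2 = np.clip(vco2 + rng.normal(0, ns, time.size), 0.5, None)
    ve = np.clip(ve + rng.normal(0, ns, time.size), 0.5, None)
    hr = np.clip(hr + rng.normal(0, 2.0 if ns > 0 else 0.0, time.size), 30, 230)

    breath = pd.DataFrame({
        "participant_id": participant["participant_id"],
        "time_s": time,
        "vo2_mlkgmin": vo2,
        "vco2_mlkgmin": vco2,
        "ve_lmin": ve,
        "hr_bpm": hr,
        "workload_w": workload,
        "phase": phase,
    })
    rest_sbp = float(np.clip(
        participant["resting_sbp"] + rng.normal(0, 4.0 if ns > 0 else 0.0),
        80, 220))
    peak_sbp = rest_sbp + float(ground_truth["true_sbp_w_slope"]) * peak_workload
    if ns > 0:
        peak_sbp += rng.normal(0, 4.0)
    sbp_row = {
        "participant_id": participant["participant_id"],
        "rest_sbp": round(rest_sbp, 1),
        "peak_sbp": round(peak_sbp, 1),
        "peak_workload_w": round(peak_workload, 1),
    }
    return breath, sbp_row


# ---------------------------------------------------------------------------
# Whole-study convenience wrapper
# ---------------------------------------------------------------------------

@dataclass
class StudyData:
    """All generated tables for one synthetic study."""
    covariates: pd.DataFrame
    ground_truth: pd.DataFrame
    hr: pd.DataFrame          # includes the private true_context column
    steps: pd.DataFrame
    breath: pd.DataFrame
    sbp: pd.DataFrame
    params: CohortParams


def generate_study(params: CohortParams) -> StudyData:
    """Generate the full study: cohort, watch streams and CPET sessions.

    All randomness descends from ``params.seed`` through a seed tree, so the
    output is bit-identical across runs for a fixed seed.
    """
    root = np.random.SeedSequence(params.seed)
    ss_cohort, ss_watch, ss_cpet = root.spawn(3)
    covariates, ground_truth = generate_cohort(
        params, np.random.default_rng(ss_cohort))

    hr_parts, step_parts, breath_parts, sbp_rows = [], [], [], []
    watch_seeds = ss_watch.spawn(params.n_participants)
    cpet_seeds = ss_cpet.spawn(params.n_participants)
    for i in range(params.n_participants):
        person = covariates.iloc[i]
        gt = ground_truth.iloc[i]
        hr_df, steps_df = generate_watch_stream(
            person, gt, params, np.random.default_rng(watch_seeds[i]))
        if len(hr_df):
            hr_parts.append(hr_df)
        if len(steps_df):
            step_parts.append(steps_df)
        breath, sbp_row = generate_cpet_session(
            person, gt, params, np.random.default_rng(cpet_seeds[i]))
        breath_parts.append(breath)
        sbp_rows.append(sbp_row)

    empty_hr = pd.DataFrame(columns=HR_COLUMNS + ["true_context"])
    empty_steps = pd.DataFrame(columns=STEP_COLUMNS)
    return StudyData(
        covariates=covariates,
        ground_truth=ground_truth,
        hr=pd.concat(hr_parts, ignore_index=True) if hr_parts else empty_hr,
        steps=pd.concat(step_parts, ignore_index=True) if step_parts else empty_steps,
        breath=pd.concat(breath_parts, ignore_index=True),
        sbp=pd.DataFrame(sbp_rows),
        params=params,
    )


def write_study_csvs(study: StudyData, out_dir: str | Path) -> dict[str, Path]:
    """Write the input CSV dialects consumed by the processing stages, plus
    the ground truth.  The public HR CSV omits the true context, which goes
    to a separate truth file."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    hr_pub = study.hr[HR_COLUMNS].copy()
    paths["hr"] = out / "hr.csv"
    hr_pub.to_csv(paths["hr"], index=False)

    paths["steps"] = out / "steps.csv"
    study.steps[STEP_COLUMNS].to_csv(paths["steps"], index=False)

    paths["breath"] = out / "breath.csv"
    study.breath.to_csv(paths["breath"], index=False)

    paths["sbp"] = out / "sbp.csv"
    study.sbp.to_csv(paths["sbp"], index=False)

    paths["covariates"] = out / "covariates.csv"
    study.covariates.to_csv(paths["covariates"], index=False)

    paths["ground_truth"] = out / "ground_truth.csv"
    study.ground_truth.to_csv(paths["ground_truth"], index=False)

    truth = study.hr[["participant_id", "timestamp", "true_context"]]
    paths["hr_truth"] = out / "hr_truth.csv"
    truth.to_csv(paths["hr_truth"], index=False)
    return paths
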