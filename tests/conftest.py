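"""Shared fixtures and synthetic-session builders for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wearcpet.synth import CohortParams, generate_study

BASE = pd.Timestamp("2019-01-01")


def make_ramp_session(break_vo2: float = 13.0, s1: float = 0.9,
                      s2: float = 1.3, n_ramp: int = 270, dt: float = 2.0,
                      vo2_0: float = 5.0, peak: float = 25.0,
                      noise_sd: float = 0.0, unloaded_s: float = 180.0,
                      recovery_s: float = 0.0, ve_ratio: float = 27.0,
                      hr_peak: float = 170.0,
                      rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Deterministic piecewise-linear gas-exchange session on a regular
    grid; VCO2 breaks slope at ``break_vo2`` (the planted VAT)."""
    rng = rng or np.random.default_rng(0)
    t = np.arange(0.0, unloaded_s + n_ramp * dt + recovery_s + dt / 2, dt)
    phase = np.where(t < unloaded_s, "unloaded",
                     np.where(t <= unloaded_s + n_ramp * dt, "ramp", "recovery"))
    frac = np.clip((t - unloaded_s) / (n_ramp * dt), 0.0, 1.0)
    vo2 = vo2_0 + (peak - vo2_0) * frac
    vo2[phase == "recovery"] = peak * 0.8
    vco2 = 0.85 * vo2_0 + s1 * (vo2 - vo2_0) + (s2 - s1) * np.maximum(
        vo2 - break_vo2, 0.0)
    hr = 90.0 + (hr_peak - 90.0) * frac
    if noise_sd > 0:
        vo2 = vo2 + rng.normal(0, noise_sd, t.size)
        vco2 = vco2 + rng.normal(0, noise_sd, t.size)
    return pd.DataFrame({
        "participant_id": "T0001",
        "time_s": t,
        "vo2_mlkgmin": np.clip(vo2, 0.1, None),
        "vco2_mlkgmin": np.clip(vco2, 0.1, None),
        "ve_lmin": ve_ratio * np.clip(vco2, 0.1, None) / 10.0,
        "hr_bpm": hr,
        "workload_w": np.where(phase == "ramp", 25.0 * (t - unloaded_s) / 60.0, 0.0),
        "phase": phase,
    })


def make_random_session(rng: np.random.Generator, n: int = 300) -> pd.DataFrame:
    """Irregularly sampled session with heavily tied values, for exercising
    exact window/tie handling against brute-force oracles."""
    t = np.cumsum(rng.uniform(0.5, 4.0, n))
    n_unloaded = max(3, int(0.2 * n))
    phase = np.array(["unloaded"] * n_unloaded + ["ramp"] * (n - n_unloaded))
    # integer-valued channels force median ties
    vo2 = rng.integers(5, 40, n).astype(float)
    vco2 = rng.integers(5, 45, n).astype(float)
    return pd.DataFrame({
        "participant_id": "R0001",
        "time_s": t,
        "vo2_mlkgmin": vo2,
        "vco2_mlkgmin": vco2,
        "ve_lmin": rng.integers(10, 90, n).astype(float),
        "hr_bpm": rng.integers(60, 190, n).astype(float),
        "workload_w": np.where(phase == "ramp", np.arange(n, dtype=float), 0.0),
        "phase": phase,
    })


def brute_force_window_stat(t, v, window_s, lo, hi, mode):
    """O(n^2) oracle: extremum of trailing right-closed windowed medians
    with window ends inside [lo, hi], by explicit membership enumeration."""
    t = np.asarray(t, dtype=float)
    v = np.asarray(v, dtype=float)
    meds = []
    for end in t:
        if lo <= end <= hi:
            meds.append(np.median(v[(t > end - window_s) & (t <= end)]))
    return max(meds) if mode == "max" else min(meds)


def hr_frame(rows):
    """rows: (pid, timestamp-str, hr, context)."""
    df = pd.DataFrame(rows, columns=["participant_id", "timestamp",
                                     "hr_bpm", "context"])
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def step_frame(rows):
    """rows: (pid, start-str, end-str, steps)."""
    df = pd.DataFrame(rows, columns=["participant_id", "start", "end", "steps"])
    df["start"] = pd.to_datetime(df["start"])
    df["end"] = pd.to_datetime(df["end"])
    return df


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic study reused across read-only tests."""
    params = CohortParams(n_participants=25, follow_up_days_range=(33, 40),
                          seed=424)
    return generate_study(params)


def synthetic_analysis_table(n: int = 250, seed: int = 7,
                             beta_hr: float = -2.4,
                             beta_steps: float = 1000.0) -> pd.DataFrame:
    """Analysis table with planted links built directly from the cohort
    generator (no stream simulation), for fast battery tests."""
    from wearcpet.synth import generate_cohort
    from wearcpet.assoc import build_analysis_table

    params = CohortParams(n_participants=n, seed=seed,
                          beta_hr_per_sd_fitness=beta_hr,
                          beta_steps_per_sd_fitness=beta_steps)
    cov, gt = generate_cohort(params)
    rng = np.random.default_rng(seed + 1)
    f = gt["latent_fitness"].to_numpy()
    watch_summary = pd.DataFrame({
        "participant_id": cov["participant_id"],
        "nonactive_hr_mean": gt["true_nonactive_hr"] + rng.normal(0, 0.3, n),
        "mean_daily_steps": gt["true_mean_daily_steps"] + rng.normal(0, 300, n),
        "median_wear_hours": rng.integers(12, 16, n).astype(float),
        "n_hr_days": 100, "n_step_days": 100,
        "included_hr": True, "included_steps": True, "included_primary": True,
    })
    pred_hr = 208.0 - 0.7 * cov["age"].to_numpy()
    cpet_results = pd.DataFrame({
        "participant_id": cov["participant_id"],
        "peak_vo2": gt["true_peak_vo2"],
        "pct_predicted_peak_vo2": 99.0 + 15.0 * f + rng.normal(0, 8, n),
        "vat_vo2": gt["true_vat_vo2"],
        "ve_vco2_nadir": gt["true_ve_vco2_nadir"],
        "pct_predicted_max_hr": 100.0 * gt["true_peak_hr"] / pred_hr,
        "sbp_w_slope": gt["true_sbp_w_slope"],
        "peak_rer": rng.normal(1.12, 0.05, n),
        "adequate_effort": rng.random(n) < 0.95,
    })
    return build_analysis_table(cov, watch_summary, cpet_results)
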