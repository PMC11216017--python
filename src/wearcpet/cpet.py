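"""CPET gas-exchange processing: the six fitness indices plus peak RER.

A session is a breath-by-breath series (here on a regular grid) with columns
``time_s, vo2_mlkgmin, vco2_mlkgmin, ve_lmin, hr_bpm, workload_w, phase``
where phase is ``unloaded`` (3 min of unloaded pedalling), ``ramp``
(incremental ramp to exhaustion) or ``recovery``.

Windowed statistics use trailing, right-closed 30-second windows defined in
time: the window ending at sample time t contains the samples in (t-30, t].
"Final minute of exercise" means window ends within the last 60 s of the
ramp phase; the VE/VCO2 nadir is searched over all of exercise (unloaded +
ramp).  Recovery samples never influence any index.

The ventilatory anaerobic threshold is located with the V-slope method: a
continuous two-segment linear least-squares fit of VCO2 on VO2 over the ramp
phase, the breakpoint chosen over the grid of interior sample VO2 values
(restricted below the 90th percentile of ramp VO2 to stay clear of the
respiratory-compensation region) minimising the total residual sum of
squares, subject to the upper slope exceeding the lower.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import (
    MEDIAN_WINDOW_S,
    MIN_WINDOW_SAMPLES,
    PEAK_SEARCH_SPAN_S,
    RER_EFFORT_THRESHOLD,
    TANAKA_COEFFS,
    VSLOPE_CANDIDATE_QUANTILE,
    VSLOPE_MIN_RSS_IMPROVEMENT,
    WASSERMAN_HANSEN_COEFFS,
)

EXERCISE_PHASES = ("unloaded", "ramp")


# ---------------------------------------------------------------------------
# Rolling window medians
# ---------------------------------------------------------------------------

def rolling_median(time_s: np.ndarray, values: np.ndarray,
                   window_s: float = MEDIAN_WINDOW_S,
                   min_samples: int = MIN_WINDOW_SAMPLES,
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Trailing right-closed windowed medians.

    For each sample time t, the median of the values at times in (t - w, t].
    Returns ``(medians, thin)`` where ``thin`` flags windows holding fewer
    than ``min_samples`` samples.
    """
    t = np.asarray(time_s, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    if t.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if window_s >= t[-1] - t[0]:
        raise ValueError("window must be shorter than the series span")
    # first index strictly inside (t_j - w, t_j]
    starts = np.searchsorted(t, t - window_s, side="right")
    med = np.empty(t.size)
    counts = np.arange(1, t.size + 1) - starts
    for j in range(t.size):
        med[j] = np.median(v[starts[j]:j + 1])
    return med, counts < min_samples


def _exercise(series: pd.DataFrame) -> pd.DataFrame:
    ex = series[series["phase"].isin(EXERCISE_PHASES)]
    if len(ex) == 0:
        raise ValueError("no exercise-phase samples in series")
    return ex.sort_values("time_s")


def _ramp_bounds(series: pd.DataFrame) -> tuple[float, float]:
    ramp = series[series["phase"] == "ramp"]
    if len(ramp) == 0:
        raise ValueError("no ramp-phase samples in series")
    t = ramp["time_s"].to_numpy(dtype=float)
    return float(t.min()), float(t.max())


def _windowed_extremum(series: pd.DataFrame, values: np.ndarray,
                       t_lo: float, t_hi: float, mode: str,
                       window_s: float = MEDIAN_WINDOW_S) -> float:
    """Extremum of rolling medians whose window end falls in [t_lo, t_hi]."""
    t = series["time_s"].to_numpy(dtype=float)
    med, _ = rolling_median(t, values, window_s)
    sel = (t >= t_lo) & (t <= t_hi)
    if not sel.any():
        raise ValueError("no window ends inside the search span")
    return float(med[sel].max() if mode == "max" else med[sel].min())


def peak_vo2(series: pd.DataFrame, window_s: float = MEDIAN_WINDOW_S,
             span_s: float = PEAK_SEARCH_SPAN_S) -> float:
    """Peak VO2 (mL/kg/min): highest 30-s median with window end in the
    final minute of the ramp phase.  Recovery samples are ignored."""
    ex = _exercise(series)
    r0, r1 = _ramp_bounds(ex)
    if r1 - r0 < span_s:
        raise ValueError(
            f"ramp phase spans {r1 - r0:.0f} s; need at least {span_s:.0f} s "
            "to define the final minute of exercise")
    return _windowed_extremum(ex, ex["vo2_mlkgmin"].to_numpy(dtype=float),
                              r1 - span_s, r1, "max", window_s)


def ve_vco2_nadir(series: pd.DataFrame, weight_kg: float | None = None,
                  window_s: float = MEDIAN_WINDOW_S) -> float:
    """Ventilatory efficiency: lowest 30-s median of VE/VCO2 over exercise
    (unloaded + ramp).

    VE is in L/min; VCO2 is carried in mL/kg/min, so pass ``weight_kg`` to
    convert (omit it only if the vco2 column is already in L/min).
    """
    ex = _exercise(series)
    vco2 = ex["vco2_mlkgmin"].to_numpy(dtype=float)
    if np.any(vco2 <= 0):
        raise ValueError("VCO2 must be positive throughout exercise")
    if weight_kg is not None:
        vco2 = vco2 * weight_kg / 1000.0
    ratio = ex["ve_lmin"].to_numpy(dtype=float) / vco2
    t = ex["time_s"].to_numpy(dtype=float)
    return _windowed_extremum(ex, ratio, t[0], t[-1], "min", window_s)


def peak_rer(series: pd.DataFrame, window_s: float = MEDIAN_WINDOW_S,
             span_s: float = PEAK_SEARCH_SPAN_S) -> float:
    """Peak respiratory exchange ratio: highest 30-s median of VCO2/VO2
    with window end in the final minute of the ramp (effort marker)."""
    ex = _exercise(series)
    r0, r1 = _ramp_bounds(ex)
    rer = (ex["vco2_mlkgmin"].to_numpy(dtype=float)
           / ex["vo2_mlkgmin"].to_numpy(dtype=float))
    return _windowed_extremum(ex, rer, max(r1 - span_s, r0), r1, "max", window_s)


def peak_exercise_hr(series: pd.DataFrame,
                     window_s: float = MEDIAN_WINDOW_S) -> float:
    """Highest 30-s median HR with window end in the ramp phase."""
    ex = _exercise(series)
    r0, r1 = _ramp_bounds(ex)
    return _windowed_extremum(ex, ex["hr_bpm"].to_numpy(dtype=float),
                              r0, r1, "max", window_s)


# ---------------------------------------------------------------------------
# Prediction equations
# ---------------------------------------------------------------------------

def predicted_peak_vo2_mlmin(age: float, sex: str, height_cm: float,
                             weight_kg: float,
                             coeffs: dict | None = None) -> float:
    """Wasserman-Hansen predicted peak VO2 (mL/min) for cycle ergometry.

    Sex-specific ideal weight from height; participants above ideal weight
    get a fixed surcharge per excess kilogram, those below it an averaged
    weight.  Coefficients come from the configuration and are overridable.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be positive")
    coeffs = coeffs or WASSERMAN_HANSEN_COEFFS
    if sex not in coeffs:
        raise ValueError(f"sex must be one of {sorted(coeffs)} (got {sex!r})")
    c = coeffs[sex]
    ideal = c["iw_slope"] * height_cm + c["iw_intercept"]
    factor = c["f_intercept"] - c["f_slope"] * age
    off = c["weight_offset"]
    if weight_kg >= ideal:
        pred = (ideal + off) * factor + c["excess_slope"] * (weight_kg - ideal)
    else:
        pred = ((ideal + weight_kg) / 2.0 + off) * factor
    return pred


def percent_predicted_peak_vo2(measured_peak_vo2: float, age: float, sex: str,
                               height_cm: float, weight_kg: float,
                               coeffs: dict | None = None) -> float:
    """100 x measured peak VO2 (mL/kg/min) over the Wasserman-Hansen
    prediction scaled to body weight."""
    pred_mlmin = predicted_peak_vo2_mlmin(age, sex, height_cm, weight_kg, coeffs)
    pred_mlkgmin = pred_mlmin / weight_kg
    if pred_mlkgmin <= 0:
        raise ValueError(
            f"predicted peak VO2 is nonpositive ({pred_mlkgmin:.2f} mL/kg/min)")
    return 100.0 * measured_peak_vo2 / pred_mlkgmin


def percent_predicted_max_hr(series: pd.DataFrame, age: float,
                             coeffs: dict | None = None) -> float:
    """100 x peak exercise HR over the Tanaka-predicted maximum
    (intercept - slope x age)."""
    c = coeffs or TANAKA_COEFFS
    pred = c["intercept"] - c["slope"] * age
    return 100.0 * peak_exercise_hr(series) / pred


def sbp_w_slope(rest_sbp: float, peak_sbp: float, peak_workload_w: float) -> float:
    """(peak SBP - rest SBP) / peak workload, in mm Hg per watt.  The
    formula is signed: a hypotensive response yields a negative slope."""
    if peak_workload_w <= 0:
        raise ValueError(
            f"peak workload must be positive (got {peak_workload_w})")
    return (peak_sbp - rest_sbp) / peak_workload_w


# ---------------------------------------------------------------------------
# V-slope ventilatory anaerobic threshold
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VatFit:
    """Result of the V-slope breakpoint search."""
    vat_vo2: float                 # VO2 at the breakpoint (nan if none found)
    low_confidence: bool
    rss_improvement: float         # relative RSS gain over a single line
    slope_lower: float = np.nan
    slope_upper: float = np.nan


def detect_vat(series: pd.DataFrame,
               candidate_quantile: float = VSLOPE_CANDIDATE_QUANTILE,
               min_rss_improvement: float = VSLOPE_MIN_RSS_IMPROVEMENT,
               smooth_window_s: float | None = MEDIAN_WINDOW_S,
               ) -> VatFit:
    """Locate the VAT as the V-slope breakpoint of VCO2 vs VO2.

    Fits, for every admissible candidate breakpoint c (interior ramp-sample
    VO2 values below the ``candidate_quantile`` of ramp VO2), the continuous
    two-segment model ``vco2 = b0 + b1*vo2 + b2*max(vo2 - c, 0)`` and keeps
    the candidate minimising the residual sum of squares among fits with
    ``b2 > 0`` (upper slope strictly above the lower).  When no admissible
    candidate exists the result carries ``vat_vo2 = nan`` with the
    low-confidence flag; a fit whose RSS improvement over a single straight
    line is below ``min_rss_improvement`` is returned flagged.
    """
    ramp = series[series["phase"] == "ramp"].sort_values("time_s")
    if len(ramp) < 20:
        raise ValueError(
            f"ramp phase has {len(ramp)} samples; V-slope needs at least 20")
    x = ramp["vo2_mlkgmin"].to_numpy(dtype=float)
    y = ramp["vco2_mlkgmin"].to_numpy(dtype=float)
    t = ramp["time_s"].to_numpy(dtype=float)
    # fit on median-smoothed breath data, as V-slope reading is done on
    # averaged rather than raw breaths (noise-free data pass unchanged:
    # windowed medians of monotone series are sample values)
    if smooth_window_s is not None and t[-1] - t[0] > smooth_window_s:
        x, _ = rolling_median(t, x, smooth_window_s)
        y, _ = rolling_median(t, y, smooth_window_s)
    order = np.argsort(x, kind="stable")
    x, y = x[order], y[order]
    n = x.size

    # single-line baseline
    X1 = np.column_stack([np.ones(n), x])
    beta1, res1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    rss0 = float(res1[0]) if res1.size else float(
        np.sum((y - X1 @ beta1) ** 2))

    # candidates: interior sample VO2 values with >=2 points on each side,
    # below the configured quantile of ramp VO2
    qmax = np.quantile(x, candidate_quantile)
    cand_idx = np.arange(2, n - 2)
    cand_idx = cand_idx[x[cand_idx] <= qmax]
    cand = np.unique(x[cand_idx])
    cand = cand[(cand > x[0]) & (cand < x[-1])]
    if cand.size == 0:
        return VatFit(np.nan, True, 0.0)

    # suffix sums over the sorted samples for vectorised hinge regressions
    def suffix(a):
        return np.concatenate([np.cumsum(a[::-1])[::-1], [0.0]])

    Tn = suffix(np.ones(n))
    Tx, Txx = suffix(x), suffix(x * x)
    Ty, Txy = suffix(y), suffix(x * y)
    Sy, Sx, Sxx, Sxy = Ty[0], Tx[0], Txx[0], Txy[0]
    Syy = float(np.sum(y * y))

    j = np.searchsorted(x, cand, side="right")
    nh, tx, txx = Tn[j], Tx[j], Txx[j]
    ty, txy = Ty[j], Txy[j]
    Sh = tx - cand * nh
    Shh = txx - 2 * cand * tx + cand ** 2 * nh
    Sxh = txx - cand * tx
    Shy = txy - cand * ty

    k = cand.size
    A = np.empty((k, 3, 3))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = Sx
    A[:, 0, 2] = A[:, 2, 0] = Sh
    A[:, 1, 1] = Sxx
    A[:, 1, 2] = A[:, 2, 1] = Sxh
    A[:, 2, 2] = Shh
    b = np.stack([np.full(k, Sy), np.full(k, Sxy), Shy], axis=1)
    beta = np.einsum("kij,kj->ki", np.linalg.pinv(A), b)
    rss = Syy - np.einsum("ki,ki->k", beta, b)
    rss = np.maximum(rss, 0.0)

    admissible = beta[:, 2] > 0
    if not admissible.any():
        return VatFit(np.nan, True, 0.0)
    rss_adm = np.where(admissible, rss, np.inf)
    best = int(np.argmin(rss_adm))
    improvement = (rss0 - rss[best]) / rss0 if rss0 > 1e-12 else 0.0
    return VatFit(
        vat_vo2=float(cand[best]),
        low_confidence=bool(improvement < min_rss_improvement),
        rss_improvement=float(improvement),
        slope_lower=float(beta[best, 1]),
        slope_upper=float(beta[best, 1] + beta[best, 2]),
    )


# ---------------------------------------------------------------------------
# Session-level result
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CPETResult:
    """The six fitness indices plus peak RER for one session."""
    participant_id: str
    peak_vo2: float
    pct_predicted_peak_vo2: float
    vat_vo2: float
    ve_vco2_nadir: float
    pct_predicted_max_hr: float
    sbp_w_slope: float
    peak_rer: float
    adequate_effort: bool          # peak RER >= 1.05 (inclusive)
    flags: tuple[str, ...] = ()


def process_session(series: pd.DataFrame, rest_sbp: float, peak_sbp: float,
                    peak_workload_w: float, age: float, sex: str,
                    height_cm: float, weight_kg: float) -> CPETResult:
    """Compute all indices for one participant's session."""
    flags = []
    pv = peak_vo2(series)
    vat = detect_vat(series)
    if vat.low_confidence:
        flags.append("vat_low_confidence")
    slope = sbp_w_slope(rest_sbp, peak_sbp, peak_workload_w)
    if slope < 0:
        flags.append("hypotensive_response")
    rer = peak_rer(series)
    return CPETResult(
        participant_id=str(series["participant_id"].iloc[0]),
        peak_vo2=pv,
        pct_predicted_peak_vo2=percent_predicted_peak_vo2(
            pv, age, sex, height_cm, weight_kg),
        vat_vo2=vat.vat_vo2,
        ve_vco2_nadir=ve_vco2_nadir(series, weight_kg),
        pct_predicted_max_hr=percent_predicted_max_hr(series, age),
        sbp_w_slope=slope,
        peak_rer=rer,
        adequate_effort=bool(rer >= RER_EFFORT_THRESHOLD),
        flags=tuple(flags),
    )


def process_cpet(breath: pd.DataFrame, sbp: pd.DataFrame,
                 covariates: pd.DataFrame) -> pd.DataFrame:
    """CPET stage over a whole cohort: one result row per participant."""
    sbp_idx = sbp.set_index("participant_id")
    cov_idx = covariates.set_index("participant_id")
    rows = []
    for pid, series in breath.groupby("participant_id", sort=True):
        s = sbp_idx.loc[pid]
        c = cov_idx.loc[pid]
        r = process_session(
            series.sort_values("time_s"), float(s["rest_sbp"]),
            float(s["peak_sbp"]), float(s["peak_workload_w"]),
            float(c["age"]), str(c["sex"]), float(c["height_cm"]),
            float(c["weight_kg"]))
        rows.append({
            "participant_id": pid,
            "peak_vo2": r.peak_vo2,
            "pct_predicted_peak_vo2": r.pct_predicted_peak_vo2,
            "vat_vo2": r.vat_vo2,
            "ve_vco2_nadir": r.ve_vco2_nadir,
            "pct_predicted_max_hr": r.pct_predicted_max_hr,
            "sbp_w_slope": r.sbp_w_slope,
            "peak_rer": r.peak_rer,
            "adequate_effort": r.adequate_effort,
            "flags": ";".join(r.flags),
        })
    return pd.DataFrame(rows)
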