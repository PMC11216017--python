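"""Shared constants, prediction-equation coefficients and analysis configuration.

Everything a user might reasonably want to override lives here rather than as
magic numbers inside the processing functions: the person-day validity
thresholds, the motion-context inference rule's cut-offs, the reference
equations for predicted peak VO2 (Wasserman-Hansen, cycle ergometry) and
predicted maximum heart rate (Tanaka), and the covariate sets of the two
regression models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

# ---------------------------------------------------------------------------
# Smartwatch processing thresholds
# ---------------------------------------------------------------------------

#: Gap to the adjacent HR record (seconds) above which condition (1) of the
#: nonactive rule holds ("recording interval greater than 1 minute"; strict).
GAP_THRESHOLD_S: float = 60.0

#: Hourly step total below which condition (2) holds ("less than 30 steps
#: within the same hour"; strict).
HOURLY_STEP_THRESHOLD: int = 30

#: Person-day validity: a day is dropped when wear time is below this
#: ("less than 5 hours"; equality passes).
MIN_WEAR_HOURS: float = 5.0

#: Person-day validity: a day is dropped when its step total is below this
#: ("less than 1000"; equality passes).
MIN_DAILY_STEPS: int = 1000

#: Participant inclusion: at least this many contributing days ("30 or more").
MIN_DAYS: int = 30

#: Volitional-effort marker: sessions with peak RER at or above this value
#: count as adequate effort ("1.05 or higher"; inclusive).
RER_EFFORT_THRESHOLD: float = 1.05

#: Local timezone in which all stream timestamps are interpreted (civil time;
#: timestamps are handled as naive local clock readings).
DEFAULT_TIMEZONE: str = "America/New_York"

# ---------------------------------------------------------------------------
# CPET windowing
# ---------------------------------------------------------------------------

#: Width of the trailing, right-closed median window (seconds).
MEDIAN_WINDOW_S: float = 30.0

#: Length of the "final minute of exercise" peak-search span (seconds).
PEAK_SEARCH_SPAN_S: float = 60.0

#: Windows holding fewer samples than this are flagged as thin.
MIN_WINDOW_SAMPLES: int = 3

#: V-slope: candidate breakpoints are restricted to VO2 below this quantile
#: of the ramp-phase VO2, keeping the fit below the respiratory-compensation
#: region.
VSLOPE_CANDIDATE_QUANTILE: float = 0.90

#: V-slope: relative RSS improvement of the two-segment fit over a single
#: line below which the detection is flagged low-confidence.
VSLOPE_MIN_RSS_IMPROVEMENT: float = 0.05

#: Simulation benchmark: mean absolute VAT recovery error (mL/kg/min) the
#: detector is expected to beat under the default noisy-session generator.
VAT_RECOVERY_TOLERANCE: float = 1.5

# ---------------------------------------------------------------------------
# Reference equations
# ---------------------------------------------------------------------------

#: Predicted maximum HR (bpm) = intercept - slope * age. Tanaka formula.
TANAKA_COEFFS: dict[str, float] = {"intercept": 208.0, "slope": 0.7}

#: Wasserman-Hansen predicted peak VO2 for cycle ergometry (mL/min), the
#: classic sex-specific, ideal-weight-branched form:
#:
#:   ideal weight (kg) = iw_slope * height_cm + iw_intercept
#:   age factor        = f_intercept - f_slope * age      (mL/min per kg)
#:   men,   weight >= ideal:  ideal * factor + excess_slope * (weight - ideal)
#:   men,   weight <  ideal:  (ideal + weight)/2 * factor
#:   women, weight >= ideal:  (ideal + 43) * factor + excess_slope * (weight - ideal)
#:   women, weight <  ideal:  ((ideal + weight)/2 + 43) * factor
WASSERMAN_HANSEN_COEFFS: dict[str, dict[str, float]] = {
    "male": {
        "iw_slope": 0.79,
        "iw_intercept": -60.7,
        "f_intercept": 50.72,
        "f_slope": 0.372,
        "weight_offset": 0.0,
        "excess_slope": 6.0,
    },
    "female": {
        "iw_slope": 0.65,
        "iw_intercept": -42.8,
        "f_intercept": 22.78,
        "f_slope": 0.17,
        "weight_offset": 43.0,
        "excess_slope": 6.0,
    },
}

# ---------------------------------------------------------------------------
# Association battery configuration
# ---------------------------------------------------------------------------

#: The six CPET exposures, in report order.
CPET_EXPOSURES: tuple[str, ...] = (
    "peak_vo2",
    "pct_predicted_peak_vo2",
    "vat_vo2",
    "ve_vco2_nadir",
    "pct_predicted_max_hr",
    "sbp_w_slope",
)

#: Exposures that are natural-log transformed before standardization
#: (right-skewed in the source data).
LOG_TRANSFORMED_EXPOSURES: frozenset[str] = frozenset({"peak_vo2", "vat_vo2"})

#: Model 1 covariates: demographics only.
MODEL1_COVARIATES: tuple[str, ...] = ("age", "sex", "race")

#: Model 2 additions shared by both outcomes. Outcome-specific covariates
#: (HR-lowering treatment for the nonactive-HR outcome, watch wear time for
#: the daily-steps outcome) are appended by the battery, never both.
MODEL2_EXTRA_COVARIATES: tuple[str, ...] = (
    "bmi",
    "current_smoker",
    "total_cholesterol",
    "hdl",
    "fasting_glucose",
    "diabetes",
    "resting_sbp",
    "prevalent_cvd",
    "lipid_treatment",
    "htn_treatment",
    "season",
    "state",
)

#: Categorical covariates (encoded as factors in the regression formulas).
CATEGORICAL_COVARIATES: frozenset[str] = frozenset(
    {"sex", "race", "season", "state", "current_smoker", "diabetes",
     "prevalent_cvd", "lipid_treatment", "htn_treatment",
     "hr_lowering_treatment"}
)

#: State-of-residence levels observed fewer times than this are pooled into
#: an "other" level before model fitting.
STATE_POOL_MIN_COUNT: int = 20

#: BMI category edges (kg/m2): <25, >=25 but <30, >=30.
BMI_CUTS: tuple[float, float] = (25.0, 30.0)


@dataclass(frozen=True)
class AnalysisConfig:
    """Configuration of one association-battery run.

    The primary battery is the 6 exposures x 2 outcomes x 2 models grid on
    the joint >=30-day sample; the switches enable the sensitivity variants.
    """

    exposures: tuple[str, ...] = CPET_EXPOSURES
    outcomes: tuple[str, ...] = ("nonactive_hr", "daily_steps")
    models: tuple[str, ...] = ("model1", "model2")
    log_exposures: frozenset[str] = LOG_TRANSFORMED_EXPOSURES
    modifiers: tuple[str, ...] = ("sex", "age_group", "bmi_cat")
    #: restrict to sessions with peak RER >= 1.05
    rer_sensitivity: bool = True
    #: nonactive-HR models additionally adjusted for daily steps
    adjust_steps_in_hr_model: bool = True
    #: daily-steps analysis repeated on the step-inclusion-only sample
    expanded_step_sample: bool = True
    #: confirmatory analysis with watch measures as exposures
    role_swap: bool = True
    #: run interaction / stratified analyses
    interactions: bool = True
    min_days: int = MIN_DAYS
    state_pool_min_count: int = STATE_POOL_MIN_COUNT

    def covariates(self, model: str, outcome: str) -> list[str]:
        """Covariate list for one (model, outcome) cell.

        The HR-lowering-treatment covariate enters only the nonactive-HR
        models and watch wear time only the daily-steps models.
        """
        if model not in ("model1", "model2"):
            raise ValueError(f"unknown model tag {model!r}")
        if outcome not in ("nonactive_hr", "daily_steps"):
            raise ValueError(f"unknown outcome {outcome!r}")
        cov = list(MODEL1_COVARIATES)
        if model == "model2":
            cov += list(MODEL2_EXTRA_COVARIATES)
            if outcome == "nonactive_hr":
                cov.append("hr_lowering_treatment")
            else:
                cov.append("median_wear_hours")
        return cov


def with_overrides(cfg: AnalysisConfig, **kwargs) -> AnalysisConfig:
    """Return a copy of *cfg* with fields replaced."""
    return replace(cfg, **kwargs)
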