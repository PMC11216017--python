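# Methods

`wearcpet` reimplements, as a tested pipeline, an analysis style used in
community cohort studies of wearables and fitness: long-running smartwatch
streams are reduced to two participant-level measures — mean **nonactive
heart rate** and mean **daily steps** — and regressed on six
cardiopulmonary-exercise-testing (CPET) indices under two covariate models.
Because no individual-level cohort data are available, the package ships a
synthetic-data generator with planted ground truth, and every claim the
package makes about itself is a property of that generator that the test
suite and `scripts/acceptance.py` recompute.

## Smartwatch processing

**Motion-context inference.** Consumer smartwatches label only a fraction of
HR records with a motion context. The remainder are classified from two
signals: (1) the recording interval to the adjacent HR record — watches
sample HR much more densely during activity, so active records arrive less
than a minute apart ~99% of the time while sedentary records arrive more
than a minute apart ~99% of the time — and (2) the step total of the clock
hour containing the record. An unlabeled record is **nonactive** iff its
interval exceeds 60 s (strict) *and* its hour carries fewer than 30 steps
(strict); device labels are authoritative when present. The interval is
taken to the immediately preceding record; the first record of a
participant-day, whose backward interval would span the overnight gap, uses
the forward interval instead.

**Hourly steps.** Step records are intervals with counts. Intervals crossing
hour boundaries are apportioned proportionally to overlap and hour totals
are rounded half-to-even, so the grid total matches the raw total to within
one step per record.

**Person-day filtering and summaries.** Wear time is the number of distinct
clock hours of a day containing at least one HR or step record — the only
wear signal actually present in the streams. Days with wear below 5 hours
or steps below 1000 (both strict, so equality passes) are excluded from the
step analysis. Nonactive-HR averaging uses all nonactive records, including
those on step-invalid days, because the day filters belong to the step
pathway; a switch restricts it if desired. Participants enter an analysis
with 30 or more qualifying days (inclusive), tracked separately for the HR
sample, the step sample and the joint primary sample. All timestamps are
naive readings of one configured civil timezone; a DST-shortened or
-lengthened day is just a calendar day.

## CPET indices

All windowed statistics use trailing, right-closed 30-s windows defined in
time: the window ending at sample time t holds the samples in (t−30, t].

* **Peak VO2** — highest 30-s median VO2 with window end in the final 60 s
  of the ramp phase. Unloaded pedalling and recovery never enter the peak
  search.
* **% predicted peak VO2** — measured peak over the sex-specific
  Wasserman-Hansen cycle-ergometry prediction (ideal weight from height;
  above-ideal weight adds 6 mL/min per excess kg; below-ideal weight is
  averaged with ideal). Coefficients live in `config.py` and are
  overridable, as are the Tanaka coefficients below.
* **VO2 at VAT** — V-slope method: continuous two-segment least-squares fit
  of VCO2 on VO2 over the ramp, breakpoint chosen over the grid of interior
  sample VO2 values minimising total RSS subject to the upper slope
  exceeding the lower. Candidates are restricted below the 90th percentile
  of ramp VO2 to stay clear of the respiratory-compensation region. The fit
  runs on 30-s-median-smoothed breath data, reflecting how V-slope reading
  is done on averaged rather than raw breaths; on noise-free data the
  smoothing is exact (windowed medians of monotone series are sample
  values) so the planted breakpoint is still recovered to grid resolution.
  A fit improving RSS over a single line by less than 5% (relative) is
  flagged low-confidence; when no candidate yields a strictly steeper upper
  slope the VAT is reported missing with the flag rather than raising.
* **VE/VCO2 nadir** — lowest 30-s median of the VE/VCO2 ratio over all of
  exercise (unloaded + ramp).
* **% predicted maximum HR** — highest 30-s median HR during the ramp over
  the Tanaka prediction 208 − 0.7 × age.
* **SBP/W slope** — (peak SBP − rest SBP)/peak workload; the formula is
  signed and a hypotensive (negative) response is flagged, not rejected.
* **Peak RER** — highest 30-s median of VCO2/VO2 in the final ramp minute;
  sessions with peak RER ≥ 1.05 (inclusive) count as adequate effort.

VCO2 is carried in mL/kg/min (same units as VO2) so RER and the V-slope are
unit-free; the VE/VCO2 ratio converts VCO2 to L/min via body weight.

## Association battery

Peak VO2 and VO2 at VAT are natural-log transformed (right-skewed), then
each exposure is standardized to mean 0, SD 1 with the population-SD
(ddof 0) convention on the complete-case sample of the model being fitted —
so model-1 and model-2 z-scales may differ slightly when missing lab values
shrink the model-2 sample. Model 1 adjusts for age, sex and race; model 2
additionally for BMI, smoking, total cholesterol, HDL, fasting glucose,
diabetes, resting SBP, prevalent CVD, lipid-lowering and hypertension
treatment, season of enrollment and state of residence (rare state levels
pooled below a configurable count, default 20), plus HR-lowering treatment
only in nonactive-HR models and watch wear time only in daily-steps models.
Missing covariates are handled by complete-case deletion. Covariates that
are constant on a complete-case sample are dropped with a flag (they alias
the intercept); genuinely collinear designs raise an error naming the
columns. Tests of the exposure coefficient are two-sided t-tests without
robust or clustered corrections.

P values are Benjamini-Hochberg adjusted within each family of six
exposures per (analysis, outcome, model) cell; families are never pooled
across outcomes. Note that BH-adjusted p-values are **not idempotent**:
re-adjusting already-adjusted values inflates them toward the largest
adjusted value, a property of the step-up formula itself (the reference
implementation in `statsmodels` behaves identically). The tests therefore
assert the true invariants — agreement with an independent oracle,
monotonicity (adjusted ≥ raw) and permutation equivariance.

Effect modification by sex, median-split age (ties to the younger group,
median from the analysis sample) and 3-level BMI (<25, ≥25 but <30, ≥30;
boundary values go up) is tested by adding exposure × modifier terms to the
model-2 specification and F-testing the interaction block, with stratified
refits per level (empty or degenerate strata reported missing). Sensitivity
variants: restriction to adequate-effort sessions; nonactive-HR models
additionally adjusted for daily steps; the daily-steps battery on the
larger step-only inclusion sample; and a role-swapped confirmatory analysis
with the standardized watch measures as exposures and the CPET measures
(log scale for peak VO2 and VAT VO2) as outcomes.

## The synthetic-data generator

One latent fitness factor per participant (SD 1) drives everything:
nonactive HR at −2.4 bpm per SD, daily steps at +1000 steps per SD, log
peak VO2 at +0.25 per SD, and the remaining CPET indices with
physiologically signed loadings. Marginals follow the cohort the package
emulates: age 53 ± 9 y, 59% female, nonactive HR 73 ± 6 bpm, 7269 ± 2760
steps/day, ~14 h/day wear, 65–227-day follow-up.

Activity is a two-state Markov chain on the clock-hour grid inside a
07:00–22:00 wear window (active share 0.18, mean active bout 1 h — chosen
so fewer than ~5% of worn days lack any stepping, as on real 14-hour wear
days), giving each hour a single true context at exactly the granularity
the inference rule reads. HR record gaps are log-normal per state (medians
45 s active / 1500 s sedentary) with the spread calibrated so exactly 99%
of gaps fall on the correct side of 60 s at the default 1% leakage; at zero
leakage the distributions are truncated one second clear of the threshold
so that flooring timestamps to whole seconds cannot land a gap on the
strict boundary. Active hours receive the day's step target (≥30 per active
hour), sedentary hours fewer than 30, each with configurable leakage. These
choices make zero-leakage streams *exactly* classifiable — which is what
turns classifier agreement into a sharp test — while default leakage
exercises the realistic ≥95% regime.

CPET sessions sit on a regular 2-s grid: 3 min unloaded, an 8–10-min ramp
(15 or 25 W/min) with VO2 rising linearly to the true peak, VCO2 piecewise
linear in VO2 with the slope break planted at the true VAT (lower slope
0.85–0.95, upper 1.30–1.50, which puts peak RER near 1.1–1.2 so only a few
percent of sessions fail the effort criterion), VE tracking VCO2 through a
shallow-U efficiency ratio whose minimum is the planted nadir, and 60 s of
recovery. Gaussian noise (default SD 1 mL/kg/min) is added per channel.

What the generator does **not** emulate: optical-sensor noise spectra,
loose-fit dropouts, irregular breath timing, within-person drift of HR or
activity over follow-up, DST transitions, and correlated covariate
structure beyond a mild BMI–fitness link. Passing tests therefore show
that the processing rules and estimators are correct and calibrated under
the stated generative assumptions — not that the device-specific artifacts
of real streams are handled.

## Numerical and scale choices

The V-slope search solves all candidate hinge regressions at once from
suffix sums (O(n + k) after sorting), using a pseudo-inverse for
degenerate candidate Gram matrices; RSS ties take the smallest candidate.
Rolling medians are computed by explicit window enumeration (`searchsorted`
bounds), matching an O(n²) oracle exactly, ties included; windows holding
fewer than 3 samples are flagged. Hour totals round half-to-even.
Simulation problem sizes in the tests and the acceptance script (e.g. 20
seeded end-to-end runs at n=110 participants with ~5-week follow-up; 1000
replicates at n=300 for the calibration checks; 200 noisy sessions for VAT
recovery) were chosen to make the Monte-Carlo error small relative to each
acceptance band while keeping a full run in minutes; all are parameters,
not constants.

## Known limitations

* Wear time is hour-granular; sub-hour non-wear is invisible.
* The VAT detector assumes a single slope break below the
  respiratory-compensation point; sessions with no identifiable break are
  reported missing rather than imputed.
* The expanded step-only sample and role-swap analyses reuse the same
  z-scale convention as the primary battery; no measurement-error
  correction is attempted for either watch measure.
* The back-conversion of a standardized log-scale coefficient into natural
  units (bpm per mL/kg/min) depends on the evaluation point; the package
  reports coefficients per SD and leaves any rescaling to the reader.
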