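"""Association battery: CPET fitness indices vs smartwatch measures.

Primary analysis: ordinary least squares of each smartwatch outcome
(nonactive HR in bpm; daily steps in steps/day) on each of the six CPET
exposures, one exposure at a time, under two covariate models:

* model 1 — age, sex, self-reported race;
* model 2 — model 1 plus BMI, smoking, total cholesterol, HDL, fasting
  glucose, diabetes, resting SBP, prevalent CVD, lipid-lowering treatment,
  hypertension treatment, season of enrollment and state of residence, with
  HR-lowering treatment only in the nonactive-HR models and watch wear time
  only in the daily-steps models.

Peak VO2 and VO2 at VAT are natural-log transformed (right-skewed), then
every exposure is standardized to mean 0, SD 1 (population SD, ddof 0) on
the complete-case sample of the model being fitted, so a coefficient reads
as outcome units per SD of exposure.  P values are Benjamini-Hochberg
FDR-adjusted within each family of six exposures per (outcome, model) cell.

Sensitivity variants: restriction to sessions with peak RER >= 1.05;
additional adjustment of the nonactive-HR model for daily steps; the
expanded step-only sample; and the role-swapped confirmatory analysis with
watch measures as exposures.  Effect modification by sex, median-split age
and 3-level BMI is tested with multiplicative interaction terms plus
stratified fits.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.formula.api as smf

from .config import (
    AnalysisConfig,
    BMI_CUTS,
    CATEGORICAL_COVARIATES,
    CPET_EXPOSURES,
)


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def transform_standardize(values, log_transform: bool = False) -> np.ndarray:
    """Optional natural log, then (x - mean)/SD with the population-SD
    (ddof 0) convention.  NaNs are preserved; mean and SD come from the
    non-missing values."""
    x = np.asarray(values, dtype=float)
    mask = ~np.isnan(x)
    if log_transform:
        if np.any(x[mask] <= 0):
            raise ValueError("log transform requires strictly positive values")
        x = np.where(mask, np.log(np.where(mask, x, 1.0)), np.nan)
    mu = x[mask].mean()
    sd = x[mask].std(ddof=0)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("cannot standardize a zero-variance variable")
    return (x - mu) / sd


def bh_adjust(p_values, family=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Within each family (all values together when ``family`` is None):
    sort ascending, q_i = min_{j >= i} p_(j) * m / j, capped at 1; values
    are returned in the original order.
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if family is not None:
        fam = np.asarray(family)
        out = np.empty_like(p)
        for f in np.unique(fam):
            out[fam == f] = bh_adjust(p[fam == f])
        return out
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def add_derived_modifiers(df: pd.DataFrame,
                          age_median: float | None = None) -> pd.DataFrame:
    """Add the effect-modification groupings: ``age_group`` (older = strictly
    above the sample median age; ties go to the younger group) and
    ``bmi_cat`` (<25, >=25 but <30, >=30 kg/m2)."""
    out = df.copy()
    med = df["age"].median() if age_median is None else age_median
    out["age_group"] = np.where(out["age"] > med, "older", "younger")
    out["bmi_cat"] = pd.cut(
        out["bmi"], bins=[-np.inf, *BMI_CUTS, np.inf], right=False,
        labels=["<25", "25-30", ">=30"]).astype(str)
    return out


def pool_small_levels(series: pd.Series, min_count: int,
                      other: str = "other") -> pd.Series:
    """Pool factor levels observed fewer than ``min_count`` times."""
    counts = series.value_counts()
    small = set(counts[counts < min_count].index)
    return series.where(~series.isin(small), other)


# ---------------------------------------------------------------------------
# Single model fit
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelResult:
    """One exposure-outcome OLS fit."""
    exposure: str
    outcome: str
    model: str
    beta: float          # outcome units per SD of exposure
    se: float
    p_raw: float
    n: int
    adj_r2: float
    p_fdr: float = np.nan
    analysis: str = "primary"
    flags: str = ""


def _term(c: str) -> str:
    return f"C({c})" if c in CATEGORICAL_COVARIATES else c


def _check_full_rank(model) -> None:
    X = np.asarray(model.exog)
    _, r, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    deficient = piv[diag <= tol]
    if deficient.size:
        names = [model.exog_names[i] for i in deficient]
        raise ValueError(f"design matrix is rank deficient; collinear "
                         f"columns: {names}")


def fit_model(data: pd.DataFrame, outcome: str, exposure: str,
              covariates: list[str], log_exposure: bool = False,
              model_tag: str = "model", analysis: str = "primary",
              ) -> ModelResult:
    """OLS of ``outcome`` on the standardized ``exposure`` plus covariates.

    Complete-case deletion over every used column; the exposure is
    (optionally log-transformed and) standardized on that complete-case
    sample.  Raises on a rank-deficient design, naming the collinear
    columns.
    """
    used = [outcome, exposure] + [c for c in covariates]
    d = data.loc[:, list(dict.fromkeys(used))].dropna()
    n = len(d)
    if n < len(covariates) + 2:
        raise ValueError(
            f"only {n} complete cases for {exposure} -> {outcome}; need at "
            f"least {len(covariates) + 2}")
    # covariates constant on the complete-case sample carry no information
    # (and would alias the intercept); drop them with a flag
    kept = [c for c in covariates if d[c].nunique(dropna=True) > 1]
    dropped = [c for c in covariates if c not in kept]
    d = d.assign(exposure_z=transform_standardize(d[exposure], log_exposure))
    rhs = ["exposure_z"] + [_term(c) for c in kept]
    model = smf.ols(f"{outcome} ~ " + " + ".join(rhs), data=d)
    _check_full_rank(model)
    if n - model.exog.shape[1] < 2:   # dummy expansion can exhaust the df
        raise ValueError(
            f"only {n} complete cases for {exposure} -> {outcome} against a "
            f"{model.exog.shape[1]}-column design; too few residual df")
    fit = model.fit()
    return ModelResult(
        exposure=exposure, outcome=outcome, model=model_tag,
        beta=float(fit.params["exposure_z"]),
        se=float(fit.bse["exposure_z"]),
        p_raw=float(fit.pvalues["exposure_z"]),
        n=n, adj_r2=float(fit.rsquared_adj), analysis=analysis,
        flags=(f"dropped_constant:{','.join(dropped)}" if dropped else ""),
    )


# ---------------------------------------------------------------------------
# Interaction / stratified analysis
# ---------------------------------------------------------------------------

def _drop_degenerate(d: pd.DataFrame, covariates: list[str]) -> list[str]:
    """Remove covariates constant within the (sub)sample."""
    return [c for c in covariates if d[c].nunique(dropna=True) > 1]


def interaction_analysis(data: pd.DataFrame, outcome: str, exposure: str,
                         modifier: str, covariates: list[str],
                         log_exposure: bool = False) -> dict:
    """Multiplicative effect-modification test plus stratified fits.

    Adds exposure x modifier interaction term(s) to the adjusted model and
    reports the joint interaction p (F-test of the interaction block); also
    refits the model within each modifier level (degenerate covariates
    dropped per stratum).  Empty strata are reported missing.
    """
    levels = [lv for lv in pd.unique(data[modifier].dropna())]
    if len(levels) < 2:
        raise ValueError(f"modifier {modifier!r} needs >= 2 nonempty levels")
    used = list(dict.fromkeys([outcome, exposure, modifier] + covariates))
    d = data.loc[:, used].dropna()
    d = d.assign(exposure_z=transform_standardize(d[exposure], log_exposure))
    covs = [c for c in covariates if c != modifier]
    base_rhs = ["exposure_z", f"C({modifier})"] + [_term(c) for c in covs]
    reduced = smf.ols(f"{outcome} ~ " + " + ".join(base_rhs), data=d).fit()
    full = smf.ols(
        f"{outcome} ~ " + " + ".join(base_rhs)
        + f" + exposure_z:C({modifier})", data=d).fit()
    f_stat, p_int, df_diff = full.compare_f_test(reduced)

    strata: dict[str, ModelResult | None] = {}
    for lv in sorted(map(str, levels)):
        sub = data[data[modifier].astype(str) == lv]
        sub = sub.loc[:, [c for c in used if c != modifier]].dropna()
        if len(sub) < len(covs) + 3:
            strata[lv] = None
            continue
        try:
            strata[lv] = fit_model(
                sub, outcome, exposure, _drop_degenerate(sub, covs),
                log_exposure, model_tag="model2",
                analysis=f"stratified:{modifier}={lv}")
        except ValueError:   # stratum too small once factors expand
            strata[lv] = None
    return {
        "exposure": exposure, "outcome": outcome, "modifier": modifier,
        "interaction_F": float(f_stat), "interaction_p": float(p_int),
        "df": int(df_diff), "n": int(len(d)), "strata": strata,
    }


# ---------------------------------------------------------------------------
# The full battery
# ---------------------------------------------------------------------------

def build_analysis_table(covariates: pd.DataFrame,
                         watch_summary: pd.DataFrame,
                         cpet_results: pd.DataFrame,
                         cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Join covariates, watch summaries and CPET results into the analysis
    table, rename the outcomes, pool rare state levels."""
    cfg = cfg or AnalysisConfig()
    df = (covariates
          .merge(watch_summary, on="participant_id", how="left")
          .merge(cpet_results, on="participant_id", how="left"))
    df = df.rename(columns={"nonactive_hr_mean": "nonactive_hr",
                            "mean_daily_steps": "daily_steps"})
    for c in ("included_hr", "included_steps", "included_primary"):
        if c in df.columns:
            df[c] = df[c].astype("boolean").fillna(False).astype(bool)
    df["state"] = pool_small_levels(df["state"], cfg.state_pool_min_count)
    return df


def _fdr_by_cell(rows: list[ModelResult]) -> list[ModelResult]:
    """BH adjustment within each (analysis, outcome, model) family."""
    if not rows:
        return rows
    df = pd.DataFrame([asdict(r) for r in rows])
    fam = (df["analysis"] + "|" + df["outcome"] + "|" + df["model"])
    df["p_fdr"] = bh_adjust(df["p_raw"].to_numpy(), family=fam.to_numpy())
    return [ModelResult(**rec) for rec in df.to_dict("records")]


@dataclass
class BatteryResults:
    """All regression rows plus the interaction table."""
    results: pd.DataFrame
    interactions: pd.DataFrame

    def sign_pattern_ok(self) -> bool:
        """True when the primary battery reproduces the expected sign
        pattern: the three VO2-based exposures negative against nonactive
        HR and positive against daily steps, in both models."""
        vo2 = ["peak_vo2", "pct_predicted_peak_vo2", "vat_vo2"]
        prim = self.results[(self.results["analysis"] == "primary")
                            & self.results["exposure"].isin(vo2)]
        hr = prim[prim["outcome"] == "nonactive_hr"]["beta"]
        st = prim[prim["outcome"] == "daily_steps"]["beta"]
        return bool((hr < 0).all() and (st > 0).all())


def run_battery(analysis_df: pd.DataFrame,
                cfg: AnalysisConfig | None = None) -> BatteryResults:
    """Run the full association battery on a prepared analysis table.

    Emits the 6 x 2 x 2 primary grid on the joint inclusion sample plus the
    configured sensitivity variants, with FDR adjustment within each
    (analysis, outcome, model) family of six tests.
    """
    cfg = cfg or AnalysisConfig()
    rows: list[ModelResult] = []
    inter_rows: list[dict] = []

    primary = analysis_df[analysis_df["included_primary"]].copy()

    def battery_rows(sample, outcomes, analysis, extra_cov=None):
        out = []
        for outcome in outcomes:
            for model in cfg.models:
                covs = cfg.covariates(model, outcome)
                if extra_cov and model == "model2":
                    covs = covs + list(extra_cov)
                for exp in cfg.exposures:
                    out.append(fit_model(
                        sample, outcome, exp, covs,
                        log_exposure=exp in cfg.log_exposures,
                        model_tag=model, analysis=analysis))
        return out

    rows += battery_rows(primary, cfg.outcomes, "primary")

    if cfg.rer_sensitivity and "adequate_effort" in primary.columns:
        effort = primary[
            primary["adequate_effort"].astype("boolean").fillna(False).astype(bool)]
        if len(effort):
            rows += battery_rows(effort, cfg.outcomes, "rer_ge_1.05")

    if cfg.adjust_steps_in_hr_model:
        for exp in cfg.exposures:
            covs = cfg.covariates("model2", "nonactive_hr") + ["daily_steps"]
            rows.append(fit_model(
                primary, "nonactive_hr", exp, covs,
                log_exposure=exp in cfg.log_exposures,
                model_tag="model2", analysis="hr_step_adjusted"))

    if cfg.expanded_step_sample:
        expanded = analysis_df[analysis_df["included_steps"]]
        rows += battery_rows(expanded, ["daily_steps"], "expanded_steps")

    if cfg.role_swap:
        swap = primary.copy()
        for exp in cfg.log_exposures:
            swap[exp] = np.log(swap[exp])
        for model in cfg.models:
            for watch_exp, outcome_style in (("nonactive_hr", "nonactive_hr"),
                                             ("daily_steps", "daily_steps")):
                covs = cfg.covariates(model, outcome_style)
                for cp in cfg.exposures:
                    rows.append(fit_model(
                        swap, cp, watch_exp, covs, log_exposure=False,
                        model_tag=model, analysis=f"role_swap:{watch_exp}"))

    rows = _fdr_by_cell(rows)

    if cfg.interactions:
        mod_df = add_derived_modifiers(primary)
        for modifier in cfg.modifiers:
            for outcome in cfg.outcomes:
                cell = []
                for exp in cfg.exposures:
                    res = interaction_analysis(
                        mod_df, outcome, exp, modifier,
                        cfg.covariates("model2", outcome),
                        log_exposure=exp in cfg.log_exposures)
                    cell.append(res)
                p_adj = bh_adjust([r["interaction_p"] for r in cell])
                for r, q in zip(cell, p_adj):
                    inter_rows.append({
                        "exposure": r["exposure"], "outcome": r["outcome"],
                        "modifier": r["modifier"], "n": r["n"],
                        "interaction_F": r["interaction_F"],
                        "interaction_p": r["interaction_p"],
                        "interaction_p_fdr": float(q),
                    })

    results = pd.DataFrame([asdict(r) for r in rows])
    interactions = pd.DataFrame(inter_rows)
    return BatteryResults(results=results, interactions=interactions)
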