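"""Association-battery tests: standardization, OLS recovery, BH-FDR,
effect-modification machinery and the battery grid."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.multitest import multipletests

from conftest import synthetic_analysis_table
from wearcpet.assoc import (
    add_derived_modifiers,
    bh_adjust,
    fit_model,
    interaction_analysis,
    run_battery,
    transform_standardize,
)
from wearcpet.config import AnalysisConfig
from wearcpet.synth import CohortParams, generate_cohort


# ---------------------------------------------------------------------------
# transform_standardize
# ---------------------------------------------------------------------------

def test_standardize_definition_and_log():
    x = np.array([3.0, 7.0, 11.0, 15.0])
    z = transform_standardize(x)
    assert z.mean() == pytest.approx(0.0, abs=1e-12)
    assert z.std(ddof=0) == pytest.approx(1.0)
    # {e, e^2, e^3} -> logs {1,2,3} -> z = +/- sqrt(3/2), 0 under ddof 0
    z = transform_standardize(np.exp([1.0, 2.0, 3.0]), log_transform=True)
    np.testing.assert_allclose(z, [-np.sqrt(1.5), 0.0, np.sqrt(1.5)])
    with pytest.raises(ValueError, match="positive"):
        transform_standardize([1.0, -2.0], log_transform=True)
    with pytest.raises(ValueError, match="variance"):
        transform_standardize([5.0, 5.0, 5.0])


# ---------------------------------------------------------------------------
# bh_adjust
# ---------------------------------------------------------------------------

def _bh_oracle(p):
    """Literal step-up definition, independently coded."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    out = np.empty(m)
    for rank, i in enumerate(order, start=1):
        out[i] = min(min(p[j] * m / (list(order).index(j) + 1)
                         for j in order[rank - 1:]), 1.0)
    return out


def test_bh_hand_example_and_single():
    np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]),
                               [0.03, 0.03, 0.03])
    np.testing.assert_allclose(bh_adjust([0.4]), [0.4])
    with pytest.raises(ValueError, match="0, 1"):
        bh_adjust([0.5, 1.5])


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_bh_properties(p):
    q = bh_adjust(p)
    # monotone: adjusted never below raw
    assert np.all(q >= np.asarray(p) - 1e-15)
    # order-equivariant: permuting the inputs permutes the outputs
    perm = np.arange(len(p))[::-1]
    np.testing.assert_allclose(bh_adjust(np.asarray(p)[perm]), q[perm],
                               atol=1e-12)
    # agrees with the reference implementation
    np.testing.assert_allclose(q, multipletests(p, method="fdr_bh")[1],
                               atol=1e-12)


def test_bh_matches_definition_oracle_and_families():
    rng = np.random.default_rng(11)
    for _ in range(20):
        p = rng.random(rng.integers(1, 12))
        np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)
    p = np.array([0.01, 0.04, 0.01, 0.04])
    fam = np.array(["a", "a", "b", "b"])
    q = bh_adjust(p, family=fam)
    np.testing.assert_allclose(q, [0.02, 0.04, 0.02, 0.04])


# ---------------------------------------------------------------------------
# fit_model
# ---------------------------------------------------------------------------

def _planted_frame(n=500, beta=-2.4, seed=2):
    params = CohortParams(n_participants=n, seed=seed)
    cov, gt = generate_cohort(params)
    rng = np.random.default_rng(seed + 100)
    cov = cov.copy()
    cov["exposure"] = gt["true_peak_vo2"]
    z = transform_standardize(cov["exposure"], log_transform=True)
    cov["outcome"] = (73.0 + beta * z + 0.1 * (cov["age"] - 53)
                      + rng.normal(0, 5.0, n))
    return cov


def test_fit_model_recovers_planted_effect():
    data = _planted_frame()
    res = fit_model(data, "outcome", "exposure",
                    ["age", "sex", "race"], log_exposure=True,
                    model_tag="model1")
    assert abs(res.beta - (-2.4)) < 3 * res.se
    assert res.n == 500
    assert res.se > 0


def test_fit_model_matches_normal_equations():
    data = _planted_frame(n=120, seed=5)
    res = fit_model(data, "outcome", "exposure", ["age", "bmi"],
                    log_exposure=True)
    d = data[["outcome", "exposure", "age", "bmi"]].dropna()
    z = transform_standardize(d["exposure"], log_transform=True)
    X = np.column_stack([np.ones(len(d)), z, d["age"], d["bmi"]])
    y = d["outcome"].to_numpy()
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert res.beta == pytest.approx(beta[1], rel=1e-8)
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(d) - X.shape[1])
    se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
    assert res.se == pytest.approx(se, rel=1e-8)


def test_fit_model_rank_deficiency_names_columns():
    data = _planted_frame(n=100, seed=6)
    data["exposure_copy"] = 2.0 * np.log(data["exposure"]) + 1.0
    with pytest.raises(ValueError, match="rank deficient"):
        fit_model(data, "outcome", "exposure", ["age", "exposure_copy"],
                  log_exposure=True)


def test_fit_model_requires_enough_complete_cases():
    data = _planted_frame(n=10)
    with pytest.raises(ValueError, match="complete cases"):
        fit_model(data, "outcome", "exposure",
                  [f"age"] * 1 + ["sex", "race", "bmi", "resting_sbp",
                                  "total_cholesterol", "hdl",
                                  "fasting_glucose", "season"])


# ---------------------------------------------------------------------------
# modifiers
# ---------------------------------------------------------------------------

def test_bmi_categories_and_age_split_boundaries():
    df = pd.DataFrame({"age": [50.0, 53.0, 53.5, 60.0],
                       "bmi": [24.99, 25.0, 29.99, 30.0]})
    out = add_derived_modifiers(df, age_median=53.0)
    assert list(out["bmi_cat"]) == ["<25", "25-30", "25-30", ">=30"]
    # ties at the median age go to the younger group
    assert list(out["age_group"]) == ["younger", "younger", "older", "older"]


def test_interaction_detects_planted_modification():
    rng = np.random.default_rng(9)
    n = 600
    params = CohortParams(n_participants=n, seed=21)
    cov, gt = generate_cohort(params)
    d = cov.copy()
    d["exposure"] = gt["true_peak_vo2"]
    z = transform_standardize(d["exposure"], log_transform=True)
    older = (d["age"] > d["age"].median()).to_numpy()
    d["outcome"] = 73 - 4.0 * z * (~older) - 0.5 * z * older + rng.normal(0, 4, n)
    d = add_derived_modifiers(d)
    res = interaction_analysis(d, "outcome", "exposure", "age_group",
                               ["age", "sex"], log_exposure=True)
    assert res["interaction_p"] < 0.01
    strata = res["strata"]
    assert set(strata) == {"older", "younger"}
    assert strata["younger"].beta < strata["older"].beta  # stronger in young


def test_interaction_requires_two_levels():
    d = _planted_frame(n=50)
    d["mod"] = "only"
    with pytest.raises(ValueError, match="levels"):
        interaction_analysis(d, "outcome", "exposure", "mod", ["age"])


# ---------------------------------------------------------------------------
# battery
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def battery():
    table = synthetic_analysis_table(n=250, seed=7)
    return run_battery(table, AnalysisConfig(interactions=False))


def test_battery_emits_full_primary_grid(battery):
    prim = battery.results[battery.results["analysis"] == "primary"]
    assert len(prim) == 24  # 6 exposures x 2 outcomes x 2 models
    assert (prim.groupby(["outcome", "model"]).size() == 6).all()
    assert (prim["p_fdr"] >= prim["p_raw"] - 1e-15).all()
    assert (prim["se"] > 0).all()


def test_battery_reproduces_expected_sign_pattern(battery):
    assert battery.sign_pattern_ok()


def test_role_swap_transposes_and_agrees_in_sign(battery):
    swap = battery.results[
        battery.results["analysis"].str.startswith("role_swap")]
    assert len(swap) == 24
    assert set(swap["exposure"]) == {"nonactive_hr", "daily_steps"}
    vo2 = ["peak_vo2", "pct_predicted_peak_vo2", "vat_vo2"]
    prim = battery.results[battery.results["analysis"] == "primary"]
    for cp in vo2:
        direct = prim[(prim["exposure"] == cp)
                      & (prim["outcome"] == "nonactive_hr")]["beta"]
        swapped = swap[(swap["outcome"] == cp)
                       & (swap["exposure"] == "nonactive_hr")]["beta"]
        assert (direct < 0).all() and (swapped < 0).all()


def test_config_forbids_mismatched_outcome_covariates():
    cfg = AnalysisConfig()
    assert "hr_lowering_treatment" in cfg.covariates("model2", "nonactive_hr")
    assert "hr_lowering_treatment" not in cfg.covariates("model2", "daily_steps")
    assert "median_wear_hours" in cfg.covariates("model2", "daily_steps")
    with pytest.raises(ValueError, match="outcome"):
        cfg.covariates("model2", "vo2")
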