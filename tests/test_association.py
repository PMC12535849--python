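import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.outliers_influence import variance_inflation_factor
import statsmodels.api as sm

from conftest import make_2x2
from fabrykit.association import (
    CarrierAssociation,
    bh_adjust,
    build_analysis_set,
    fit_linear,
    fit_logistic,
    fit_ordinal,
    run_stratified,
    vif,
)
from fabrykit.errors import DataError, ModelError


# ---------------------------------------------------------------- analysis sets

def _toy_cohort():
    return pd.DataFrame({
        "sex": ["female"] * 5 + ["male"] * 4,
        "ac_G": [0, 1, 2, 0, 1, 0, 1, 0, 0],
        "ac_H": [0, 0, 0, 1, 0, 0, 0, 1, 0],
    })


def test_homozygous_female_excluded_everywhere():
    aset = build_analysis_set(_toy_cohort(), "G", "female")
    assert aset.excluded_homozygous == 1
    assert aset.n_cases == 2
    # the homozygous row (index 2) appears in neither arm
    assert 2 not in aset.data.index


def test_controls_exclude_carriers_of_other_groups():
    aset = build_analysis_set(_toy_cohort(), "G", "female")
    assert aset.n_controls == 1  # row 3 carries H, so only row 0 qualifies
    aset_m = build_analysis_set(_toy_cohort(), "G", "male")
    assert aset_m.n_cases == 1 and aset_m.n_controls == 2


def test_all_wildtype_cohort_warns_empty():
    cohort = pd.DataFrame({"sex": ["male"] * 3, "ac_G": [0, 0, 0]})
    with pytest.warns(UserWarning, match="no male carriers"):
        aset = build_analysis_set(cohort, "G", "male")
    assert aset.empty


def test_analysis_set_is_single_sex():
    aset = build_analysis_set(_toy_cohort(), "G", "male")
    assert (aset.data["sex"] == "male").all()


# ---------------------------------------------------------------- logistic

def test_unadjusted_or_equals_cross_product():
    res = fit_logistic(make_2x2(20, 80, 10, 90), "y", covariates=())
    assert res.effect == pytest.approx((20 * 90) / (80 * 10), abs=1e-6)
    assert res.ci_low <= res.effect <= res.ci_high


def test_balanced_table_or_one():
    res = fit_logistic(make_2x2(50, 50, 50, 50), "y", covariates=())
    assert res.effect == pytest.approx(1.0, abs=1e-9)
    assert res.ci_low < 1.0 < res.ci_high


def test_cross_product_oracle_over_small_tables():
    for a, b, c, d in itertools.product((4, 11, 27), repeat=4):
        res = fit_logistic(make_2x2(a, b, c, d), "y", covariates=())
        assert res.effect == pytest.approx((a * d) / (b * c), rel=1e-5)


def test_confounder_adjustment_removes_spurious_association(rng):
    n = 20_000
    confounder = rng.random(n) < 0.4
    exposure = (rng.random(n) < np.where(confounder, 0.5, 0.1)).astype(int)
    y = (rng.random(n) < np.where(confounder, 0.4, 0.05)).astype(int)
    data = pd.DataFrame({"carrier": exposure, "y": y, "conf": confounder.astype(float)})
    crude = fit_logistic(data, "y", covariates=())
    adjusted = fit_logistic(data, "y", covariates=("conf",))
    assert crude.ci_low > 1.0  # confounding induces a spurious crude OR
    assert adjusted.ci_low <= 1.0 <= adjusted.ci_high


def test_separation_flagged_not_fatal():
    data = make_2x2(10, 0, 5, 50)  # every exposed subject is a case
    res = fit_logistic(data, "y", covariates=())
    assert res.separation
    assert res.ci_high == np.inf


def test_single_class_outcome_raises():
    data = make_2x2(0, 30, 0, 30)
    with pytest.raises(ModelError):
        fit_logistic(data, "y", covariates=())


def test_missing_rows_dropped_and_counted():
    data = make_2x2(20, 80, 10, 90)
    data.loc[:4, "y"] = np.nan
    res = fit_logistic(data, "y", covariates=())
    assert res.n_dropped == 5


# ---------------------------------------------------------------- ordinal

def test_two_level_ordinal_equals_logistic():
    data = make_2x2(25, 75, 12, 88)
    logit = fit_logistic(data, "y", covariates=())
    ordinal = fit_ordinal(data, "y", covariates=())
    assert ordinal.effect == pytest.approx(logit.effect, rel=1e-3)


def test_ordinal_balanced_or_one():
    data = pd.DataFrame({
        "carrier": [0, 0, 0, 1, 1, 1] * 20,
        "y": [0, 1, 2, 0, 1, 2] * 20,
    })
    res = fit_ordinal(data, "y", covariates=())
    assert res.effect == pytest.approx(1.0, abs=1e-4)


def test_proportional_odds_recovery(rng):
    n = 20_000
    exposure = rng.integers(0, 2, n)
    true_logor = np.log(2.0)
    cuts = np.array([0.0, 1.5])  # three outcome levels
    eta = true_logor * exposure
    u = rng.logistic(size=n)
    y = (eta + u > cuts[0]).astype(int) + (eta + u > cuts[1]).astype(int)
    data = pd.DataFrame({"carrier": exposure, "y": y})
    res = fit_ordinal(data, "y", covariates=())
    assert res.ci_low < 2.0 < res.ci_high


def test_ordinal_single_level_raises():
    data = pd.DataFrame({"carrier": [0, 1] * 10, "y": [2] * 20})
    with pytest.raises(ModelError):
        fit_ordinal(data, "y", covariates=())


# ---------------------------------------------------------------- linear

def test_linear_slope_recovery(rng):
    n = 10_000
    exposure = rng.integers(0, 2, n)
    y = 2.0 * exposure + rng.normal(0, 1, n)
    data = pd.DataFrame({"carrier": exposure, "y": y})
    res = fit_linear(data, "y", covariates=())
    se = (res.ci_high - res.effect) / 1.96
    assert abs(res.effect - 2.0) < 4 * se
    assert res.group_mean_sd[0] == pytest.approx(y[exposure == 1].mean())


def test_linear_null_interval_contains_zero(rng):
    n = 5000
    data = pd.DataFrame({
        "carrier": rng.integers(0, 2, n),
        "y": rng.normal(size=n),
    })
    res = fit_linear(data, "y", covariates=())
    assert res.ci_low < 0.0 < res.ci_high


def test_statin_adjust_adds_covariate(rng):
    n = 2000
    data = pd.DataFrame({
        "carrier": rng.integers(0, 2, n),
        "cholesterol": rng.normal(5.5, 1.0, n),
        "statin_use": rng.integers(0, 2, n).astype(float),
    })
    res = fit_linear(data, "cholesterol", covariates=(), statin_adjust=True)
    assert "statin_use" in res.covariates
    res_plain = fit_linear(data, "cholesterol", covariates=())
    assert "statin_use" not in res_plain.covariates


def test_linear_zero_variance_raises():
    data = pd.DataFrame({"carrier": [0, 1] * 10, "y": [3.0] * 20})
    with pytest.raises(ModelError):
        fit_linear(data, "y", covariates=())


# ---------------------------------------------------------------- BH adjustment

def _bh_bruteforce(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    out = np.empty(m)
    for i in range(m):
        out[i] = min(min(ranked[j] * m / (j + 1) for j in range(i, m)), 1.0)
    result = np.empty(m)
    result[order] = out
    return result


def test_bh_known_values():
    assert bh_adjust([0.03]).tolist() == [0.03]
    assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])
    got = bh_adjust([0.005, 0.011, 0.02, 0.04, 0.5])
    assert np.allclose(got, [0.025, 0.0275, 1 / 30, 0.05, 0.5])


def test_bh_rejects_bad_p():
    with pytest.raises(DataError):
        bh_adjust([0.1, 1.2])
    with pytest.raises(DataError):
        bh_adjust([0.1, np.nan])


@settings(derandomize=True, max_examples=120)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6))
def test_bh_matches_bruteforce_and_invariants(p):
    got = bh_adjust(p)
    assert np.allclose(got, _bh_bruteforce(p), atol=1e-12)
    assert (got >= np.asarray(p) - 1e-15).all()
    assert (got <= 1.0).all()
    order = np.argsort(p, kind="stable")
    assert (np.diff(got[order]) >= -1e-15).all()  # nondecreasing in sorted-p order


# ---------------------------------------------------------------- VIF

def test_vif_orthogonal_predictors():
    # +/-1 full factorial columns are exactly orthogonal to each other and
    # to the intercept
    x1 = np.array([1, 1, -1, -1] * 5, dtype=float)
    x2 = np.array([1, -1, 1, -1] * 5, dtype=float)
    out = vif(pd.DataFrame({"x1": x1, "x2": x2}))
    assert np.allclose(out, 1.0)


def test_vif_near_collinear(rng):
    x1 = rng.normal(size=500)
    x2 = x1 + rng.normal(0, 0.01, 500)
    out = vif(pd.DataFrame({"x1": x1, "x2": x2}))
    assert (out > 10).all()


def test_vif_exact_collinearity_infinite(rng):
    x1 = rng.normal(size=100)
    out = vif(pd.DataFrame({"x1": x1, "x2": 2 * x1, "x3": rng.normal(size=100)}))
    assert np.isinf(out["x1"]) and np.isinf(out["x2"])
    assert np.isfinite(out["x3"])


def test_vif_too_few_rows_raises(rng):
    with pytest.raises(DataError):
        vif(pd.DataFrame(rng.normal(size=(3, 4))))
    with pytest.raises(DataError):
        vif(pd.DataFrame({"x": [1.0, 2.0, 3.0]}))


def test_vif_matches_statsmodels(rng):
    X = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
    X["d"] = X["a"] * 0.8 + rng.normal(0, 0.5, 200)
    ours = vif(X)
    design = sm.add_constant(X)
    arr = design.to_numpy()
    for i, col in enumerate(X.columns, start=1):
        assert ours[col] == pytest.approx(variance_inflation_factor(arr, i), rel=1e-8)


# ---------------------------------------------------------------- integration

def test_carrier_association_model_object(annotated, dense_config):
    aset = build_analysis_set(annotated, "ALL_P", "male", groups=dense_config.groups)
    res = CarrierAssociation(aset, "fdf_high", kind="logistic").fit()
    assert res.group == "ALL_P" and res.sex == "male"
    assert res.p_raw <= 1.0
    assert "OR" in res.summary()


def test_run_stratified_patterns(annotated, dense_config):
    from fabrykit.cvrisk import CVRiskModel

    cv = CVRiskModel(annotated, outcome="fdf_high").fit()
    strata = cv.stratify(annotated)
    results = run_stratified(annotated, dense_config.groups, strata)
    frame = {(r.group, r.sex, r.stratum): r for r in results}
    # pathogenic unconditional effect: elevated in both strata
    assert frame[("ALL_P", "male", "high")].effect > 1.0
    assert frame[("ALL_P", "male", "low")].effect > 1.0
    # every result carries a BH-adjusted p no smaller than its raw p
    for r in results:
        if r.p_adjusted is not None:
            assert r.p_adjusted >= r.p_raw - 1e-12
    # stratified models are CV-unadjusted by design
    assert all(r.covariates == () for r in results)
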