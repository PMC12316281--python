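"""Weighted regression stage: closed forms, cross-checks, simulations."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from foodexposure import (
    ExposureModel,
    bivariate_screen,
    compare_measures,
    fit_linear_area,
    fit_logistic,
    fit_multinomial,
    gvif,
)
from foodexposure.errors import (
    RankDeficiencyError,
    SeparationWarning,
    SingularDesignError,
)
from foodexposure.mnlogit import fit_intercept_only, fit_mnlogit


def _table_to_frame(table, outcome_levels, cov_levels, outcome, cov):
    """Expand a contingency table (rows = covariate, cols = outcome)."""
    rows = []
    for i, cl in enumerate(cov_levels):
        for j, ol in enumerate(outcome_levels):
            rows += [{cov: cl, outcome: ol}] * int(table[i][j])
    return pd.DataFrame(rows)


# ---------------------------------------------------------------- mnl core
def test_weighted_mnl_matches_statsmodels_at_unit_weights(rng):
    """Our Newton MNL equals statsmodels MNLogit when weights are 1."""
    n = 400
    x = rng.normal(size=n)
    z = rng.choice([0.0, 1.0], n)
    eta1 = -0.3 + 0.8 * x + 0.5 * z
    eta2 = 0.2 - 0.4 * x + 0.1 * z
    denom = 1 + np.exp(eta1) + np.exp(eta2)
    u = rng.uniform(size=n)
    p1 = np.exp(eta1) / denom
    p2 = np.exp(eta2) / denom
    y = np.where(u < p1, 1, np.where(u < p1 + p2, 2, 0))
    X = np.column_stack([np.ones(n), x, z])
    ours = fit_mnlogit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref = sm.MNLogit(y, X).fit(disp=0)
    assert np.allclose(ours.params, ref.params.T, atol=1e-5)
    assert ours.llf == pytest.approx(ref.llf, abs=1e-6)
    assert np.allclose(ours.bse, np.asarray(ref.bse).T, atol=1e-4)


def test_intercept_only_loglik_closed_form(rng):
    y = rng.choice(3, size=200, p=[0.5, 0.3, 0.2])
    w = rng.uniform(0.5, 2.0, 200)
    X = np.ones((200, 1))
    assert fit_intercept_only(y, w) == pytest.approx(
        fit_mnlogit(y, X, w).llf, abs=1e-6
    )


# ------------------------------------------------------------- multinomial
def test_multinomial_or_matches_2x3_cross_products():
    """Single binary covariate: ORs equal the table's cross-product ratios."""
    table = [[30, 20, 10], [15, 25, 35]]  # rows: cov in {ref, other}
    df = _table_to_frame(
        table, ["T1", "T2", "T3"], ["no", "yes"], "n_stores_class", "car"
    )
    res = fit_multinomial(df, "n_stores_class", ["car"])
    est = res.estimates
    got = est[(est["level"] == "yes") & ~est["reference"]]
    or_t2 = (table[1][1] * table[0][0]) / (table[0][1] * table[1][0])
    or_t3 = (table[1][2] * table[0][0]) / (table[0][2] * table[1][0])
    by_contrast = dict(zip(got["contrast"], got["or_"]))
    assert np.log(by_contrast["T2 vs T1"]) == pytest.approx(np.log(or_t2), abs=1e-6)
    assert np.log(by_contrast["T3 vs T1"]) == pytest.approx(np.log(or_t3), abs=1e-6)


def test_weight_scale_invariance():
    table = [[30, 20, 10], [15, 25, 35]]
    df = _table_to_frame(
        table, ["T1", "T2", "T3"], ["no", "yes"], "n_stores_class", "car"
    )
    w = np.full(len(df), 1.0)
    a = fit_multinomial(df, "n_stores_class", ["car"], weights=w)
    b = fit_multinomial(df, "n_stores_class", ["car"], weights=2.0 * w)
    assert np.allclose(a.params, b.params, atol=1e-9)


def test_multinomial_null_ci_coverage(rng):
    """Null simulation: per-interval 95% Wald CI coverage of OR=1 lies in
    [0.90, 0.99] over 200 replicates."""
    covered = 0
    total = 0
    reps = 200
    for _ in range(reps):
        n = 300
        car = rng.choice(["no", "yes"], n)
        y = rng.choice(["T1", "T2", "T3"], n)
        df = pd.DataFrame({"car": car, "n_stores_class": y})
        est = fit_multinomial(df, "n_stores_class", ["car"]).estimates
        sub = est[~est["reference"]]
        covered += int(((sub["ci_low"] <= 1.0) & (sub["ci_high"] >= 1.0)).sum())
        total += len(sub)
    assert 0.90 <= covered / total <= 0.99


# ----------------------------------------------------------------- logistic
def test_logistic_or_equals_ad_over_bc():
    a, b, c, d = 40, 25, 15, 30  # exposed/outcome 2x2 with all cells > 0
    df = pd.DataFrame(
        {
            "fv_class": ["ge50"] * a + ["lt50"] * b + ["ge50"] * c + ["lt50"] * d,
            "car": ["yes"] * (a + b) + ["no"] * (c + d),
        }
    )
    res = fit_logistic(df, "fv_class", ["car"])
    est = res.estimates
    got = float(est.loc[(est["level"] == "yes") & ~est["reference"], "or_"].iloc[0])
    assert np.log(got) == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)


def test_logistic_planted_effect_recovered(rng):
    """Planted log-OR 0.7 at n=5000 estimated within 3 SE."""
    n = 5000
    x = rng.choice([0.0, 1.0], n)
    p = 1 / (1 + np.exp(-(-0.3 + 0.7 * x)))
    y = (rng.uniform(size=n) < p).astype(int)
    df = pd.DataFrame(
        {
            "fv_class": np.where(y == 1, "ge50", "lt50"),
            "car": np.where(x == 1, "yes", "no"),
        }
    )
    res = fit_logistic(df, "fv_class", ["car"])
    est = res.estimates
    row = est[(est["level"] == "yes") & ~est["reference"]].iloc[0]
    logor = np.log(row["or_"])
    se = (np.log(row["ci_high"]) - np.log(row["ci_low"])) / (2 * 1.959964)
    assert abs(logor - 0.7) <= 3 * se


def test_reference_level_or_is_one():
    df = pd.DataFrame(
        {
            "fv_class": ["ge50", "lt50"] * 30,
            "car": (["yes"] * 30 + ["no"] * 30),
        }
    )
    est = fit_logistic(df, "fv_class", ["car"]).estimates
    ref = est[est["reference"]].iloc[0]
    assert ref["level"] == "no"
    assert ref["or_"] == 1.0 and ref["ci_low"] == 1.0 and ref["ci_high"] == 1.0


# ------------------------------------------------------------------ linear
def test_linear_noiseless_perfect_fit(rng):
    n = 60
    x = rng.normal(size=n)
    df = pd.DataFrame({"area_km2": 2.0 + 3.0 * x, "x": x})
    res = fit_linear_area(df, "area_km2", ["x"])
    assert res.extra["r_squared"] == pytest.approx(1.0)
    assert res.extra["shapiro_stat"] == 1.0  # degenerate residuals


def test_linear_planted_zone_effect(rng):
    """Peri-urban +0.8 km2 planted effect recovered within 3 SE at n=699."""
    n = 699
    zone = rng.choice(["center", "pericentral", "periurban"], n)
    y = 1.5 + 0.8 * (zone == "periurban") + rng.normal(0, 0.5, n)
    df = pd.DataFrame({"area_km2": y, "home_location": zone})
    res = fit_linear_area(df, "area_km2", ["home_location"])
    est = res.estimates
    row = est[(est["level"] == "periurban") & ~est["reference"]].iloc[0]
    se = (row["ci_high"] - row["ci_low"]) / (2 * 1.959964)
    assert abs(row["or_"] - 0.8) <= 3 * se  # or_ column holds the coefficient


def test_linear_null_slope_coverage(rng):
    """Permuted outcome: slope CIs cover 0 in >=90% of 200 replicates."""
    n = 200
    cover = 0
    reps = 200
    for _ in range(reps):
        x = rng.choice(["no", "yes"], n)
        y = rng.normal(size=n)
        df = pd.DataFrame({"area_km2": y, "car": x})
        est = fit_linear_area(df, "area_km2", ["car"]).estimates
        row = est[~est["reference"]].iloc[0]
        if row["ci_low"] <= 0.0 <= row["ci_high"]:
            cover += 1
    assert 0.90 <= cover / reps <= 0.99


def test_rank_deficiency_raises(rng):
    n = 50
    x = rng.choice(["a", "b"], n)
    df = pd.DataFrame({"area_km2": rng.normal(size=n), "u": x, "v": x})
    with pytest.raises(RankDeficiencyError):
        fit_linear_area(df, "area_km2", ["u", "v"])


# --------------------------------------------------------------- screening
def test_screen_type_one_error_rate(rng):
    """Independent covariate rejected at the 0.2 threshold ~20% of the time."""
    rejections = 0
    reps = 300
    for _ in range(reps):
        n = 800
        df = pd.DataFrame(
            {
                "n_stores_class": rng.choice(["T1", "T2", "T3"], n),
                "car": rng.choice(["no", "yes"], n),
            }
        )
        if bivariate_screen(df, "n_stores_class", "car").keep:
            rejections += 1
    assert abs(rejections / reps - 0.2) <= 0.04


def test_screen_perfect_association_kept():
    df = pd.DataFrame(
        {
            "n_stores_class": ["T1"] * 30 + ["T2"] * 30 + ["T3"] * 30,
            "zone": ["a"] * 30 + ["b"] * 30 + ["c"] * 30,
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SeparationWarning)
        res = bivariate_screen(df, "n_stores_class", "zone")
    assert res.keep and res.p_value < 1e-10


def test_screen_constant_covariate_flagged():
    df = pd.DataFrame(
        {"n_stores_class": ["T1", "T2", "T3"] * 10, "car": ["yes"] * 30}
    )
    res = bivariate_screen(df, "n_stores_class", "car")
    assert not res.keep and res.flag == "degenerate"
    assert np.isnan(res.p_value)


def test_screen_empty_cell_warns_and_penalizes(rng):
    df = pd.DataFrame(
        {
            "n_stores_class": ["T1"] * 20 + ["T2"] * 20 + ["T3"] * 20,
            "car": ["no"] * 20 + ["yes"] * 40,  # T1 x yes cell empty
        }
    )
    with pytest.warns(SeparationWarning):
        res = bivariate_screen(df, "n_stores_class", "car")
    assert res.flag == "penalized"
    assert np.isfinite(res.p_value)


# --------------------------------------------------------------------- gvif
def test_gvif_orthogonal_design():
    n = 80
    x = np.tile([0.0, 1.0], n // 2)
    z = np.repeat([0.0, 1.0], n // 2)
    X = np.column_stack([x, z])
    rep = gvif(X, {"x": [0], "z": [1]})
    assert np.allclose(rep["gvif"], 1.0, atol=1e-9)
    assert bool(rep["acceptable"].all())
    assert np.allclose(rep["adjusted_gvif"], 1.0, atol=1e-9)


def test_gvif_matches_auxiliary_regression_vif(rng):
    """Single-df covariates: GVIF equals 1/(1-R^2_j) from OLS of x_j on rest."""
    n = 500
    base = rng.normal(size=n)
    X = np.column_stack(
        [
            base + rng.normal(0, 0.8, n),
            base + rng.normal(0, 1.2, n),
            rng.normal(size=n),
        ]
    )
    rep = gvif(X, {"a": [0], "b": [1], "c": [2]})
    for j, name in enumerate(["a", "b", "c"]):
        others = np.delete(X, j, axis=1)
        ols = sm.OLS(X[:, j], sm.add_constant(others)).fit()
        vif = 1.0 / (1.0 - ols.rsquared)
        got = float(rep.loc[rep["covariate"] == name, "gvif"].iloc[0])
        assert got == pytest.approx(vif, rel=1e-6)


def test_gvif_duplicated_covariate_singular(rng):
    x = rng.normal(size=100)
    X = np.column_stack([x, x])
    with pytest.raises(SingularDesignError):
        gvif(X, {"a": [0], "b": [1]})


def test_gvif_flag_threshold():
    n = 2000
    rng = np.random.default_rng(5)
    base = rng.normal(size=n)
    X = np.column_stack([base + rng.normal(0, 0.1, n), base])
    out = gvif(X, {"a": [0], "b": [1]})
    assert (out["adjusted_gvif"] >= 1.0 - 1e-9).all()
    assert not out["acceptable"].any()  # heavy collinearity -> flagged


# ------------------------------------------------------- model facade / API
def test_model_facade_summary_and_gvif(rng):
    n = 400
    df = pd.DataFrame(
        {
            "n_stores_class": rng.choice(["T1", "T2", "T3"], n),
            "car": rng.choice(["no", "yes"], n),
            "age": rng.choice(["<35", "35-50", ">50"], n),
        }
    )
    res = ExposureModel.from_dataframe(
        df, "n_stores_class", ["car", "age"]
    ).fit()
    text = res.summary()
    assert "n_stores_class" in text and "car" in text
    g = res.gvif()
    assert set(g["covariate"]) == {"car", "age"}
    assert (g["gvif"] >= 1.0 - 1e-9).all()
    assert int(g.loc[g["covariate"] == "age", "df"].iloc[0]) == 2


# --------------------------------------------------------------- comparison
def test_compare_identical_inputs_no_flips():
    est = pd.DataFrame(
        {
            "outcome": ["n_stores_class"] * 2,
            "area_kind": ["home_buffer"] * 2,
            "covariate": ["car", "car"],
            "level": ["no", "yes"],
            "contrast": ["T3 vs T1"] * 2,
            "or_": [1.0, 0.5],
            "ci_low": [1.0, 0.3],
            "ci_high": [1.0, 0.9],
            "p": [np.nan, 0.01],
            "reference": [True, False],
        }
    )
    other = est.assign(area_kind="activity_space")
    cmp = compare_measures(est, other)
    assert not cmp["flip"].any()
    assert len(compare_measures(est.iloc[:0], other.iloc[:0])) == 0


def test_compare_detects_flip():
    home = pd.DataFrame(
        {
            "outcome": ["n_stores_class"],
            "area_kind": ["home_buffer"],
            "covariate": ["car"],
            "level": ["yes"],
            "contrast": ["T3 vs T1"],
            "or_": [0.5],
            "ci_low": [0.3],
            "ci_high": [0.9],
            "p": [0.01],
            "reference": [False],
        }
    )
    act = home.assign(area_kind="activity_space", p=0.6, ci_high=1.4)
    cmp = compare_measures(home, act)
    assert bool(cmp["flip"].iloc[0])
    assert bool(cmp["significant_home"].iloc[0])
    assert not bool(cmp["significant_activity"].iloc[0])
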