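"""Standardization, combined-stress imputation and selection-gradient fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import rosette as r
from rosette.selection import FITNESS_FAMILY
from rosette.simulate import FITNESS_MEASURE


def _inv_logit(x):
    return 1.0 / (1.0 + np.exp(-x))


def test_standardize_mean_zero_sd_one():
    df = pd.DataFrame(
        {"treatment": ["a"] * 3 + ["b"] * 4, "size": [1.0, 2, 3, 10, 20, 30, 40]}
    )
    out = r.standardize_within_treatment(df, traits=("size",))
    assert out.loc[out["treatment"] == "a", "size"].tolist() == [-1.0, 0.0, 1.0]
    for _, grp in out.groupby("treatment"):
        assert grp["size"].mean() == pytest.approx(0.0, abs=1e-10)
        assert grp["size"].std(ddof=1) == pytest.approx(1.0, abs=1e-10)


def test_standardize_idempotent():
    rng = np.random.default_rng(0)
    df = pd.DataFrame({"treatment": ["a"] * 50, "sla": rng.normal(20, 3, 50)})
    once = r.standardize_within_treatment(df, traits=("sla",))
    twice = r.standardize_within_treatment(once, traits=("sla",))
    assert np.allclose(once["sla"], twice["sla"], atol=1e-10)


def test_standardize_zero_variance_dropped():
    df = pd.DataFrame({"treatment": ["a"] * 5, "sla": [2.0] * 5})
    out = r.standardize_within_treatment(df, traits=("sla",))
    assert out["sla"].isna().all()


def test_combine_family_means_arithmetic():
    heat = pd.Series({"F1": 20.0, "F2": 20.0})
    drought = pd.Series({"F1": 30.0, "F3": 12.0})
    imputed, single = r.combine_family_means(heat, drought)
    assert imputed["F1"] == pytest.approx(25.0)
    assert imputed["F2"] == pytest.approx(20.0) and single["F2"]
    assert imputed["F3"] == pytest.approx(12.0) and single["F3"]
    assert not single["F1"]


def test_impute_combined_stress_table():
    rows = []
    for trt, fam, sla in [
        ("heat", "F1", 20.0), ("heat", "F1", 22.0),
        ("drought", "F1", 30.0),
        ("heat_drought", "F1", np.nan), ("heat_drought", "F1", np.nan),
        ("heat_drought", "F2", np.nan),
        ("control", "F1", 99.0),
    ]:
        rows.append({"treatment": trt, "family": fam, "sla": sla})
    df = pd.DataFrame(rows)
    out = r.impute_combined_stress_traits(df, traits=("sla",))
    combined = out[out["treatment"] == "heat_drought"]
    f1 = combined[combined["family"] == "F1"]["sla"]
    # family mean under heat = 21, under drought = 30 -> imputed 25.5,
    # identical for every plant of the family
    assert np.allclose(f1, 25.5)
    # family absent from both single-stress treatments stays missing
    assert combined[combined["family"] == "F2"]["sla"].isna().all()
    # other treatments untouched
    assert out.loc[out["treatment"] == "control", "sla"].iloc[0] == 99.0


def test_univariate_recovery_logit():
    """beta = 0.6 logit truth recovered within 2 SE in >= 90% of replicates."""
    hits = 0
    reps = 50
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        z = rng.normal(0, 1, 2000)
        w = (rng.random(2000) < _inv_logit(0.6 * z)).astype(float)
        res = r.fit_univariate_selection(z, w, "binomial")
        if abs(res.coef["x"] - 0.6) < 2 * res.se["x"]:
            hits += 1
    assert hits >= int(0.9 * reps)


def test_univariate_quadratic_model_choice():
    """Pure quadratic logit truth selects the quadratic model by AIC."""
    rng = np.random.default_rng(123)
    z = rng.normal(0, 1, 2000)
    w = (rng.random(2000) < _inv_logit(-0.5 * z**2)).astype(float)
    res = r.fit_univariate_selection(z, w, "binomial")
    assert res.model_form == "linear+quadratic"
    assert res.aic_quadratic < res.aic_linear


def test_irls_agrees_with_direct_likelihood_optimizer():
    """Logit gradient from the GLM equals a brute-force ML optimum on a
    small instance."""
    rng = np.random.default_rng(5)
    z = rng.normal(0, 1, 50)
    w = (rng.random(50) < _inv_logit(0.8 * z)).astype(float)
    res = r.fit_univariate_selection(z, w, "binomial")
    b = res.coef

    def negll(theta):
        eta = theta[0] + theta[1] * z + (theta[2] * z**2 if len(theta) == 3 else 0.0)
        p = np.clip(_inv_logit(eta), 1e-12, 1 - 1e-12)
        return -np.sum(w * np.log(p) + (1 - w) * np.log(1 - p))

    k = 3 if res.model_form == "linear+quadratic" else 2
    x0 = np.zeros(k)
    opt = minimize(negll, x0, method="BFGS")
    fitted = [b["const"], b["x"]] + ([b["x2"]] if k == 3 else [])
    assert np.allclose(fitted, opt.x, atol=1e-5)


def test_separation_flagged_non_estimable():
    z = np.linspace(-2, 2, 40)
    w = (z > 0).astype(float)  # perfectly separated
    res = r.fit_univariate_selection(z, w, "binomial")
    assert not res.estimable


def test_binary_fitness_needs_both_outcomes():
    z = np.random.default_rng(0).normal(0, 1, 20)
    with pytest.raises(ValueError, match="both outcomes"):
        r.fit_univariate_selection(z, np.ones(20), "binomial")


def test_multivariate_null_coefficients():
    """Only trait 1 causal: gradients for traits 2-6 center on zero."""
    cover = np.zeros(5)
    reps = 40
    for seed in range(reps):
        rng = np.random.default_rng(1000 + seed)
        Z = pd.DataFrame(rng.normal(0, 1, (1500, 6)), columns=list(r.TRAITS))
        w = (rng.random(1500) < _inv_logit(0.6 * Z["size"])).astype(float)
        res = r.fit_multivariate_selection(Z, w.to_numpy(), "binomial")
        for i, trait in enumerate(list(r.TRAITS)[1:]):
            cover[i] += abs(res.coef[trait]) < 2 * res.se[trait]
    assert (cover / reps >= 0.85).all()


def test_multivariate_deconfounds_correlated_traits():
    """Direct selection on trait 1 with r = 0.7 trait correlation: the
    univariate coefficient on trait 2 is biased away from zero, the
    multivariate gradient is not."""
    rng = np.random.default_rng(77)
    n = 4000
    z1 = rng.normal(0, 1, n)
    z2 = 0.7 * z1 + np.sqrt(1 - 0.49) * rng.normal(0, 1, n)
    w = (rng.random(n) < _inv_logit(0.8 * z1)).astype(float)
    uni = r.fit_univariate_selection(z2, w, "binomial")
    Z = pd.DataFrame({"size": z1, "x_mid": z2})
    multi = r.fit_multivariate_selection(Z, w, "binomial")
    assert abs(uni.coef["x"]) > 3 * uni.se["x"]  # confounded
    assert abs(multi.coef["x_mid"]) < 2.5 * multi.se["x_mid"]  # deconfounded


def test_intercept_only_fitness_gives_no_significant_gradients():
    rng = np.random.default_rng(9)
    Z = pd.DataFrame(rng.normal(0, 1, (500, 6)), columns=list(r.TRAITS))
    w = rng.normal(30.0, 5.0, 500)  # longevity independent of traits
    res = r.fit_multivariate_selection(Z, w, "gaussian")
    assert all(res.pvalues[t] > 0.001 for t in r.TRAITS)


def test_aliased_trait_dropped():
    rng = np.random.default_rng(4)
    Z = pd.DataFrame(rng.normal(0, 1, (100, 3)), columns=["a", "b", "c"])
    Z["c"] = Z["a"] + Z["b"]  # exact collinearity
    w = rng.normal(10, 1, 100)
    res = r.fit_multivariate_selection(Z, w, "gaussian")
    assert res.estimable
    assert "c" not in res.coef


def test_treatment_fitness_mapping():
    assert FITNESS_MEASURE == {
        "control": "flowered",
        "heat": "survived",
        "drought": "survived",
        "heat_drought": "longevity",
    }
    assert FITNESS_FAMILY["flowered"] == "binomial"
    assert FITNESS_FAMILY["longevity"] == "gaussian"


def test_run_selection_analysis_shapes(small_experiment, small_config):
    plants, states = small_experiment
    areas = r.simulate_all_series(states, small_config)
    gt = r.fit_all_plants(areas)
    table = r.build_trait_table(plants, gt, correct=False)
    res = r.run_selection_analysis(table)
    assert set(res["treatment"]) <= set(r.TREATMENTS)
    for trt, grp in res.groupby("treatment"):
        assert grp["fitness_measure"].iloc[0] == FITNESS_MEASURE[trt]
    # reported form is the AIC arg-min of the two candidates
    ok = res.dropna(subset=["aic_linear", "aic_quadratic"])
    quad = ok["model_form"] == "linear+quadratic"
    assert (ok.loc[quad, "aic_quadratic"] < ok.loc[quad, "aic_linear"]).all()
    assert (ok.loc[~quad, "aic_linear"] <= ok.loc[~quad, "aic_quadratic"]).all()
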