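"""Rank-sum contrasts, correlations, PCA and the factorial validator."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import rosette as r


def enumeration_rank_sum_p(a, b):
    """Independent oracle: exact two-sided p by enumerating every assignment
    of the pooled ranks to group A."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = len(a)
    obs = ranks[:na].sum()
    null = [sum(c) for c in itertools.combinations(ranks, na)]
    null = np.asarray(null)
    center = null.mean()
    p = np.mean(np.abs(null - center) >= abs(obs - center) - 1e-12)
    return min(float(p), 1.0)


def test_exact_p_simple_case():
    # {1,2,3} vs {4,5,6}: most extreme split, two-sided p = 2/20
    _, p = r.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], mode="exact")
    assert p == pytest.approx(0.1)


def test_identical_multisets_p_one():
    stat, p = r.wilcoxon_rank_sum([1.0, 2.0], [1.0, 2.0])
    assert p >= 0.99
    s2, p2 = r.wilcoxon_rank_sum([3.0] * 4, [3.0] * 5)
    assert p2 == 1.0 and s2 == pytest.approx(10.0)  # U at null center


def test_exact_matches_enumeration_exhaustively():
    """Exact p equals the enumeration oracle for every split of 1..n into
    groups, all combined sizes up to 10."""
    for n in range(4, 11):
        values = np.arange(1.0, n + 1.0)
        for na in range(2, n - 1):
            for combo in itertools.combinations(range(n), na):
                a = values[list(combo)]
                b = np.delete(values, list(combo))
                _, p = r.wilcoxon_rank_sum(a, b, mode="exact")
                assert p == pytest.approx(enumeration_rank_sum_p(a, b), abs=1e-12)


def test_null_p_uniform():
    """Null calibration at n = 30 per group: replicate p-values look U(0,1)."""
    rng = np.random.default_rng(21)
    ps = []
    for _ in range(1000):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0, 1, 30)
        ps.append(r.wilcoxon_rank_sum(a, b, mode="approx")[1])
    ks = stats.kstest(ps, "uniform")
    assert ks.pvalue > 0.01


def test_empty_group_raises():
    with pytest.raises(ValueError):
        r.wilcoxon_rank_sum([], [1.0])


def test_edge_contrast_structure(small_experiment, small_config):
    plants, _ = small_experiment
    table = r.edge_contrast_table(plants, traits=("survived", "flowered", "size"))
    # flowering rows only for treatments where any plant flowered
    flowering_treatments = set(
        plants.loc[plants["flowered"] == 1, "treatment"].unique()
    )
    assert set(table.loc[table["trait"] == "flowered", "treatment"]) <= flowering_treatments
    assert ((table["p"] > 0) & (table["p"] <= 1)).all()
    # one row per trait x treatment with data
    assert not table.duplicated(["trait", "treatment"]).any()


def test_edge_contrast_type_I_rate():
    """Identical group distributions: ~5% of contrasts significant."""
    rng = np.random.default_rng(3)
    sig = total = 0
    for rep in range(60):
        df = pd.DataFrame(
            {
                "population": rng.choice(["SE", "SW", "NE", "NW", "C"], 120),
                "treatment": rng.choice(["control", "heat"], 120),
                "family": "F1",
                "size": rng.normal(0, 1, 120),
            }
        )
        tab = r.edge_contrast_table(df, traits=("size",))
        sig += int((tab["p"] < 0.05).sum())
        total += len(tab)
    rate = sig / total
    assert 0.005 <= rate <= 0.12  # binomial band around 0.05


def test_correlation_matches_direct_formula():
    rng = np.random.default_rng(8)
    df = pd.DataFrame(rng.normal(0, 1, (10, 6)), columns=list(r.TRAITS))
    corr, p, n = r.correlation_matrix(df)
    for i in r.TRAITS:
        assert corr.loc[i, i] == 1.0
        for j in r.TRAITS:
            x, y = df[i], df[j]
            brute = ((x - x.mean()) * (y - y.mean())).sum() / (
                np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            )
            assert corr.loc[i, j] == pytest.approx(brute, abs=1e-12)
    assert np.allclose(corr, corr.T)


def test_correlation_exact_negative():
    df = pd.DataFrame({"size": [1.0, 2, 3, 4], "x_mid": [4.0, 3, 2, 1]})
    corr, _, _ = r.correlation_matrix(df, traits=("size", "x_mid"))
    assert corr.loc["size", "x_mid"] == pytest.approx(-1.0)


def test_correlation_constant_trait_absent():
    df = pd.DataFrame({"size": [1.0, 2, 3, 4], "x_mid": [2.0, 2, 2, 2]})
    corr, _, _ = r.correlation_matrix(df, traits=("size", "x_mid"))
    assert np.isnan(corr.loc["size", "x_mid"])


def test_pca_two_perfect_traits():
    df = pd.DataFrame({"size": [1.0, 2, 3, 4, 5], "x_mid": [2.0, 4, 6, 8, 10]})
    loadings, scores, evals = r.pca_per_treatment(df, traits=("size", "x_mid"))
    assert evals[0] == pytest.approx(2.0)
    assert evals.sum() == pytest.approx(2.0)


def test_pca_reconstruction_and_invariance():
    rng = np.random.default_rng(15)
    df = pd.DataFrame(rng.normal(0, 1, (60, 6)), columns=list(r.TRAITS))
    loadings, scores, evals = r.pca_per_treatment(df)
    assert evals.sum() == pytest.approx(6.0)
    # orthogonal reconstruction of the standardized data
    Z = (df - df.mean()) / df.std(ddof=1)
    back = scores.to_numpy() @ loadings.to_numpy().T
    assert np.allclose(back, Z.to_numpy(), atol=1e-10)
    # sign convention
    for col in loadings.columns:
        v = loadings[col].to_numpy()
        assert v[np.argmax(np.abs(v))] > 0
    # affine rescaling of any trait leaves the correlation-based PCA alone
    df2 = df.copy()
    df2["sla"] = 100.0 * df2["sla"] - 7.0
    l2, s2, e2 = r.pca_per_treatment(df2)
    assert np.allclose(e2, evals, atol=1e-10)
    assert np.allclose(np.abs(l2.to_numpy()), np.abs(loadings.to_numpy()), atol=1e-10)


def test_factorial_additivity_arithmetic():
    """Noise-free cell means 10/8/7/2: interaction = 2 - (10 - 2 - 3) = -3."""
    cells = {(0, 0): 10.0, (1, 0): 8.0, (0, 1): 7.0, (1, 1): 2.0}
    h, d, y = [], [], []
    for (hh, dd), mean in cells.items():
        for _ in range(5):
            h.append(hh); d.append(dd); y.append(mean)
    res = r.factorial_effects(y, h, d)
    assert res.loc["const", "coef"] == pytest.approx(10.0)
    assert res.loc["heat", "coef"] == pytest.approx(-2.0)
    assert res.loc["drought", "coef"] == pytest.approx(-3.0)
    assert res.loc["heat_x_drought", "coef"] == pytest.approx(-3.0)
    # balanced noise-free cells are reproduced exactly by the linear predictor
    pred = (
        res.loc["const", "coef"]
        + res.loc["heat", "coef"] * np.array(h)
        + res.loc["drought", "coef"] * np.array(d)
        + res.loc["heat_x_drought", "coef"] * np.array(h) * np.array(d)
    )
    assert np.allclose(pred, y)


def test_factorial_zero_interaction_coverage():
    hits = 0
    reps = 50
    for seed in range(reps):
        rng = np.random.default_rng(seed)
        h = np.repeat([0, 1, 0, 1], 40)
        d = np.repeat([0, 0, 1, 1], 40)
        y = 10.0 - 2.0 * h - 1.0 * d + rng.normal(0, 1, 160)
        res = r.factorial_effects(y, h, d)
        ci = 2 * res.loc["heat_x_drought", "se"]
        hits += abs(res.loc["heat_x_drought", "coef"]) < ci
    assert hits >= int(0.85 * reps)


def test_factorial_empty_cell_raises():
    with pytest.raises(ValueError, match="cells"):
        r.factorial_effects([1.0, 2.0], [0, 1], [0, 0])
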