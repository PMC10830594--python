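"""Descriptive and comparative statistics across populations and treatments.

South-vs-north rank-sum contrasts of traits and performance per treatment,
per-treatment Pearson trait correlations, a correlation-matrix PCA, and a
simplified fixed-effects 2x2 factorial estimator used to validate synthetic
experiments (it is not a mixed-model reproduction of the full analysis).

Two-sided p-values throughout; no multiple-testing correction is applied.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .simulate import SOUTHERN_POPULATIONS, TRAITS

logger = logging.getLogger(__name__)

EXACT_MAX_N = 12  # exact rank-sum enumeration up to this combined group size


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon/Mann-Whitney rank-sum test.

    Returns ``(U statistic of the first group, p)``. ``mode='exact'``
    enumerates the permutation null (valid without ties); ``'approx'`` uses
    the normal approximation with tie and continuity corrections; ``'auto'``
    picks exact when ``len(a) + len(b) <= 12`` and the data are tie-free.
    Identical pooled values return p = 1 at the null-centered statistic.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return len(a) * len(b) / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if mode == "auto":
        mode = "exact" if (len(pooled) <= EXACT_MAX_N and not has_ties) else "approx"
    if mode == "exact":
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif mode == "approx":
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def edge_contrast_table(
    plants: pd.DataFrame,
    traits=("survived", "flowered") + TRAITS,
    treatments=None,
    south: frozenset = SOUTHERN_POPULATIONS,
    mode: str = "auto",
    family_means: bool = False,
) -> pd.DataFrame:
    """Southern (SE, SW) vs northern/central rank-sum contrast per trait and
    treatment.

    Flowering is only contrasted in treatments where any flowering occurred;
    a treatment cell missing either group yields no row (absent, not p=1).
    With ``family_means=True`` the test unit is the family mean instead of
    the plant.
    """
    treatments = treatments or sorted(plants["treatment"].unique())
    rows = []
    for treatment in treatments:
        cell = plants[plants["treatment"] == treatment]
        south_mask = cell["population"].isin(south)
        for trait in traits:
            if trait not in cell.columns:
                continue
            if trait == "flowered" and cell["flowered"].fillna(0).sum() == 0:
                continue
            sub = cell[[trait, "family"]].assign(south=south_mask)
            if family_means:
                sub = (
                    sub.groupby(["family", "south"], as_index=False)[trait].mean()
                )
            va = sub.loc[sub["south"], trait].dropna().to_numpy()
            vb = sub.loc[~sub["south"], trait].dropna().to_numpy()
            if len(va) == 0 or len(vb) == 0:
                continue
            stat, p = wilcoxon_rank_sum(va, vb, mode=mode)
            rows.append(
                {
                    "trait": trait,
                    "treatment": treatment,
                    "n_south": len(va),
                    "n_north": len(vb),
                    "statistic": stat,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def correlation_matrix(
    table: pd.DataFrame, traits=TRAITS
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson correlations with t-distribution p-values.

    Returns (r, p, n) trait-by-trait frames; pairs with fewer than 3 complete
    cases or a constant trait get NaN.
    """
    traits = [t for t in traits if t in table.columns]
    k = len(traits)
    r = pd.DataFrame(np.eye(k), index=traits, columns=traits)
    p = pd.DataFrame(np.nan, index=traits, columns=traits)
    n = pd.DataFrame(0, index=traits, columns=traits, dtype=int)
    for i, ti in enumerate(traits):
        n.loc[ti, ti] = int(table[ti].notna().sum())
        for j in range(i + 1, k):
            tj = traits[j]
            sub = table[[ti, tj]].dropna()
            n.loc[ti, tj] = n.loc[tj, ti] = len(sub)
            if len(sub) < 3 or sub[ti].nunique() < 2 or sub[tj].nunique() < 2:
                r.loc[ti, tj] = r.loc[tj, ti] = np.nan
                continue
            res = stats.pearsonr(sub[ti], sub[tj])
            r.loc[ti, tj] = r.loc[tj, ti] = float(res.statistic)
            p.loc[ti, tj] = p.loc[tj, ti] = float(res.pvalue)
    return r, p, n


def pca_per_treatment(
    table: pd.DataFrame, traits=TRAITS
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of the trait correlation matrix on complete cases.

    Traits are standardized, constant traits dropped; components are ordered
    by decreasing eigenvalue and signed so each component's largest-magnitude
    loading is positive. Eigenvalues sum to the number of retained traits.

    Returns (loadings [trait x PC], scores [case x PC], eigenvalues).
    """
    traits = [t for t in traits if t in table.columns]
    data = table[traits].dropna()
    keep = [t for t in traits if data[t].nunique() > 1]
    dropped = set(traits) - set(keep)
    if dropped:
        logger.warning("constant traits dropped from PCA: %s", sorted(dropped))
    data = data[keep]
    if len(data) < len(keep) + 1:
        raise ValueError("PCA needs more complete cases than traits")
    Z = (data - data.mean()) / data.std(ddof=1)
    corr = np.corrcoef(Z.to_numpy(), rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    # sign convention: largest-magnitude loading positive
    for j in range(evecs.shape[1]):
        if evecs[np.argmax(np.abs(evecs[:, j])), j] < 0:
            evecs[:, j] *= -1
    pcs = [f"PC{j + 1}" for j in range(len(keep))]
    loadings = pd.DataFrame(evecs, index=keep, columns=pcs)
    scores = pd.DataFrame(Z.to_numpy() @ evecs, index=data.index, columns=pcs)
    return loadings, scores, evals


def factorial_effects(
    y,
    heat,
    drought,
    binary: bool = False,
) -> pd.DataFrame:
    """Fixed-effects 2x2 factorial fit: intercept, heat, drought, interaction.

    Control is the reference cell; the interaction coefficient measures the
    deviation of the combined cell from additivity (on the logit scale for
    binary outcomes). All four cells must be represented.
    """
    y = np.asarray(y, dtype=float)
    heat = np.asarray(heat, dtype=float)
    drought = np.asarray(drought, dtype=float)
    keep = np.isfinite(y)
    y, heat, drought = y[keep], heat[keep], drought[keep]
    cells = {(h, d) for h, d in zip(heat, drought)}
    if len(cells) < 4:
        raise ValueError("all four factorial cells must be non-empty")
    X = pd.DataFrame(
        {"const": 1.0, "heat": heat, "drought": drought, "heat_x_drought": heat * drought}
    )
    if binary:
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    else:
        res = sm.OLS(y, X).fit()
    return pd.DataFrame(
        {"coef": res.params, "se": res.bse, "p": res.pvalues}
    )
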