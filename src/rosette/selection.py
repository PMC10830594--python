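"""Phenotypic selection analysis on standardized traits.

Traits are standardized to mean 0 / sd 1 within treatment. Fitness is the
treatment's own measure — flowering propensity in the benign-temperature
control, survival under single heat or drought stress, longevity under
combined stress. Because functional traits are unmeasurable for the many
plants that die under combined stress, SLA, LDMC and root:shoot are replaced
there by family means averaged over the two single-stress treatments.

Univariate selection fits both ``W ~ z`` and ``W ~ z + z^2`` (logit-link
binomial GLM for binary fitness, ordinary least squares for longevity) and
reports the model with the lower AIC; multivariate gradients come from a
single linear model with all six traits. Quadratic coefficients are reported
as fitted, not doubled to a Lande-Arnold gamma.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import FITNESS_MEASURE, TRAITS

logger = logging.getLogger(__name__)

IMPUTED_TRAITS = ("sla", "ldmc", "root_shoot")


def standardize_within_treatment(
    table: pd.DataFrame,
    traits=TRAITS,
    treatment_col: str = "treatment",
) -> pd.DataFrame:
    """z-score each trait within each treatment (sample sd, n-1 denominator).

    A trait with zero variance in a treatment is set to NaN there (dropped
    from selection models) and logged.
    """
    out = table.copy()
    for trait in traits:
        if trait not in out.columns:
            continue

        def _z(x: pd.Series) -> pd.Series:
            sd = x.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                logger.warning("zero variance: trait %r dropped in one treatment", trait)
                return pd.Series(np.nan, index=x.index)
            return (x - x.mean()) / sd

        out[trait] = out.groupby(treatment_col, group_keys=False)[trait].apply(_z)
    return out


def combine_family_means(
    heat_means: pd.Series, drought_means: pd.Series
) -> tuple[pd.Series, pd.Series]:
    """Average the per-family trait means of the two single-stress treatments.

    Families present in only one treatment keep that single mean and are
    flagged ``single_source``; families absent from both are absent from the
    result (their plants drop out of the combined-stress analysis).
    """
    joined = pd.concat(
        {"heat": heat_means, "drought": drought_means}, axis=1
    )
    imputed = joined.mean(axis=1, skipna=True)
    single = joined.isna().any(axis=1) & ~joined.isna().all(axis=1)
    imputed = imputed.dropna()
    return imputed, single.reindex(imputed.index, fill_value=False)


def impute_combined_stress_traits(
    table: pd.DataFrame,
    traits=IMPUTED_TRAITS,
    family_col: str = "family",
    treatment_col: str = "treatment",
    combined: str = "heat_drought",
    sources: tuple[str, str] = ("heat", "drought"),
) -> pd.DataFrame:
    """Replace combined-stress functional traits by averaged family means.

    Operates on the analysis-scale (transformed, pre-standardization) trait
    table; only rows of the combined treatment and only ``traits`` are
    touched. Every plant of a family gets the same imputed value.
    """
    out = table.copy()
    mask = out[treatment_col] == combined
    for trait in traits:
        heat_means = (
            table.loc[table[treatment_col] == sources[0]]
            .groupby(family_col)[trait]
            .mean()
        )
        drought_means = (
            table.loc[table[treatment_col] == sources[1]]
            .groupby(family_col)[trait]
            .mean()
        )
        imputed, single = combine_family_means(heat_means, drought_means)
        if single.any():
            logger.info(
                "%s: %d families imputed from a single stress treatment",
                trait, int(single.sum()),
            )
        out.loc[mask, trait] = out.loc[mask, family_col].map(imputed).to_numpy()
    return out


@dataclass
class SelectionResult:
    """Coefficients of one selection model (Table-3-style row)."""

    treatment: str
    trait: str  # trait name, or "multivariate"
    fitness_measure: str
    model_form: str  # "linear" or "linear+quadratic"
    coef: dict[str, float] = field(default_factory=dict)
    se: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    aic_linear: float = float("nan")
    aic_quadratic: float = float("nan")
    estimable: bool = True


def _fit_glm(y: np.ndarray, X: pd.DataFrame, family: str):
    if family == "binomial":
        model = sm.GLM(y, X, family=sm.families.Binomial())
    elif family == "gaussian":
        model = sm.OLS(y, X)
    else:
        raise ValueError(f"unknown fitness family {family!r}")
    return model.fit()


def _is_separated(res, family: str) -> bool:
    if family != "binomial":
        return False
    # runaway coefficients / vanishing deviance signal complete separation
    return bool(np.any(np.abs(res.params) > 50) or not np.all(np.isfinite(res.bse)))


def fit_univariate_selection(
    z: np.ndarray,
    w: np.ndarray,
    family: str,
    treatment: str = "",
    trait: str = "",
    fitness_measure: str = "",
) -> SelectionResult:
    """AIC choice between ``W ~ z`` and ``W ~ z + z^2``; report the winner.

    Binary fitness uses a logit-link binomial GLM fit by iteratively
    reweighted least squares; longevity uses OLS. Complete separation marks
    the result non-estimable.
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    keep = np.isfinite(z) & np.isfinite(w)
    z, w = z[keep], w[keep]
    if len(z) < 10:
        raise ValueError("univariate selection needs at least 10 observations")
    if family == "binomial" and len(np.unique(w)) < 2:
        raise ValueError("binary fitness must include both outcomes")

    X_lin = sm.add_constant(pd.DataFrame({"x": z}))
    X_quad = sm.add_constant(pd.DataFrame({"x": z, "x2": z**2}))

    result = SelectionResult(
        treatment=treatment, trait=trait, fitness_measure=fitness_measure,
        model_form="linear",
    )
    try:
        res_lin = _fit_glm(w, X_lin, family)
        res_quad = _fit_glm(w, X_quad, family)
    except Exception:
        result.estimable = False
        return result
    if _is_separated(res_lin, family) or _is_separated(res_quad, family):
        result.estimable = False
        return result

    result.aic_linear = float(res_lin.aic)
    result.aic_quadratic = float(res_quad.aic)
    if result.aic_quadratic < result.aic_linear:
        result.model_form = "linear+quadratic"
        chosen = res_quad
    else:
        chosen = res_lin
    result.coef = {k: float(v) for k, v in chosen.params.items()}
    result.se = {k: float(v) for k, v in chosen.bse.items()}
    result.pvalues = {k: float(v) for k, v in chosen.pvalues.items()}
    return result


def fit_multivariate_selection(
    Z: pd.DataFrame,
    w: np.ndarray,
    family: str,
    treatment: str = "",
    fitness_measure: str = "",
) -> SelectionResult:
    """Linear selection gradients from one model with all traits.

    Rank-deficient designs drop aliased traits with a warning.
    """
    w = np.asarray(w, dtype=float)
    keep = np.isfinite(w) & Z.notna().all(axis=1).to_numpy()
    Z, w = Z.loc[keep], w[keep]
    if len(Z) < 10:
        raise ValueError("multivariate selection needs at least 10 complete cases")

    X = sm.add_constant(Z.astype(float))
    rank = np.linalg.matrix_rank(X.to_numpy())
    while rank < X.shape[1] and X.shape[1] > 1:
        # drop the last trait column involved in the rank deficiency
        dropped = X.columns[-1]
        logger.warning("aliased trait %r dropped from multivariate model", dropped)
        X = X.drop(columns=[dropped])
        rank = np.linalg.matrix_rank(X.to_numpy())

    result = SelectionResult(
        treatment=treatment, trait="multivariate",
        fitness_measure=fitness_measure, model_form="linear",
    )
    try:
        res = _fit_glm(w, X, family)
    except Exception:
        result.estimable = False
        return result
    if _is_separated(res, family):
        result.estimable = False
        return result
    result.coef = {k: float(v) for k, v in res.params.items()}
    result.se = {k: float(v) for k, v in res.bse.items()}
    result.pvalues = {k: float(v) for k, v in res.pvalues.items()}
    result.aic_linear = float(res.aic)
    return result


FITNESS_FAMILY = {
    "flowered": "binomial",
    "survived": "binomial",
    "longevity": "gaussian",
}


def run_selection_analysis(
    trait_table: pd.DataFrame,
    traits=TRAITS,
    impute_combined: bool = True,
) -> pd.DataFrame:
    """Table-3-style selection results for every treatment.

    Expects the analysis-scale trait table (six traits plus fate columns);
    applies the combined-stress imputation, standardizes within treatment,
    then fits per-trait univariate models and the multivariate linear model.
    """
    table = trait_table.copy()
    if impute_combined:
        table = impute_combined_stress_traits(table)
    table = standardize_within_treatment(table, traits=traits)

    rows = []
    for treatment, grp in table.groupby("treatment"):
        measure = FITNESS_MEASURE[treatment]
        family = FITNESS_FAMILY[measure]
        w = grp[measure].to_numpy(dtype=float)
        for trait in traits:
            try:
                r = fit_univariate_selection(
                    grp[trait].to_numpy(), w, family,
                    treatment=treatment, trait=trait, fitness_measure=measure,
                )
            except ValueError as exc:
                logger.warning("%s / %s skipped: %s", treatment, trait, exc)
                continue
            rows.append(
                {
                    "treatment": treatment,
                    "trait": trait,
                    "fitness_measure": measure,
                    "model_form": r.model_form,
                    "aic_linear": r.aic_linear,
                    "aic_quadratic": r.aic_quadratic,
                    "coef_x": r.coef.get("x", float("nan")),
                    "coef_x2": r.coef.get("x2", float("nan")),
                    "se_x": r.se.get("x", float("nan")),
                    "p_x": r.pvalues.get("x", float("nan")),
                    "estimable": r.estimable,
                    "multivariate_coef": float("nan"),
                }
            )
        try:
            rm = fit_multivariate_selection(
                grp[list(traits)], w, family,
                treatment=treatment, fitness_measure=measure,
            )
        except ValueError as exc:
            logger.warning("%s multivariate skipped: %s", treatment, exc)
            continue
        for row in rows:
            if row["treatment"] == treatment and np.isnan(row["multivariate_coef"]):
                row["multivariate_coef"] = rm.coef.get(row["trait"], float("nan"))
    return pd.DataFrame(rows)
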