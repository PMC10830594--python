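"""Functional traits from harvest records, transforms and nuisance correction.

Traits follow the standard plant-ecology definitions with deliberately mixed
units: SLA = rosette area [mm^2] per leaf dry mass [mg] (dead leaves
excluded); LDMC = leaf dry mass [mg] per leaf fresh mass [g] (dead leaves
excluded); root:shoot = root dry mass over the dry mass of all leaves plus
inflorescences. Growth rate, root:shoot, SLA and LDMC are log10-transformed
for analysis; size and x_mid stay on the raw scale.

Nuisance correction residualizes a trait against days-to-germination, block
and tray-within-block — each term only if it explains "considerable"
variance, operationalized as an ANOVA p below a configurable threshold — and
re-adds the grand mean, so corrected and raw traits share their mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

LOG10_TRAITS = ("growth_rate", "root_shoot", "sla", "ldmc")
ALL_TRAITS = ("size", "x_mid", "growth_rate", "sla", "ldmc", "root_shoot")


@dataclass(frozen=True)
class FunctionalTraits:
    sla: float  # mm^2 / mg
    ldmc: float  # mg / g
    root_shoot: float  # dimensionless


def compute_functional_traits(
    area_mm2: float,
    leaf_dry_mg: float,
    leaf_fresh_g: float,
    root_dry_mg: float,
    inflorescence_dry_mg: float = 0.0,
    dead_leaf_dry_mg: float = 0.0,
    include_dead_leaves_in_shoot: bool = True,
) -> FunctionalTraits:
    """SLA, LDMC and root:shoot for one harvested plant.

    A zero or missing denominator yields NaN for that trait (the plant is
    dropped for it downstream) rather than raising.
    """

    def _ratio(num: float, den: float) -> float:
        if den is None or not np.isfinite(den) or den <= 0 or not np.isfinite(num):
            return float("nan")
        return num / den

    shoot = leaf_dry_mg + inflorescence_dry_mg
    if include_dead_leaves_in_shoot:
        shoot = shoot + dead_leaf_dry_mg
    return FunctionalTraits(
        sla=_ratio(area_mm2, leaf_dry_mg),
        ldmc=_ratio(leaf_dry_mg, leaf_fresh_g),
        root_shoot=_ratio(root_dry_mg, shoot),
    )


def functional_trait_table(
    plants: pd.DataFrame, include_dead_leaves_in_shoot: bool = True
) -> pd.DataFrame:
    """Vectorized trait computation for a plant table with harvest columns."""
    out = plants[["plant"]].copy()
    dead = plants.get("dead_leaf_dry_mg", pd.Series(0.0, index=plants.index)).fillna(0.0)
    shoot = plants["leaf_dry_mg"] + plants["inflorescence_dry_mg"].fillna(0.0)
    if include_dead_leaves_in_shoot:
        shoot = shoot + dead

    def _safe(num, den):
        den = den.where(den > 0)
        return num / den

    out["sla"] = _safe(plants["harvest_area_mm2"], plants["leaf_dry_mg"])
    out["ldmc"] = _safe(plants["leaf_dry_mg"], plants["leaf_fresh_g"])
    out["root_shoot"] = _safe(plants["root_dry_mg"], shoot)
    return out


def transform_traits(traits: pd.DataFrame, columns=LOG10_TRAITS) -> pd.DataFrame:
    """log10-transform exactly the ratio-scale traits; others untouched.

    Nonpositive values become NaN (plant excluded for that trait) and are
    logged. Back-transforming with 10**x restores the input.
    """
    out = traits.copy()
    for col in columns:
        if col not in out.columns:
            continue
        vals = out[col].astype(float)
        bad = vals.notna() & (vals <= 0)
        if bad.any():
            logger.warning(
                "transform_traits: %d nonpositive values in %r set to NaN",
                int(bad.sum()), col,
            )
        out[col] = np.where(vals > 0, np.log10(vals.where(vals > 0)), np.nan)
    return out


def _term_design(covariates: pd.DataFrame, term: str) -> pd.DataFrame:
    """Design columns (without intercept) for one nuisance term."""
    if term == "germination_day":
        return covariates[["germination_day"]].astype(float)
    if term == "block":
        return pd.get_dummies(
            covariates["block"].astype(str), prefix="block", drop_first=True, dtype=float
        )
    if term == "tray":
        # tray nested within block: one level per (block, tray) combination
        lab = covariates["block"].astype(str) + "/" + covariates["tray"].astype(str)
        return pd.get_dummies(lab, prefix="tray", drop_first=True, dtype=float)
    raise ValueError(f"unknown nuisance term {term!r}")


def correct_for_nuisance(
    values: pd.Series,
    covariates: pd.DataFrame,
    terms: tuple[str, ...] = ("germination_day", "block", "tray"),
    alpha: float = 0.05,
    joint: bool = False,
) -> tuple[pd.Series, dict[str, float]]:
    """Residualize a trait against nuisance terms that explain real variance.

    For each term (in order: germination day, block, tray within block) an
    ANOVA-style F test of the term against the current values is run; when
    p < ``alpha`` the values are replaced by the OLS residuals plus the grand
    mean. With ``joint=True`` all passing terms are removed in a single
    regression instead of sequentially.

    Returns the corrected series and the per-term p-values. Aliased
    (singular) terms are dropped with a warning.
    """
    y = values.astype(float)
    mask = y.notna()
    pvals: dict[str, float] = {}
    selected: list[str] = []
    current = y.copy()

    for term in terms:
        X = _term_design(covariates, term)
        Xm = sm.add_constant(X[mask], has_constant="add")
        # factor levels absent after masking leave all-zero columns
        Xm = Xm.loc[:, (Xm != 0).any()]
        if np.linalg.matrix_rank(Xm.to_numpy()) < Xm.shape[1]:
            logger.warning("nuisance term %r aliased; dropped", term)
            pvals[term] = float("nan")
            continue
        if Xm.shape[1] < 2 or mask.sum() <= Xm.shape[1]:
            pvals[term] = float("nan")
            continue
        res = sm.OLS(current[mask], Xm).fit()
        p = float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0
        pvals[term] = p
        if p < alpha:
            selected.append(term)
            if not joint:
                grand = current[mask].mean()
                corrected = current.copy()
                corrected[mask] = res.resid + grand
                current = corrected

    if joint and selected:
        X = pd.concat([_term_design(covariates, t) for t in selected], axis=1)
        Xm = sm.add_constant(X[mask], has_constant="add")
        res = sm.OLS(y[mask], Xm).fit()
        corrected = y.copy()
        corrected[mask] = res.resid + y[mask].mean()
        current = corrected

    return current, pvals


def build_trait_table(
    plants: pd.DataFrame,
    growth_traits: pd.DataFrame,
    correct: bool = True,
    alpha: float = 0.05,
    include_dead_leaves_in_shoot: bool = True,
) -> pd.DataFrame:
    """Analysis-scale table of the six traits per plant.

    Joins growth traits (size, x_mid, growth rate) with the harvest-derived
    functional traits, log10-transforms the ratio traits, and optionally
    applies the nuisance correction per trait.
    """
    func = functional_trait_table(plants, include_dead_leaves_in_shoot)
    table = plants[
        ["plant", "population", "family", "treatment", "block", "tray",
         "germination_day", "survived", "flowered", "longevity"]
    ].merge(func, on="plant", how="left")
    table = table.merge(
        growth_traits[["plant", "size", "x_mid", "growth_rate"]],
        on="plant",
        how="left",
    )
    table = transform_traits(table)
    if correct:
        cov = table[["germination_day", "block", "tray"]]
        for trait in ALL_TRAITS:
            if table[trait].notna().sum() > 10:
                table[trait], _ = correct_for_nuisance(table[trait], cov, alpha=alpha)
    return table
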