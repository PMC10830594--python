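"""Growth-curve fitting, AIC model selection and growth-trait extraction.

Seven candidate models of rosette area over time are fit per plant by
nonlinear least squares, compared by the Gaussian-error AIC

    AIC = n * ln(RSS / n) + 2 * (k + 1)

(with the error variance counted as a parameter; additive constants drop out
of within-plant comparisons), and the best-supported model is the AIC
minimum, with ties broken toward fewer parameters. Growth traits — the
asymptote (*size*, mm^2), the inflection day (*x_mid*) and the slope at the
inflection (*growth rate*, ``A / (4 * scal)``) — are read off the fitted
three-parameter logistic.

Parameterizations:

========  =======================================  ======
model     area(t)                                  params
========  =======================================  ======
linear           a + b*t                           a, b
exponential      a * exp(b*t)                      a, b
power            a * t**b (b > 0, so area(0) = 0)  a, b
logistic2        A_obs / (1 + exp((x_mid-t)/scal)) x_mid, scal  (A fixed at max area)
logistic3        A / (1 + exp((x_mid-t)/scal))     A, x_mid, scal
von_bertalanffy  A * (1 - exp(-k*(t-t0)))          A, k, t0
gompertz         A * exp(-exp(-k*(t-Ti)))          A, k, Ti
========  =======================================  ======
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections import Counter

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

# fixed order: also the final tie-break in model selection
MODEL_ORDER = (
    "linear",
    "exponential",
    "power",
    "logistic2",
    "logistic3",
    "von_bertalanffy",
    "gompertz",
)

_N_PARAMS = {
    "linear": 2,
    "exponential": 2,
    "power": 2,
    "logistic2": 2,
    "logistic3": 3,
    "von_bertalanffy": 3,
    "gompertz": 3,
}

_PARAM_NAMES = {
    "linear": ("a", "b"),
    "exponential": ("a", "b"),
    "power": ("a", "b"),
    "logistic2": ("x_mid", "scal"),
    "logistic3": ("asymptote", "x_mid", "scal"),
    "von_bertalanffy": ("asymptote", "k", "t0"),
    "gompertz": ("asymptote", "k", "t_i"),
}

# floor on RSS inside the log so exact fits stay comparable; ties at the
# floor fall through to the parsimony tie-break
_RSS_FLOOR = 1e-12


def model_curve(name: str, t: np.ndarray, params: np.ndarray, a_fixed: float | None = None) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    p = np.asarray(params, dtype=float)
    if name == "linear":
        return p[0] + p[1] * t
    if name == "exponential":
        return p[0] * np.exp(np.clip(p[1] * t, -500, 500))
    if name == "power":
        b = p[1]
        return p[0] * np.where(t > 0, np.power(np.maximum(t, 1e-300), b), 0.0)
    if name == "logistic2":
        if a_fixed is None:
            raise ValueError("logistic2 needs the fixed asymptote a_fixed")
        return a_fixed / (1.0 + np.exp(np.clip((p[0] - t) / p[1], -500, 500)))
    if name == "logistic3":
        return p[0] / (1.0 + np.exp(np.clip((p[1] - t) / p[2], -500, 500)))
    if name == "von_bertalanffy":
        return p[0] * (1.0 - np.exp(np.clip(-p[1] * (t - p[2]), -500, 500)))
    if name == "gompertz":
        return p[0] * np.exp(-np.exp(np.clip(-p[1] * (t - p[2]), -500, 500)))
    raise ValueError(f"unknown model {name!r}")


@dataclass(frozen=True)
class GrowthFit:
    """One model fit to one area series."""

    model: str
    params: dict[str, float]
    rss: float
    n: int
    aic: float
    converged: bool
    a_fixed: float | None = None  # logistic2 only

    def predict(self, t) -> np.ndarray:
        p = np.array([self.params[k] for k in _PARAM_NAMES[self.model]])
        return model_curve(self.model, np.asarray(t, dtype=float), p, self.a_fixed)


@dataclass(frozen=True)
class GrowthTraits:
    """The three growth traits of the sigmoid fit."""

    size: float  # asymptote, mm^2
    x_mid: float  # days to inflection
    growth_rate: float  # slope at inflection, mm^2 / day


def gaussian_nls_aic(rss: float, n: int, k: int) -> float:
    """n*ln(RSS/n) + 2*(k+1); the +1 counts the error variance."""
    return n * math.log(max(rss, _RSS_FLOOR) / n) + 2 * (k + 1)


def _initial_guess(name: str, t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Documented heuristics: asymptote <- 1.05*max; x_mid <- day nearest
    half-max; scal <- day range / 4."""
    a0 = 1.05 * max(y.max(), 1e-6)
    half_idx = int(np.argmin(np.abs(y - y.max() / 2.0)))
    xm0 = float(t[half_idx])
    rng = float(t.max() - t.min())
    sc0 = max(rng / 4.0, 1e-3)
    if name == "linear":
        b = (y[-1] - y[0]) / rng if rng > 0 else 0.0
        return np.array([y[0], b])
    if name == "exponential":
        pos = y > 0
        if pos.sum() >= 2:
            coef = np.polyfit(t[pos], np.log(y[pos]), 1)
            return np.array([max(math.exp(coef[1]), 1e-6), coef[0]])
        return np.array([max(y[0], 1e-3), 0.1])
    if name == "power":
        return np.array([max(y.max(), 1e-3) / max(t.max(), 1.0) ** 1.5, 1.5])
    if name == "logistic2":
        return np.array([xm0, sc0])
    if name == "logistic3":
        return np.array([a0, xm0, sc0])
    if name == "von_bertalanffy":
        return np.array([a0, 1.0 / (2.0 * sc0), max(xm0 - 2.0 * sc0, 0.0)])
    if name == "gompertz":
        return np.array([a0, 1.0 / sc0, xm0])
    raise ValueError(f"unknown model {name!r}")


_BOUNDS = {
    "linear": ((-np.inf, -np.inf), (np.inf, np.inf)),
    "exponential": ((1e-9, -np.inf), (np.inf, np.inf)),
    "power": ((1e-12, 1e-6), (np.inf, 10.0)),
    "logistic2": ((-np.inf, 1e-6), (np.inf, np.inf)),
    "logistic3": ((1e-6, -np.inf, 1e-6), (np.inf, np.inf, np.inf)),
    "von_bertalanffy": ((1e-6, 1e-9, -np.inf), (np.inf, np.inf, np.inf)),
    "gompertz": ((1e-6, 1e-9, -np.inf), (np.inf, np.inf, np.inf)),
}


def fit_growth_model(series: pd.DataFrame, model: str) -> GrowthFit:
    """Least-squares fit of one model to one plant's (day, area_mm2) series.

    Non-convergence after three perturbed restarts yields a flagged fit with
    AIC = +inf; too few points raises.
    """
    if model not in _N_PARAMS:
        raise ValueError(f"unknown model {model!r}")
    t = np.asarray(series["day"], dtype=float)
    y = np.asarray(series["area_mm2"], dtype=float)
    k = _N_PARAMS[model]
    if len(t) < k + 1:
        raise ValueError(f"{model} needs at least {k + 1} points, got {len(t)}")
    if len(np.unique(t)) < 2:
        raise ValueError("series needs at least 2 distinct days")

    a_fixed = float(y.max()) if model == "logistic2" else None
    if model == "logistic2" and a_fixed <= 0:
        a_fixed = 1e-6

    def resid(p: np.ndarray) -> np.ndarray:
        return model_curve(model, t, p, a_fixed) - y

    x0 = _initial_guess(model, t, y)
    lo, hi = _BOUNDS[model]
    x0 = np.clip(x0, np.asarray(lo) + 1e-12, np.asarray(hi))

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(4):  # initial guess + 3 perturbed restarts
        start = x0 if attempt == 0 else np.clip(
            x0 * rng.uniform(0.5, 1.5, size=x0.shape) + rng.normal(0, 0.1, x0.shape),
            np.asarray(lo) + 1e-12,
            np.asarray(hi),
        )
        try:
            sol = least_squares(resid, start, bounds=(lo, hi), method="trf")
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        rss = float(np.sum(sol.fun**2))
        if not math.isfinite(rss):
            continue
        if sol.status > 0 and (best is None or rss < best[0]):
            best = (rss, sol.x)
        if best is not None and attempt == 0:
            break  # first fit converged; restarts are for failures only

    names = _PARAM_NAMES[model]
    if best is None:
        return GrowthFit(
            model=model,
            params={nm: float("nan") for nm in names},
            rss=float("inf"),
            n=len(t),
            aic=float("inf"),
            converged=False,
            a_fixed=a_fixed,
        )
    rss, x = best
    return GrowthFit(
        model=model,
        params=dict(zip(names, (float(v) for v in x))),
        rss=rss,
        n=len(t),
        aic=gaussian_nls_aic(rss, len(t), k),
        converged=True,
        a_fixed=a_fixed,
    )


def select_best_model(
    series: pd.DataFrame, models: tuple[str, ...] = MODEL_ORDER
) -> tuple[GrowthFit, dict[str, float]]:
    """Fit all candidate models and return (best fit, AIC per model).

    Best = minimum AIC among converged fits; AIC ties (|delta| < 1e-9) go to
    the model with fewer parameters, then to the fixed model order. Raises if
    no model converged (caller flags the plant unusable).
    """
    t = np.asarray(series["day"], dtype=float)
    if len(t) < 4:
        raise ValueError("model selection needs at least 4 points")
    fits: dict[str, GrowthFit] = {}
    for m in models:
        try:
            fits[m] = fit_growth_model(series, m)
        except ValueError:
            continue
    aics = {m: f.aic for m, f in fits.items()}
    converged = [f for f in fits.values() if f.converged and math.isfinite(f.aic)]
    if not converged:
        raise RuntimeError("no growth model converged for this plant")

    def key(f: GrowthFit) -> tuple[float, int, int]:
        return (f.aic, _N_PARAMS[f.model], MODEL_ORDER.index(f.model))

    best = min(converged, key=key)
    # re-apply the tolerance explicitly: anything within 1e-9 of the minimum
    # AIC competes on parsimony
    near = [f for f in converged if f.aic - best.aic < 1e-9]
    best = min(near, key=lambda f: (_N_PARAMS[f.model], MODEL_ORDER.index(f.model)))
    return best, aics


def extract_growth_traits(fit: GrowthFit) -> GrowthTraits:
    """size, x_mid and growth rate from a converged three-parameter logistic.

    The slope at the inflection of ``A / (1 + exp((x_mid - t)/scal))`` is
    ``A / (4 * scal)`` analytically.
    """
    if fit.model != "logistic3":
        raise ValueError("growth traits are extracted from the logistic3 fit only")
    if not fit.converged:
        raise ValueError("cannot extract traits from a non-converged fit")
    a = fit.params["asymptote"]
    scal = fit.params["scal"]
    return GrowthTraits(
        size=a, x_mid=fit.params["x_mid"], growth_rate=a / (4.0 * scal)
    )


def support_summary(best_fits: list[GrowthFit]) -> dict[str, int]:
    """Per-model counts of best-AIC wins; counts sum to len(best_fits)."""
    c = Counter(f.model for f in best_fits)
    return {m: c.get(m, 0) for m in MODEL_ORDER}


def fit_all_plants(areas: pd.DataFrame, min_points: int = 4) -> pd.DataFrame:
    """Growth-trait table for a long-format area table.

    For each plant: select the best model by AIC, and extract the three
    growth traits from the logistic3 fit (refit as logistic3 regardless of
    the AIC winner, matching the convention of reading traits off
    the sigmoid). Plants with too few points or no converged fit are skipped.
    """
    rows = []
    for plant, grp in areas.groupby("plant"):
        grp = grp.sort_values("day")
        if len(grp) < min_points or grp["day"].nunique() < 2:
            continue
        try:
            best, aics = select_best_model(grp)
            l3 = fit_growth_model(grp, "logistic3")
        except (ValueError, RuntimeError):
            continue
        if not l3.converged:
            continue
        tr = extract_growth_traits(l3)
        row = {
            "plant": plant,
            "size": tr.size,
            "x_mid": tr.x_mid,
            "growth_rate": tr.growth_rate,
            "best_model": best.model,
        }
        row.update({f"aic_{m}": aics.get(m, float("nan")) for m in MODEL_ORDER})
        rows.append(row)
    return pd.DataFrame(rows)
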