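"""Synthetic factorial heat x drought rosette experiments with known ground truth.

Generates a complete greenhouse-style experiment: a 2x2 temperature x
watering factorial over five source populations with seed families nested in
populations, plants laid out on 54-pot trays (every second pot used), sigmoid
rosette growth observed at a fixed imaging interval, treatment-dependent
mortality that is worse than additive under combined stress, harvest weights
consistent with target functional traits (SLA, LDMC, root:shoot), and fitness
outcomes (flowering, survival, longevity) generated under known selection
coefficients on within-treatment standardized traits.

Every stochastic quantity is drawn from a per-plant substream derived from
``(seed, plant index)`` so that any subset of plants is reproducible on its
own.
"""

from __future__ import annotations


import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

TREATMENTS = ("control", "heat", "drought", "heat_drought")

#: factorial coding of each treatment cell: (temperature level, watering level)
TREATMENT_LEVELS = {
    "control": ("avg", "avg"),
    "heat": ("high", "avg"),
    "drought": ("avg", "low"),
    "heat_drought": ("high", "low"),
}

#: fitness measure analysed per treatment (flowering propensity under benign
#: temperature, survival under single stress, longevity under combined stress)
FITNESS_MEASURE = {
    "control": "flowered",
    "heat": "survived",
    "drought": "survived",
    "heat_drought": "longevity",
}

POPULATIONS = ("NE", "NW", "C", "SE", "SW")
SOUTHERN_POPULATIONS = frozenset({"SE", "SW"})

TRAITS = ("size", "x_mid", "growth_rate", "sla", "ldmc", "root_shoot")

TRAY_ROWS = 6
TRAY_COLS = 9
USABLE_POTS_PER_TRAY = (TRAY_ROWS * TRAY_COLS) // 2  # every second pot


@dataclass(frozen=True)
class GrowthParamDist:
    """Gaussian distributions of three-parameter logistic growth parameters.

    asymptote in mm^2, inflection day (x_mid) and scale (scal) in days.
    """

    asymptote_mean: float
    asymptote_sd: float
    xmid_mean: float
    xmid_sd: float
    scal_mean: float
    scal_sd: float


def _default_growth_dists() -> dict[str, GrowthParamDist]:
    # Cell means follow the emulated experiment's factorial structure:
    # asymptote 1464.85 at control with heat -209.25, drought -374.06 and a
    # -62.10 interaction; inflection day 27.12 with heat -1.48, drought
    # -1.38, interaction -2.30. The curve scale (days) is not reported and
    # is set to 4 d, a realistic steepness for rosettes of this size.
    return {
        "control": GrowthParamDist(1464.85, 150.0, 27.12, 2.0, 4.0, 0.4),
        "heat": GrowthParamDist(1255.60, 150.0, 25.64, 2.0, 4.0, 0.4),
        "drought": GrowthParamDist(1090.79, 150.0, 25.74, 2.0, 4.5, 0.4),
        "heat_drought": GrowthParamDist(819.44, 120.0, 21.96, 2.0, 4.5, 0.4),
    }


def _default_mortality() -> dict[str, float]:
    # Survival logits (intercept 3.51, heat -1.62, drought
    # -1.84, interaction -2.71): mortality is mild under single stress but
    # far worse than additive when the stresses combine.
    def _m(eta: float) -> float:
        return round(1.0 - 1.0 / (1.0 + math.exp(-eta)), 3)

    return {
        "control": _m(3.51),
        "heat": _m(3.51 - 1.62),
        "drought": _m(3.51 - 1.84),
        "heat_drought": _m(3.51 - 1.62 - 1.84 - 2.71),
    }


def _default_flowering() -> dict[str, float]:
    # Flowering essentially restricted to the benign-temperature cells.
    return {"control": 0.60, "heat": 0.0, "drought": 0.40, "heat_drought": 0.0}


def _default_betas() -> dict[str, dict[str, float]]:
    # Default selection mirrors the experiment's dominant multivariate
    # gradients: selection for thin leaves (high SLA, high LDMC, low
    # root investment) on flowering in the control, and for larger size on
    # longevity under combined stress; no direct selection elsewhere.
    beta = {t: {trait: 0.0 for trait in TRAITS} for t in TREATMENTS}
    beta["control"].update({"sla": 0.29, "ldmc": 0.10, "root_shoot": -0.04})
    beta["heat_drought"].update({"size": 0.14})
    return beta


@dataclass
class SimConfig:
    """Full parameterization of a synthetic experiment.

    Defaults emulate a realistic greenhouse design: 5 populations, families
    nested within populations, 5 blocks per treatment, a 2x2 factorial of
    temperature (avg 20.6 C vs high 25.2 C) and watering (avg vs low; labels
    only), 54-pot trays with every second pot used, and twice-weekly imaging.
    """

    n_populations: int = 5
    families_per_population: int = 10
    blocks_per_treatment: int = 5
    treatments: tuple[str, ...] = TREATMENTS

    growth: dict[str, GrowthParamDist] = field(default_factory=_default_growth_dists)
    growth_model: str = "logistic3"  # any model name from rosette.growth
    noise_sd: float = 25.0  # observation noise on area, mm^2
    imaging_interval: float = 3.5  # days between tray images
    duration: int = 70  # days from germination to harvest

    mortality: dict[str, float] = field(default_factory=_default_mortality)
    flowering_base: dict[str, float] = field(default_factory=_default_flowering)
    #: survival-logit bonus for southern (SE, SW) plants under combined stress
    south_combined_survival_logit: float = 1.5

    # harvest trait targets (population means) and variability
    sla_target: float = 20.0  # mm^2 / mg
    ldmc_target: float = 250.0  # mg / g
    root_shoot_target: float = 0.5
    family_sd_frac: float = 0.10  # family effect, fraction of target mean
    plant_sd_frac: float = 0.05  # residual plant noise, fraction of target
    weight_floor_mg: float = 0.1  # keeps ratios positive for log transforms
    inflorescence_mean_mg: float = 30.0
    inflorescence_sd_mg: float = 8.0

    #: selection coefficients on within-treatment standardized traits.
    #: Binary fitness (flowered / survived) uses a logit link; longevity is
    #: Gaussian around a linear predictor.
    beta: dict[str, dict[str, float]] = field(default_factory=_default_betas)
    longevity_base: dict[str, float] = field(
        default_factory=lambda: {t: 30.0 for t in TREATMENTS}
    )
    longevity_sd: float = 8.0

    max_germination_day: int = 10

    seed: int = 0

    def validate(self) -> None:
        if self.n_populations < 1 or self.n_populations > len(POPULATIONS):
            raise ValueError(f"n_populations must be in 1..{len(POPULATIONS)}")
        if self.families_per_population < 1:
            raise ValueError("at least one family per population is required")
        if self.blocks_per_treatment < 1:
            raise ValueError("at least one block per treatment is required")
        if set(self.treatments) - set(TREATMENTS):
            raise ValueError(f"treatments must be among {TREATMENTS}")
        if self.noise_sd < 0 or self.family_sd_frac < 0 or self.plant_sd_frac < 0:
            raise ValueError("standard deviations must be >= 0")
        if self.imaging_interval <= 0:
            raise ValueError("imaging interval must be positive")
        for t in self.treatments:
            m = self.mortality[t]
            if not 0.0 <= m <= 1.0:
                raise ValueError(f"mortality[{t}]={m} outside [0, 1]")
            g = self.growth[t]
            if g.asymptote_sd < 0 or g.xmid_sd < 0 or g.scal_sd < 0:
                raise ValueError("growth parameter sds must be >= 0")


@dataclass
class TruePlantState:
    """Ground truth for one plant, used by recovery tests downstream."""

    plant: int
    population: str
    family: str
    treatment: str
    block: int
    tray: str
    pot_row: int
    pot_col: int
    germination_day: int
    model: str
    asymptote: float  # mm^2
    x_mid: float  # days since germination
    scal: float  # days
    death_day: float | None  # days since germination; None = survived
    true_traits: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.asymptote <= 0 or self.scal <= 0:
            raise ValueError("asymptote and scal must be positive")
        if self.death_day is not None and self.death_day < 0:
            raise ValueError("death day must be >= 0")


def _plant_rng(seed: int, plant: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((seed, plant)))


def _logistic3(t: np.ndarray, a: float, x_mid: float, scal: float) -> np.ndarray:
    return a / (1.0 + np.exp((x_mid - t) / scal))


def _growth_curve(model: str, t: np.ndarray, a: float, x_mid: float, scal: float) -> np.ndarray:
    """True mean curve; non-logistic choices reuse (a, x_mid, scal) sensibly."""
    t = np.asarray(t, dtype=float)
    if model in ("logistic3", "logistic2"):
        return _logistic3(t, a, x_mid, scal)
    if model == "gompertz":
        k = 1.0 / scal
        return a * np.exp(-np.exp(-k * (t - x_mid)))
    if model == "von_bertalanffy":
        k = 1.0 / (2.0 * scal)
        t0 = x_mid - 2.0 * scal
        return a * (1.0 - np.exp(-k * (t - t0)))
    if model == "linear":
        slope = a / (4.0 * scal)
        return np.clip(slope * t, 0.0, None)
    if model == "exponential":
        b = math.log(a) / max(2.0 * x_mid, 1e-9)
        return np.exp(b * t)
    if model == "power":
        b = 1.5
        scale = a / max(2.0 * x_mid, 1e-9) ** b
        return scale * np.where(t > 0, t, 0.0) ** b
    raise ValueError(f"unknown growth model {model!r}")


def simulate_experiment(config: SimConfig) -> tuple[pd.DataFrame, list[TruePlantState]]:
    """Lay out the full design and draw per-plant ground truth.

    Returns a plant table (one row per plant: design metadata, fate, harvest
    weights, fitness) and the list of :class:`TruePlantState`. Identical
    configs (including seed) give identical outputs.
    """
    config.validate()
    pops = POPULATIONS[: config.n_populations]

    states: list[TruePlantState] = []
    plant = 0
    for treatment in config.treatments:
        for block in range(1, config.blocks_per_treatment + 1):
            pot_slot = 0
            for pop in pops:
                for fam_i in range(1, config.families_per_population + 1):
                    tray_idx = pot_slot // USABLE_POTS_PER_TRAY
                    used_idx = pot_slot % USABLE_POTS_PER_TRAY
                    # every-second-pot checkerboard, row-major over 6x9
                    flat = 2 * used_idx
                    row, col = divmod(flat, TRAY_COLS)
                    rng = _plant_rng(config.seed, plant)
                    g = config.growth[treatment]
                    a = max(rng.normal(g.asymptote_mean, g.asymptote_sd), 50.0)
                    xm = max(rng.normal(g.xmid_mean, g.xmid_sd), 1.0)
                    sc = max(rng.normal(g.scal_mean, g.scal_sd), 0.5)
                    germ = int(rng.integers(0, config.max_germination_day + 1))
                    states.append(
                        TruePlantState(
                            plant=plant,
                            population=pop,
                            family=f"{pop}-F{fam_i:02d}",
                            treatment=treatment,
                            block=block,
                            tray=f"{treatment}-B{block}-T{tray_idx + 1}",
                            pot_row=row,
                            pot_col=col,
                            germination_day=germ,
                            model=config.growth_model,
                            asymptote=a,
                            x_mid=xm,
                            scal=sc,
                            death_day=None,
                        )
                    )
                    plant += 1
                    pot_slot += 1

    simulate_harvest_and_fitness(states, config)

    rows = []
    for s in states:
        rows.append(
            {
                "plant": s.plant,
                "population": s.population,
                "family": s.family,
                "treatment": s.treatment,
                "temperature": TREATMENT_LEVELS[s.treatment][0],
                "watering": TREATMENT_LEVELS[s.treatment][1],
                "block": s.block,
                "tray": s.tray,
                "pot_row": s.pot_row,
                "pot_col": s.pot_col,
                "germination_day": s.germination_day,
                **{k: s.true_traits.get(k, np.nan) for k in (
                    "survived", "flowered", "longevity",
                    "leaf_fresh_g", "leaf_dry_mg", "dead_leaf_dry_mg",
                    "root_dry_mg", "inflorescence_dry_mg", "harvest_area_mm2",
                )},
            }
        )
    plants = pd.DataFrame(rows)
    plants["death_day"] = [s.death_day for s in states]
    return plants, states


def simulate_growth_series(state: TruePlantState, config: SimConfig) -> pd.DataFrame:
    """Observed rosette-area series for one plant.

    Areas are the true growth curve sampled every ``imaging_interval`` days
    since germination plus Gaussian noise, clipped at zero, and truncated at
    the plant's death day.
    """
    if config.imaging_interval <= 0:
        raise ValueError("imaging interval must be positive")
    horizon = config.duration - state.germination_day
    if state.death_day is not None:
        horizon = min(horizon, state.death_day)
    days = np.arange(0.0, horizon + 1e-9, config.imaging_interval)
    mean = _growth_curve(state.model, days, state.asymptote, state.x_mid, state.scal)
    rng = _plant_rng(config.seed, state.plant)
    rng = np.random.default_rng(rng.integers(0, 2**31))  # growth-noise substream
    areas = mean + rng.normal(0.0, config.noise_sd, size=days.shape) if config.noise_sd > 0 else mean.copy()
    areas = np.clip(areas, 0.0, None)
    return pd.DataFrame({"plant": state.plant, "day": days, "area_mm2": areas})


def simulate_all_series(states: list[TruePlantState], config: SimConfig) -> pd.DataFrame:
    """Long-format area table (plant, day, area_mm2) for all plants."""
    return pd.concat(
        [simulate_growth_series(s, config) for s in states], ignore_index=True
    )


def _inv_logit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_harvest_and_fitness(
    states: list[TruePlantState], config: SimConfig
) -> None:
    """Draw harvest weights and fitness outcomes, writing into each state.

    True functional traits get a family-level Gaussian effect plus plant
    noise. Binary fitness (flowered, survived) is Bernoulli with success
    probability ``inv_logit(base + beta . z)`` on within-treatment
    standardized true traits; longevity of non-survivors is Gaussian around a
    linear predictor. Weights are floored at ``weight_floor_mg`` so every
    ratio stays positive.
    """
    master = np.random.default_rng(np.random.SeedSequence((config.seed, 10**9)))
    families = sorted({s.family for s in states})
    fam_eff = {
        f: {
            "sla": master.normal(0.0, config.family_sd_frac * config.sla_target),
            "ldmc": master.normal(0.0, config.family_sd_frac * config.ldmc_target),
            "root_shoot": master.normal(
                0.0, config.family_sd_frac * config.root_shoot_target
            ),
        }
        for f in families
    }

    # true trait values per plant
    for s in states:
        rng = _plant_rng(config.seed, s.plant)
        rng = np.random.default_rng(rng.integers(0, 2**31, size=3)[2])
        tt = s.true_traits
        tt["size"] = s.asymptote
        tt["x_mid"] = s.x_mid
        tt["growth_rate"] = s.asymptote / (4.0 * s.scal)
        fe = fam_eff[s.family]
        tt["sla"] = max(
            config.sla_target + fe["sla"]
            + rng.normal(0.0, config.plant_sd_frac * config.sla_target),
            1.0,
        )
        tt["ldmc"] = max(
            config.ldmc_target + fe["ldmc"]
            + rng.normal(0.0, config.plant_sd_frac * config.ldmc_target),
            10.0,
        )
        tt["root_shoot"] = max(
            config.root_shoot_target + fe["root_shoot"]
            + rng.normal(0.0, config.plant_sd_frac * config.root_shoot_target),
            0.01,
        )

    # within-treatment standardization of true traits (selection acts on z)
    by_treatment: dict[str, list[TruePlantState]] = {}
    for s in states:
        by_treatment.setdefault(s.treatment, []).append(s)

    for treatment, group in by_treatment.items():
        z = {}
        for trait in TRAITS:
            vals = np.array([s.true_traits[trait] for s in group])
            sd = vals.std(ddof=1) if len(vals) > 1 else 0.0
            z[trait] = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)
        betas = config.beta[treatment]
        lin = sum(betas[trait] * z[trait] for trait in TRAITS)

        surv_base = _logit(1.0 - config.mortality[treatment])
        flow_base = config.flowering_base[treatment]
        for i, s in enumerate(group):
            rng = _plant_rng(config.seed, s.plant)
            sub = np.random.default_rng(rng.integers(0, 2**31, size=4)[3])
            eta = surv_base + lin[i]
            if (
                treatment == "heat_drought"
                and s.population in SOUTHERN_POPULATIONS
            ):
                eta += config.south_combined_survival_logit
            survived = int(sub.random() < _inv_logit(eta))
            if survived:
                death_day = None
                longevity = float(config.duration - s.germination_day)
            else:
                mu = config.longevity_base[treatment] + (
                    config.longevity_sd * lin[i]
                    if FITNESS_MEASURE[treatment] == "longevity"
                    else 0.0
                )
                longevity = float(
                    np.clip(
                        sub.normal(mu, config.longevity_sd),
                        1.0,
                        config.duration - s.germination_day - 1,
                    )
                )
                death_day = longevity
            if survived and flow_base > 0:
                p = _inv_logit(_logit(flow_base) + lin[i])
                flowered = int(sub.random() < p)
            else:
                flowered = 0
            s.death_day = death_day
            tt = s.true_traits
            tt["survived"] = survived
            tt["flowered"] = flowered
            tt["longevity"] = longevity

            # harvest weights consistent with the target traits
            t_end = longevity if death_day is not None else config.duration - s.germination_day
            area = float(
                _growth_curve(s.model, np.array([t_end]), s.asymptote, s.x_mid, s.scal)[0]
            )
            leaf_dry = max(area / tt["sla"], config.weight_floor_mg)
            leaf_fresh = max(leaf_dry / tt["ldmc"], config.weight_floor_mg / 1000.0)
            infl = (
                max(sub.normal(config.inflorescence_mean_mg, config.inflorescence_sd_mg),
                    config.weight_floor_mg)
                if flowered
                else 0.0
            )
            root = max(tt["root_shoot"] * (leaf_dry + infl), config.weight_floor_mg)
            tt["harvest_area_mm2"] = area
            tt["leaf_dry_mg"] = leaf_dry
            tt["leaf_fresh_g"] = leaf_fresh
            tt["dead_leaf_dry_mg"] = 0.0
            tt["inflorescence_dry_mg"] = infl
            tt["root_dry_mg"] = root
            # functional traits unobservable for plants that died under
            # combined stress (drives the family-mean imputation downstream)
            if treatment == "heat_drought" and not survived:
                tt["leaf_dry_mg"] = np.nan
                tt["leaf_fresh_g"] = np.nan
                tt["root_dry_mg"] = np.nan
                tt["harvest_area_mm2"] = np.nan


def _logit(p: float) -> float:
    p = min(max(p, 1e-9), 1 - 1e-9)
    return math.log(p / (1.0 - p))


def truth_table(states: list[TruePlantState]) -> pd.DataFrame:
    """Ground-truth table (one row per plant) for recovery tests."""
    rows = []
    for s in states:
        row = {
            "plant": s.plant,
            "model": s.model,
            "asymptote": s.asymptote,
            "x_mid": s.x_mid,
            "scal": s.scal,
            "death_day": np.nan if s.death_day is None else s.death_day,
        }
        row.update({f"true_{k}": v for k, v in s.true_traits.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def write_experiment(outdir, config: SimConfig) -> dict[str, pd.DataFrame]:
    """Simulate and write plants.csv, areas.csv, truth.csv under ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    plants, states = simulate_experiment(config)
    areas = simulate_all_series(states, config)
    truth = truth_table(states)
    plants.to_csv(out / "plants.csv", index=False)
    areas.to_csv(out / "areas.csv", index=False)
    truth.to_csv(out / "truth.csv", index=False)
    return {"plants": plants, "areas": areas, "truth": truth}
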