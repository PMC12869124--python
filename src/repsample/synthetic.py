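"""Synthetic cancer-registry populations.

The real registry-linked data behind the Korean cancer sample cohorts are
access-restricted, so this module generates seeded stand-in populations with
the joint structure the downstream sampler and validators assume: per-cancer
categorical marginals (diagnosis year, sex, six age groups, 17 regions, SEER
summary stage), a right-skewed annual medical cost per cancer x age cell,
and survival with administrative censoring at a fixed calendar cutoff.

Default study conditions are calibrated from the published cohort release:
categorical weights are the published population marginals, and costs are
lognormal with per-cell location/scale matched to the published mean +/- SD
(roughly 7,900-14,000 USD means, SDs of the same order).  Survival is
piecewise-exponential in stage and age-group multipliers; the release
publishes only curve shapes and follow-up summaries, so the baseline rates
are set once to plausible five-year survival by cancer type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import published
from .exceptions import ConfigurationError

__all__ = [
    "HazardModel",
    "PopulationConfig",
    "generate_population",
    "draw_survival_time",
    "REGISTRY_COLUMNS",
]

REGISTRY_COLUMNS = [
    "patient_id",
    "cancer_type",
    "diagnosis_year",
    "sex",
    "age_at_diagnosis",
    "region17",
    "seer_stage",
    "secondary_cancer",
    "annual_cost_usd",
    "time_years",
    "event",
]

# Integer ages drawn uniformly within the stratification age group.
_AGE_RANGES = {
    "0-39": (15, 39),
    "40-49": (40, 49),
    "50-59": (50, 59),
    "60-69": (60, 69),
    "70-79": (70, 79),
    "80+": (80, 94),
}

# Approximate Korean provincial population shares; the release prints only a
# 3-group recode, so the 17-level weights are a one-time modelling choice.
_REGION_SHARES = {
    "Seoul": 0.183, "Busan": 0.065, "Daegu": 0.046, "Incheon": 0.057,
    "Gwangju": 0.028, "Daejeon": 0.028, "Ulsan": 0.022, "Sejong": 0.007,
    "Gyeonggi": 0.263, "Gangwon": 0.030, "Chungbuk": 0.031, "Chungnam": 0.041,
    "Jeonbuk": 0.035, "Jeonnam": 0.036, "Gyeongbuk": 0.051,
    "Gyeongnam": 0.064, "Jeju": 0.013,
}

_STAGE_MULTIPLIERS = {
    "in situ": 0.15,
    "localized": 0.5,
    "regional": 2.0,
    "distant": 8.0,
    "unknown": 1.5,
}
_AGE_MULTIPLIERS = {
    "0-39": 0.6, "40-49": 0.7, "50-59": 0.85,
    "60-69": 1.0, "70-79": 1.4, "80+": 2.2,
}
# Baseline death rates (per person-year at the reference stage/age cell),
# ordered to give breast the best and liver the worst prognosis.
_BASE_RATES = {"stomach": 0.05, "breast": 0.02, "colorectal": 0.06, "liver": 0.18}


@dataclass(frozen=True)
class HazardModel:
    """Piecewise-exponential survival: rate = base_rate x stage x age multiplier."""

    base_rate: float
    stage_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(_STAGE_MULTIPLIERS))
    age_multipliers: Mapping[str, float] = field(
        default_factory=lambda: dict(_AGE_MULTIPLIERS))

    def rate(self, stage: str, age_group: str) -> float:
        return (self.base_rate * self.stage_multipliers[stage]
                * self.age_multipliers[age_group])

    def validate(self) -> None:
        mults = [self.base_rate, *self.stage_multipliers.values(),
                 *self.age_multipliers.values()]
        if any(not m > 0 for m in mults):
            raise ConfigurationError("hazard multipliers must be > 0")


def _normalized(weights: Mapping, what: str, tol: float = 1e-6) -> dict:
    w = {k: float(v) for k, v in weights.items()}
    total = sum(w.values())
    if any(v < 0 for v in w.values()) or not np.isclose(total, 1.0, atol=tol):
        raise ConfigurationError(
            f"{what}: weights must be nonnegative and sum to 1 (got {total:.6g})")
    return w


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Location/scale of a lognormal with the given arithmetic mean and SD."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


@dataclass
class PopulationConfig:
    """Study conditions for one synthetic registry draw.

    Per-cancer categoricals are mappings ``cancer -> {level: weight}``;
    ``cost_model`` maps ``cancer -> {age_group: (lognormal mu, sigma)}`` in
    log-USD; ``hazard_model`` maps ``cancer -> HazardModel``.  The eligibility
    filter needs work to do, so a small fraction of rows carry a
    secondary-cancer flag or a missing stratification field.
    """

    cancer_types: list[str]
    n_per_cancer: int
    year_range: tuple[int, int]
    year_weights: dict[str, dict[int, float]]
    age_distribution: dict[str, dict[str, float]]
    sex_ratio: dict[str, float]
    region_weights: dict[str, float]
    stage_weights: dict[str, dict[str, float]]
    cost_model: dict[str, dict[str, tuple[float, float]]]
    hazard_model: dict[str, HazardModel]
    censor_cutoff_year: int = 2021
    secondary_rate: float = 0.02
    missing_rate: float = 0.02
    seed: int = 0

    @classmethod
    def default(cls, n_per_cancer: int = 10_000, seed: int = 0,
                **overrides) -> "PopulationConfig":
        """Defaults calibrated from the published cohort marginals."""
        counts = published.cohort_counts()
        costs = published.cost_summaries()
        cancers = list(published.CANCER_TYPES)

        def marg(cancer: str, variable: str) -> dict:
            sub = counts[(counts.cancer == cancer) & (counts.variable == variable)]
            w = sub.set_index("level")["population"].astype(float)
            return (w / w.sum()).to_dict()

        year_weights = {c: {int(y): w for y, w in marg(c, "year").items()}
                        for c in cancers}
        age_distribution = {c: marg(c, "age") for c in cancers}
        sex_counts = counts[counts.variable == "sex"]
        sex_ratio = {}
        for c in cancers:
            sub = sex_counts[sex_counts.cancer == c].set_index("level")["population"]
            male = float(sub.get("male", 0.0))
            sex_ratio[c] = male / float(sub.sum())
        stage_weights = {c: marg(c, "stage") for c in cancers}
        cost_model: dict[str, dict[str, tuple[float, float]]] = {}
        for c in cancers:
            sub = costs[costs.cancer == c]
            cost_model[c] = {
                row.age_group: _lognormal_params(row.pop_mean, row.pop_sd)
                for row in sub.itertuples()
            }
        hazard = {c: HazardModel(base_rate=_BASE_RATES[c]) for c in cancers}
        cfg = cls(
            cancer_types=cancers,
            n_per_cancer=n_per_cancer,
            year_range=(2012, 2019),
            year_weights=year_weights,
            age_distribution=age_distribution,
            sex_ratio=sex_ratio,
            region_weights=dict(_REGION_SHARES),
            stage_weights=stage_weights,
            cost_model=cost_model,
            hazard_model=hazard,
            seed=seed,
        )
        if overrides:
            cfg = replace(cfg, **overrides)
        return cfg

    def validate(self) -> None:
        if self.n_per_cancer < 0:
            raise ConfigurationError("n_per_cancer must be >= 0")
        lo, hi = self.year_range
        if lo > hi:
            raise ConfigurationError("year_range must be (low, high) with low <= high")
        self.region_weights = _normalized(self.region_weights, "region_weights")
        unknown = set(self.region_weights) - set(published.REGIONS_17)
        if unknown:
            raise ConfigurationError(f"unknown region labels: {sorted(unknown)}")
        for c in self.cancer_types:
            self.year_weights[c] = _normalized(self.year_weights[c], f"{c} year_weights")
            if any(not lo <= y <= hi for y in self.year_weights[c]):
                raise ConfigurationError(f"{c}: year weight outside year_range")
            self.age_distribution[c] = _normalized(
                self.age_distribution[c], f"{c} age_distribution")
            self.stage_weights[c] = _normalized(
                self.stage_weights[c], f"{c} stage_weights")
            if not 0.0 <= self.sex_ratio[c] <= 1.0:
                raise ConfigurationError(f"{c}: male fraction must be in [0, 1]")
            self.hazard_model[c].validate()
        for rate, name in [(self.secondary_rate, "secondary_rate"),
                           (self.missing_rate, "missing_rate")]:
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")


def draw_survival_time(stage: str, age_group: str, diagnosis_year: int,
                       hazard_model: HazardModel, censor_cutoff_year: int,
                       rng: np.random.Generator,
                       diagnosis_fraction: float | None = None,
                       ) -> tuple[float, str]:
    """Draw one follow-up time and outcome under administrative censoring.

    The latent death time is exponential at the stage/age-specific rate; the
    record is censored exactly when that time exceeds the administrative
    window from the (within-year uniform, unless ``diagnosis_fraction`` is
    given) diagnosis date to December 31 of ``censor_cutoff_year``.
    """
    hazard_model.validate()
    if diagnosis_fraction is None:
        diagnosis_fraction = float(rng.uniform())
    rate = hazard_model.rate(stage, age_group)
    latent = float(rng.exponential(1.0 / rate))
    window = (censor_cutoff_year + 1) - (diagnosis_year + diagnosis_fraction)
    window = max(window, 0.0)
    if latent <= window:
        return latent, "death"
    return window, "censored"


def _draw_survival_block(rates: np.ndarray, windows: np.ndarray,
                         rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    latent = rng.exponential(1.0 / rates)
    dead = latent <= windows
    times = np.where(dead, latent, windows)
    return times, dead


def _choice(rng: np.random.Generator, weights: Mapping, n: int) -> np.ndarray:
    levels = np.asarray(list(weights.keys()), dtype=object)
    p = np.asarray(list(weights.values()), dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


def generate_population(config: PopulationConfig) -> pd.DataFrame:
    """Generate a seeded registry table, one row per patient.

    Exactly ``n_per_cancer`` rows per cancer type; a pure function of the
    config including its seed.
    """
    config.validate()
    frames = []
    from .prep import AGE_GROUP_LABELS  # canonical group order

    for k, cancer in enumerate(config.cancer_types):
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, k]))
        n = config.n_per_cancer
        year = _choice(rng, config.year_weights[cancer], n).astype(int)
        male_frac = config.sex_ratio[cancer]
        sex = np.where(rng.uniform(size=n) < male_frac, "male", "female")
        age_group = _choice(rng, config.age_distribution[cancer], n)
        age = np.empty(n, dtype=int)
        for g, (lo, hi) in _AGE_RANGES.items():
            mask = age_group == g
            age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
        region = _choice(rng, config.region_weights, n)
        stage = _choice(rng, config.stage_weights[cancer], n)

        mu = np.empty(n)
        sg = np.empty(n)
        for g in AGE_GROUP_LABELS:
            mask = age_group == g
            if mask.any():
                m, s = config.cost_model[cancer][g]
                mu[mask], sg[mask] = m, s
        cost = rng.lognormal(mean=mu, sigma=sg)

        hz = config.hazard_model[cancer]
        rates = np.array([hz.rate(s, g) for s, g in zip(stage, age_group)])
        diag_frac = rng.uniform(size=n)
        windows = np.maximum(
            (config.censor_cutoff_year + 1) - (year + diag_frac), 0.0)
        times, dead = _draw_survival_block(rates, windows, rng)

        secondary = rng.uniform(size=n) < config.secondary_rate

        df = pd.DataFrame({
            "cancer_type": cancer,
            "diagnosis_year": year,
            "sex": sex,
            "age_at_diagnosis": age.astype(float),
            "region17": region,
            "seer_stage": stage,
            "secondary_cancer": secondary,
            "annual_cost_usd": cost,
            "time_years": times,
            "event": np.where(dead, "death", "censored"),
        })

        # Missingness injected into one stratification field per hit row so
        # the eligibility filter has work to do.
        miss = rng.uniform(size=n) < config.missing_rate
        if miss.any():
            which = rng.integers(0, 4, size=int(miss.sum()))
            idx = np.flatnonzero(miss)
            for j, col in enumerate(["sex", "region17", "seer_stage",
                                     "age_at_diagnosis"]):
                df.loc[idx[which == j], col] = np.nan
        frames.append(df)

    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=REGISTRY_COLUMNS[1:])
    out.insert(0, "patient_id", np.arange(len(out), dtype=int))
    return out[REGISTRY_COLUMNS]
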