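"""Descriptive cohort reports and the end-to-end pipeline driver.

Reproduces the release-style summaries: per-cancer counts and sampling
percentages by age group, sex, 3-group region, SEER stage and incidence
year; cost mean +/- SD per cancer x age cell; in-text statistics (>=60
proportions, male-to-female rate ratios).  All printed percentages use
round-half-up at one decimal, matching the published style.  The published
"rate ratio" is computed as a count ratio — person-time denominators are
not published, and the printed values match count ratios at one decimal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import published
from .prep import (EligibilityRules, apply_exclusions, build_strata,
                   example_region3_mapping, recode_age_groups, recode_regions,
                   suppress_small_strata)
from .sampler import SamplerConfig, margin_of_error_report, sample_cohort
from .survival import (follow_up_summary, pass_proportion_by_cancer,
                       validate_cohort)
from .synthetic import PopulationConfig, generate_population

logger = logging.getLogger("repsample")

__all__ = [
    "round_half_up",
    "sampling_fraction",
    "age_group_proportion",
    "sex_rate_ratio",
    "cost_summary_table",
    "count_summary_table",
    "PipelineArtifacts",
    "run_pipeline",
]

KRW_PER_USD = 1300  # published conversion, display only


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (the published tables' convention, not banker's)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def sampling_fraction(sample_n: int, population_n: int) -> float:
    """Sample share of the population as a one-decimal percentage."""
    if population_n <= 0:
        raise ValueError("population_n must be > 0")
    if not 0 <= sample_n <= population_n:
        raise ValueError("need 0 <= sample_n <= population_n")
    return round_half_up(100.0 * sample_n / population_n, 1)


def age_group_proportion(counts: Mapping[str, int] | pd.Series,
                         groups: Sequence[str]) -> float:
    """Percentage of patients in a subset of age groups, one decimal."""
    counts = pd.Series(counts)
    unknown = set(groups) - set(counts.index)
    if unknown:
        raise ValueError(f"unknown age groups: {sorted(unknown)}")
    total = counts.sum()
    if total <= 0:
        raise ValueError("zero total count")
    return round_half_up(100.0 * counts.loc[list(groups)].sum() / total, 1)


def sex_rate_ratio(male_n: int, female_n: int) -> float:
    """Male-to-female ratio of case counts, one decimal."""
    if female_n <= 0:
        raise ValueError("female_n must be > 0")
    return round_half_up(male_n / female_n, 1)


def cost_summary_table(records: pd.DataFrame,
                       by: Sequence[str] = ("cancer_type", "age_group6"),
                       in_krw: bool = False) -> pd.DataFrame:
    """n / mean / SD of annual cost per group.

    SD uses the sample (n-1) convention for display; the sampler's sigma_h
    keeps the population convention.
    """
    df = records
    if "age_group6" in by and "age_group6" not in df.columns:
        df = df.assign(age_group6=recode_age_groups(df["age_at_diagnosis"]))
    cost = df["annual_cost_usd"] * (KRW_PER_USD if in_krw else 1)
    df = df.assign(_cost=cost)
    out = (df.groupby(list(by), sort=True)["_cost"]
             .agg(n="count", mean="mean", sd=lambda s: s.std(ddof=1))
             .reset_index())
    return out


def count_summary_table(population: pd.DataFrame, sample: pd.DataFrame,
                        region3_mapping: Mapping[str, str]) -> pd.DataFrame:
    """Release-style counts: long format (cancer, variable, level,
    population_n, sample_n, pct), with pct = 100 * sample / population at one
    decimal.  Region is reported on the 3-group recode only."""
    def prepare(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        if "age_group6" not in out.columns:
            out["age_group6"] = recode_age_groups(out["age_at_diagnosis"])
        out["region3"] = recode_regions(out["region17"], region3_mapping)
        return out

    pop = prepare(population)
    samp = prepare(sample)
    variables = {
        "age": "age_group6", "sex": "sex", "region3": "region3",
        "stage": "seer_stage", "year": "diagnosis_year",
    }
    rows = []
    for cancer in sorted(pop["cancer_type"].unique()):
        p_c = pop[pop.cancer_type == cancer]
        s_c = samp[samp.cancer_type == cancer]
        for var, col in variables.items():
            p_counts = p_c[col].value_counts()
            s_counts = s_c[col].value_counts()
            for level in sorted(p_counts.index, key=str):
                pn = int(p_counts.get(level, 0))
                sn = int(s_counts.get(level, 0))
                rows.append({
                    "cancer_type": cancer, "variable": var,
                    "level": str(level), "population_n": pn, "sample_n": sn,
                    "pct": sampling_fraction(sn, pn) if pn else np.nan,
                })
    return pd.DataFrame(rows)


@dataclass
class PipelineArtifacts:
    population: pd.DataFrame
    eligible: pd.DataFrame
    exclusion_tally: dict
    suppression_tally: dict
    strata: list
    sampling_result: object
    cohort: pd.DataFrame
    validation: pd.DataFrame
    counts: pd.DataFrame
    costs_population: pd.DataFrame
    costs_sample: pd.DataFrame
    fractions: pd.DataFrame
    pass_proportions: pd.DataFrame
    follow_up: pd.DataFrame
    margin_report: pd.DataFrame


def _cohort_frame(eligible: pd.DataFrame, result) -> pd.DataFrame:
    by_id = {}
    for key, rec in result.per_stratum.items():
        for pid in rec.chosen.member_ids:
            by_id[int(pid)] = rec.chosen.candidate_index
    cohort = eligible[eligible["patient_id"].isin(by_id)].copy()
    cohort["candidate_index"] = cohort["patient_id"].map(by_id)
    return cohort


def run_pipeline(pop_config: PopulationConfig,
                 sampler_config: SamplerConfig,
                 rules: EligibilityRules | None = None,
                 region3_mapping: Mapping[str, str] | None = None,
                 outdir: str | Path | None = None,
                 min_events_floor: int = 5) -> PipelineArtifacts:
    """generate -> prep -> sample -> validate -> report.

    Each stage logs its seed and sizes; with ``outdir`` set, the artifacts
    are written as CSV (cohort, attempts log, validation report, summary
    tables, exclusion audit).
    """
    rules = rules or EligibilityRules()
    region3_mapping = region3_mapping or example_region3_mapping()

    logger.info("generate: n_per_cancer=%d seed=%d",
                pop_config.n_per_cancer, pop_config.seed)
    population = generate_population(pop_config)

    logger.info("prep: applying eligibility rules")
    eligible, tally = apply_exclusions(population, rules,
                                       cancer_types=pop_config.cancer_types)
    eligible = eligible.assign(
        age_group6=recode_age_groups(eligible["age_at_diagnosis"]))
    strata_all = build_strata(eligible)
    strata, suppression = suppress_small_strata(strata_all,
                                                rules.min_stratum_size)
    kept_ids = np.concatenate([s.member_ids for s in strata]) if strata \
        else np.array([], dtype=int)
    eligible = eligible[eligible["patient_id"].isin(kept_ids)]
    logger.info("prep: %d eligible, %d strata kept, %d suppressed",
                len(eligible), len(strata), suppression["strata_suppressed"])

    logger.info("sample: rate=%.2f seed=%d", sampler_config.sampling_rate,
                sampler_config.seed)
    result = sample_cohort(strata, sampler_config)
    cohort = _cohort_frame(eligible, result)

    logger.info("validate: one-sample log-rank per stratum")
    validation = validate_cohort(eligible, result.cohort_ids)

    counts = count_summary_table(eligible, cohort, region3_mapping)
    costs_pop = cost_summary_table(eligible)
    costs_samp = cost_summary_table(cohort)
    fractions = result.sampling_fractions(strata)
    passes = pass_proportion_by_cancer(validation, min_events=min_events_floor)
    fu_rows = []
    for cancer in sorted(eligible["cancer_type"].unique()):
        for name, df in [("population", eligible), ("sample", cohort)]:
            med, lo, hi = follow_up_summary(
                df.loc[df.cancer_type == cancer, "time_years"])
            fu_rows.append({"cancer_type": cancer, "cohort": name,
                            "median": med, "min": lo, "max": hi})
    follow_up = pd.DataFrame(fu_rows)
    margin = margin_of_error_report(strata, sampler_config)

    artifacts = PipelineArtifacts(
        population=population, eligible=eligible, exclusion_tally=tally,
        suppression_tally=suppression, strata=strata,
        sampling_result=result, cohort=cohort, validation=validation,
        counts=counts, costs_population=costs_pop, costs_sample=costs_samp,
        fractions=fractions, pass_proportions=passes, follow_up=follow_up,
        margin_report=margin)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cohort.to_csv(outdir / "cohort.csv", index=False)
        result.attempts_table().to_csv(outdir / "attempts.csv", index=False)
        validation.to_csv(outdir / "validation.csv", index=False)
        counts.to_csv(outdir / "summary_counts.csv", index=False)
        costs_pop.to_csv(outdir / "summary_costs_population.csv", index=False)
        costs_samp.to_csv(outdir / "summary_costs_sample.csv", index=False)
        fractions.to_csv(outdir / "sampling_fractions.csv", index=False)
        passes.to_csv(outdir / "pass_proportions.csv", index=False)
        follow_up.to_csv(outdir / "follow_up.csv", index=False)
        margin.to_csv(outdir / "margin_of_error.csv", index=False)
        pd.DataFrame([{**tally, **suppression}]).to_csv(
            outdir / "exclusions.csv", index=False)
        logger.info("artifacts written to %s", outdir)
    return artifacts
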