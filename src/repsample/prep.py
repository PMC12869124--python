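"""Eligibility filtering, recoding and stratification of a registry table.

The target population drops secondary cancers and rows missing any
stratification field, restricts breast cancer to females, partitions the
remainder into strata (cancer type x diagnosis year x sex x six age groups x
17 regions x SEER summary stage) and, for disclosure control, removes every
stratum smaller than five patients from the population outright.

The six age groups are 0-39, four ten-year bands, and 80+.  The 17 regions
are used for stratification; the released tables recode them to
metropolitan/city/rural through a mapping that is deliberately a required
configuration input (the authoritative recode is not public), with a sample
mapping shipped for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import published
from .exceptions import ConfigurationError, InputDataError

__all__ = [
    "AGE_GROUP_LABELS",
    "REQUIRED_FIELDS",
    "EligibilityRules",
    "StratumKey",
    "StratumSummary",
    "apply_exclusions",
    "recode_age_group",
    "recode_age_groups",
    "recode_region",
    "recode_regions",
    "example_region3_mapping",
    "build_strata",
    "suppress_small_strata",
]

AGE_GROUP_LABELS = ["0-39", "40-49", "50-59", "60-69", "70-79", "80+"]

_AGE_EDGES = [40, 50, 60, 70, 80]

REQUIRED_FIELDS = [
    "age_at_diagnosis", "sex", "region17", "diagnosis_year",
    "cancer_type", "seer_stage",
]

STRATUM_FIELDS = [
    "cancer_type", "diagnosis_year", "sex", "age_group6", "region17",
    "seer_stage",
]


@dataclass(frozen=True)
class EligibilityRules:
    exclude_secondary: bool = True
    required_fields: Sequence[str] = tuple(REQUIRED_FIELDS)
    breast_female_only: bool = True
    min_stratum_size: int = 5

    def __post_init__(self):
        if self.min_stratum_size < 1:
            raise ConfigurationError("min_stratum_size must be >= 1")


class StratumKey(NamedTuple):
    cancer_type: str
    diagnosis_year: int
    sex: str
    age_group6: str
    region17: str
    seer_stage: str


@dataclass
class StratumSummary:
    """One stratification cell with its population cost statistics.

    ``sigma_h`` is the population (divide-by-N) standard deviation of annual
    cost: in the representativeness interval it plays the role of a known
    population parameter, not an estimate.
    """

    key: StratumKey
    N_h: int
    pop_mean: float
    sigma_h: float
    member_ids: np.ndarray
    member_costs: np.ndarray


def recode_age_group(age_at_diagnosis: float) -> str:
    """Map an age in years onto the six stratification groups."""
    if age_at_diagnosis < 0:
        raise InputDataError(f"negative age: {age_at_diagnosis}")
    idx = int(np.searchsorted(_AGE_EDGES, age_at_diagnosis, side="right"))
    return AGE_GROUP_LABELS[idx]


def recode_age_groups(ages: pd.Series) -> pd.Series:
    """Vectorized :func:`recode_age_group`."""
    a = pd.to_numeric(ages)
    if (a < 0).any():
        raise InputDataError("negative age in input")
    idx = np.searchsorted(_AGE_EDGES, a.to_numpy(), side="right")
    return pd.Series(np.asarray(AGE_GROUP_LABELS, dtype=object)[idx],
                     index=ages.index)


def recode_region(region17: str, mapping: Mapping[str, str]) -> str:
    """Look up the 3-group (metropolitan/city/rural) recode of a region."""
    try:
        return mapping[region17]
    except KeyError:
        raise ConfigurationError(
            f"region {region17!r} not in the 17->3 mapping") from None


def recode_regions(regions: pd.Series, mapping: Mapping[str, str]) -> pd.Series:
    unmapped = set(regions.dropna().unique()) - set(mapping)
    if unmapped:
        raise ConfigurationError(
            f"regions not in the 17->3 mapping: {sorted(unmapped)}")
    return regions.map(mapping)


def example_region3_mapping() -> dict[str, str]:
    """A sample 17->3 recode for testing; not the authoritative one."""
    metro = {"Seoul", "Busan", "Daegu", "Incheon", "Gwangju", "Daejeon",
             "Ulsan"}
    city = {"Gyeonggi", "Sejong"}
    out = {}
    for r in published.REGIONS_17:
        out[r] = ("metropolitan" if r in metro
                  else "city" if r in city else "rural")
    return out


def apply_exclusions(registry: pd.DataFrame, rules: EligibilityRules,
                     cancer_types: Sequence[str] | None = None,
                     ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the eligibility filter; return the eligible rows and a tally.

    A row excluded for several reasons is tallied once, under the first
    matching reason in the order secondary cancer -> missing data -> male
    breast record; eligibility itself does not depend on the order.
    """
    missing_cols = [c for c in rules.required_fields if c not in registry.columns]
    if missing_cols:
        raise InputDataError(f"registry lacks required columns: {missing_cols}")
    known = set(cancer_types if cancer_types is not None
                else published.CANCER_TYPES)
    labels = set(registry["cancer_type"].dropna().unique())
    if not labels <= known:
        raise InputDataError(
            f"unknown cancer_type labels: {sorted(labels - known)}")

    n = len(registry)
    secondary = (registry["secondary_cancer"].fillna(False).to_numpy(bool)
                 if rules.exclude_secondary and "secondary_cancer" in registry
                 else np.zeros(n, dtype=bool))
    missing = registry[list(rules.required_fields)].isna().any(axis=1).to_numpy()
    male_breast = ((registry["cancer_type"] == "breast")
                   & (registry["sex"] == "male")).to_numpy() \
        if rules.breast_female_only else np.zeros(n, dtype=bool)

    tally = {
        "secondary_cancer": int(secondary.sum()),
        "missing_data": int((missing & ~secondary).sum()),
        "male_breast": int((male_breast & ~secondary & ~missing).sum()),
    }
    eligible = registry.loc[~(secondary | missing | male_breast)].copy()
    return eligible, tally


def build_strata(eligible: pd.DataFrame) -> list[StratumSummary]:
    """Partition eligible rows into strata and summarize annual cost per cell.

    The returned strata are disjoint and exhaustive over the input; order is
    deterministic (sorted on the stratum key).
    """
    if eligible.empty:
        return []
    df = eligible
    if "age_group6" not in df.columns:
        df = df.assign(age_group6=recode_age_groups(df["age_at_diagnosis"]))
    out: list[StratumSummary] = []
    grouped = df.groupby(STRATUM_FIELDS, sort=True)
    for key, sub in grouped:
        costs = sub["annual_cost_usd"].to_numpy(float)
        out.append(StratumSummary(
            key=StratumKey(key[0], int(key[1]), key[2], key[3], key[4], key[5]),
            N_h=len(sub),
            pop_mean=float(costs.mean()),
            sigma_h=float(costs.std(ddof=0)),
            member_ids=sub["patient_id"].to_numpy(),
            member_costs=costs,
        ))
    return out


def suppress_small_strata(strata: Sequence[StratumSummary],
                          min_stratum_size: int = 5,
                          ) -> tuple[list[StratumSummary], dict[str, int]]:
    """Drop strata below the disclosure-control size floor.

    Patients in suppressed strata leave the target population entirely; the
    tally reports both the strata and the patients removed.
    """
    if min_stratum_size < 1:
        raise ConfigurationError("min_stratum_size must be >= 1")
    kept = [s for s in strata if s.N_h >= min_stratum_size]
    dropped = [s for s in strata if s.N_h < min_stratum_size]
    tally = {
        "strata_suppressed": len(dropped),
        "patients_suppressed": int(sum(s.N_h for s in dropped)),
    }
    return kept, tally
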