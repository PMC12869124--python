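"""Survival validation of a sampled cohort against its source population.

Per stratum, the sample's survival experience is compared to the full
stratum population with a one-sample log-rank test: the population's
Nelson-Aalen cumulative hazard Lambda(t) serves as the reference, the
expected event count is E = sum_i Lambda(t_i) over the sampled subjects'
follow-up times, and Z = (O - E) / sqrt(E) is referred to a standard
normal (two-sided).  Because the sample is a subset of the population, the
test is if anything conservative; the reported proportion of strata that do
not reject at alpha = 0.05 summarizes survival representativeness.

Cohort-level agreement is checked with Kaplan-Meier curves (via lifelines)
and follow-up-time order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .prep import STRATUM_FIELDS, StratumKey, recode_age_groups

__all__ = [
    "KMCurve",
    "ReferenceHazard",
    "LogRankResult",
    "kaplan_meier",
    "reference_cumulative_hazard",
    "one_sample_logrank",
    "stratum_pass_proportion",
    "follow_up_summary",
    "validate_cohort",
    "pass_proportion_by_cancer",
    "km_sup_distance",
]


def _as_indicator(events) -> np.ndarray:
    """Accept 0/1, booleans, or {"death", "censored"} labels."""
    arr = np.asarray(events)
    if arr.dtype.kind in "OU":
        return (arr == "death").astype(int)
    return arr.astype(int)


@dataclass
class KMCurve:
    """Product-limit survival step function.

    ``survival[i]`` is S(t) just after ``event_times[i]``; S = 1 before the
    first event time.  ``at_risk``/``events`` are the risk set size and death
    count at each event time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.event_times, np.asarray(t, float),
                              side="right")
        surv = np.concatenate([[1.0], self.survival])
        return surv[idx]


@dataclass
class ReferenceHazard:
    """Nelson-Aalen cumulative hazard step function Lambda(t).

    Lambda(t) = sum over event times t_i <= t of d_i / n_i; flat beyond the
    last population event time.
    """

    event_times: np.ndarray
    cumhaz: np.ndarray

    def cumhaz_at(self, t) -> np.ndarray:
        idx = np.searchsorted(self.event_times, np.asarray(t, float),
                              side="right")
        ch = np.concatenate([[0.0], self.cumhaz])
        return ch[idx]


@dataclass
class LogRankResult:
    stratum: StratumKey | None
    n: int
    observed: int
    expected: float
    z: float
    p_value: float
    passed: bool
    undefined: bool = False


def kaplan_meier(times, events) -> KMCurve:
    """Product-limit estimator; ties of events and censorings resolve
    events-first (the standard risk-set convention)."""
    times = np.asarray(times, float)
    ind = _as_indicator(events)
    if times.size == 0:
        raise ValueError("empty input")
    if times.size != ind.size:
        raise ValueError("times and events must have equal length")
    if (times < 0).any():
        raise ValueError("negative follow-up time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, ind)
    table = kmf.event_table
    mask = table["observed"] > 0
    t = table.index.to_numpy(float)[mask.to_numpy()]
    surv = kmf.survival_function_at_times(t).to_numpy()
    return KMCurve(
        event_times=t,
        survival=surv,
        at_risk=table.loc[mask, "at_risk"].to_numpy(int),
        events=table.loc[mask, "observed"].to_numpy(int),
    )


def reference_cumulative_hazard(times, events) -> ReferenceHazard:
    """Nelson-Aalen estimator on a stratum population."""
    times = np.asarray(times, float)
    ind = _as_indicator(events)
    if times.size == 0:
        raise ValueError("empty population")
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    d_sorted = ind[order]
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    # deaths per unique time and risk set just before each time
    deaths = np.add.reduceat(d_sorted, first_idx)
    n_at_risk = times.size - first_idx
    mask = deaths > 0
    increments = deaths[mask] / n_at_risk[mask]
    return ReferenceHazard(event_times=uniq[mask],
                           cumhaz=np.cumsum(increments))


def one_sample_logrank(times, events, reference: ReferenceHazard,
                       alpha: float = 0.05,
                       stratum: StratumKey | None = None) -> LogRankResult:
    """Compare a sample's survival to a reference population's hazard.

    O is the sample's event count, E the expected count under the reference
    cumulative hazard evaluated at each subject's follow-up time.  Degenerate
    cases: O = E = 0 passes with p = 1 (no information against the null);
    E = 0 with O > 0 is undefined and reported as a flagged failure.
    """
    times = np.asarray(times, float)
    ind = _as_indicator(events)
    if times.size == 0:
        raise ValueError("empty sample")
    observed = int(ind.sum())
    expected = float(reference.cumhaz_at(times).sum())
    if expected == 0.0:
        if observed == 0:
            return LogRankResult(stratum, times.size, 0, 0.0, 0.0, 1.0, True)
        return LogRankResult(stratum, times.size, observed, 0.0,
                             np.inf, 0.0, False, undefined=True)
    z = (observed - expected) / np.sqrt(expected)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return LogRankResult(stratum, times.size, observed, expected, float(z),
                         p, p > alpha)


def stratum_pass_proportion(results: Iterable[LogRankResult]) -> float:
    """Fraction of strata whose test did not reject the null."""
    results = list(results)
    if not results:
        raise ValueError("empty result list")
    return sum(r.passed for r in results) / len(results)


def follow_up_summary(times) -> tuple[float, float, float]:
    """(median, min, max) follow-up regardless of event status."""
    times = np.asarray(times, float)
    if times.size == 0:
        raise ValueError("empty input")
    return float(np.median(times)), float(times.min()), float(times.max())


def validate_cohort(population: pd.DataFrame, cohort_ids: np.ndarray,
                    alpha: float = 0.05) -> pd.DataFrame:
    """One-sample log-rank per stratum: sampled members vs their stratum.

    ``population`` must carry the registry schema for the eligible, kept
    population; the reference hazard is built from the *full* stratum
    (sampled members included — the sample is a subset by design).
    Returns one row per sampled stratum with O, E, Z, p, pass and event
    counts; downstream reports can apply an event-count floor.
    """
    df = population
    if "age_group6" not in df.columns:
        df = df.assign(age_group6=recode_age_groups(df["age_at_diagnosis"]))
    in_cohort = df["patient_id"].isin(np.asarray(cohort_ids))
    rows = []
    for key, sub in df.groupby(STRATUM_FIELDS, sort=True):
        samp = sub.loc[in_cohort.reindex(sub.index)]
        if samp.empty:
            continue
        ref = reference_cumulative_hazard(sub["time_years"], sub["event"])
        res = one_sample_logrank(samp["time_years"], samp["event"], ref,
                                 alpha=alpha,
                                 stratum=StratumKey(*key))
        rows.append({
            **res.stratum._asdict(),
            "N_h": len(sub), "n_h": res.n,
            "population_events": int(_as_indicator(sub["event"]).sum()),
            "observed": res.observed, "expected": res.expected,
            "z": res.z, "p_value": res.p_value, "passed": res.passed,
            "undefined": res.undefined,
        })
    return pd.DataFrame(rows)


def pass_proportion_by_cancer(validation: pd.DataFrame,
                              min_events: int = 0) -> pd.DataFrame:
    """Per-cancer pass proportions, on all strata and above an event floor.

    Whether the published pass rates excluded low-event strata is not
    stated, so both summaries are reported.
    """
    rows = []
    for cancer, sub in validation.groupby("cancer_type"):
        floored = sub[sub["population_events"] >= min_events]
        rows.append({
            "cancer_type": cancer,
            "n_strata": len(sub),
            "pass_proportion": float(sub["passed"].mean()),
            "n_strata_floored": len(floored),
            "pass_proportion_floored": (float(floored["passed"].mean())
                                        if len(floored) else np.nan),
        })
    return pd.DataFrame(rows)


def km_sup_distance(times_a, events_a, times_b, events_b) -> float:
    """Sup-norm distance between two KM curves on their pooled time grid."""
    km_a = kaplan_meier(times_a, events_a)
    km_b = kaplan_meier(times_b, events_b)
    grid = np.union1d(km_a.event_times, km_b.event_times)
    if grid.size == 0:
        return 0.0
    return float(np.max(np.abs(km_a.survival_at(grid) - km_b.survival_at(grid))))


# ---------------------------------------------------------------------------
# Monte-Carlo calibration of the one-sample log-rank test


def simulate_null_rejection_rate(n_reps: int = 2000, n_pop: int = 2000,
                                 n_sample: int = 60, hazard: float = 0.3,
                                 censor_time: float = 5.0,
                                 alpha: float = 0.05,
                                 seed: int = 0) -> float:
    """Empirical size: SRSWOR samples from exponential populations with
    administrative censoring, tested against their own population hazard.

    The sampling fraction is kept small so that the overlap between sample
    and reference does not deflate the nominal size.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x6c72]))
    rejections = 0
    for _ in range(n_reps):
        latent = rng.exponential(1.0 / hazard, size=n_pop)
        times = np.minimum(latent, censor_time)
        events = (latent <= censor_time).astype(int)
        ref = reference_cumulative_hazard(times, events)
        idx = rng.choice(n_pop, size=n_sample, replace=False)
        res = one_sample_logrank(times[idx], events[idx], ref, alpha=alpha)
        rejections += not res.passed
    return rejections / n_reps


def simulate_power_scaled_hazard(n_reps: int = 500, n_pop: int = 2000,
                                 n_sample: int = 200, hazard: float = 0.3,
                                 censor_time: float = 50.0,
                                 time_scale: float = 0.5,
                                 alpha: float = 0.05,
                                 seed: int = 0) -> float:
    """Empirical power when sample survival times are scaled by
    ``time_scale`` (0.5 doubles the hazard) against an unscaled reference.

    The long censoring window makes essentially every sampled subject an
    event, so ``n_sample`` is the event count.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7072]))
    rejections = 0
    for _ in range(n_reps):
        latent = rng.exponential(1.0 / hazard, size=n_pop)
        times = np.minimum(latent, censor_time)
        events = (latent <= censor_time).astype(int)
        ref = reference_cumulative_hazard(times, events)
        idx = rng.choice(n_pop, size=n_sample, replace=False)
        scaled = np.minimum(latent[idx] * time_scale, censor_time)
        ev = (latent[idx] * time_scale <= censor_time).astype(int)
        res = one_sample_logrank(scaled, ev, ref, alpha=alpha)
        rejections += not res.passed
    return rejections / n_reps
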