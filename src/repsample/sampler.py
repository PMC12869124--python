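"""Representative stratified sampling with a finite-population-correction
criterion.

Within each stratum a simple random sample without replacement (SRSWOR) is
drawn at the configured rate (proportional allocation, 20% by default).
The draw is *representative* when the stratum's population mean annual cost
lies inside the sample's 95% confidence interval for sampling without
replacement,

    ybar_h +/- z * sqrt((N_h - n_h) / (N_h - 1)) * sigma_h / sqrt(n_h),

with sigma_h the known population SD of the stratum.  A non-representative
first draw triggers up to ``max_candidates`` independent redraws at the same
size; among the representative candidates the one whose mean is closest to
the population mean is kept.  If no candidate qualifies, the sample size is
incremented and the process repeats — at n_h = N_h the sample is the stratum
and is representative by construction, so termination is guaranteed.

Randomness discipline: one master seed; each stratum gets an independent
substream keyed by a hash of its stratum key, so adding or removing a
stratum does not perturb the draws of the others.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .prep import StratumKey, StratumSummary

__all__ = [
    "SamplerConfig",
    "CandidateSample",
    "StratumSampleRecord",
    "SamplingResult",
    "fpc_half_width",
    "fpc_confidence_interval",
    "margin_of_error_size",
    "allocate_sample_size",
    "draw_candidate",
    "select_stratum_sample",
    "sample_cohort",
]


@dataclass(frozen=True)
class SamplerConfig:
    """Sampling-rate, representativeness and resampling parameters.

    ``max_candidates`` caps the redraws after a failed first draw;
    ``always_best_of_k`` switches to the alternative reading in which the
    best of ``max_candidates`` draws is always used, even when the first
    draw already qualifies.  ``relative_margin`` only feeds the
    margin-of-error size report, not the sampling itself.
    """

    sampling_rate: float = 0.20
    z_value: float = 1.96
    max_candidates: int = 50
    augmentation_step: int = 1
    relative_margin: float = 0.01
    always_best_of_k: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.sampling_rate <= 1.0:
            raise ConfigurationError("sampling_rate must be in (0, 1]")
        if self.max_candidates < 1:
            raise ConfigurationError("max_candidates must be >= 1")
        if self.augmentation_step < 1:
            raise ConfigurationError("augmentation_step must be >= 1")


@dataclass
class CandidateSample:
    stratum: StratumKey
    member_ids: np.ndarray
    n_h: int
    sample_mean: float
    ci_low: float
    ci_high: float
    representative: bool
    candidate_index: int


@dataclass
class StratumSampleRecord:
    key: StratumKey
    chosen: CandidateSample
    attempts: int
    final_n_h: int
    augmented: bool
    # (candidate_index, n_h, sample_mean, representative) for every draw
    candidate_log: list[tuple[int, int, float, bool]]


@dataclass
class SamplingResult:
    per_stratum: dict[StratumKey, StratumSampleRecord]
    cohort_ids: np.ndarray
    config: SamplerConfig

    def attempts_table(self) -> pd.DataFrame:
        rows = []
        for key, rec in self.per_stratum.items():
            rows.append({
                **key._asdict(),
                "final_n_h": rec.final_n_h,
                "attempts": rec.attempts,
                "augmented": rec.augmented,
                "candidate_index": rec.chosen.candidate_index,
                "sample_mean": rec.chosen.sample_mean,
                "ci_low": rec.chosen.ci_low,
                "ci_high": rec.chosen.ci_high,
            })
        return pd.DataFrame(rows)

    def sampling_fractions(self, strata: Sequence[StratumSummary]
                           ) -> pd.DataFrame:
        """Realized per-cancer and overall sampling fractions."""
        pop = {}
        for s in strata:
            pop[s.key.cancer_type] = pop.get(s.key.cancer_type, 0) + s.N_h
        samp: dict[str, int] = {}
        for key, rec in self.per_stratum.items():
            samp[key.cancer_type] = samp.get(key.cancer_type, 0) + rec.final_n_h
        rows = [{"cancer_type": c, "population_n": pop[c],
                 "sample_n": samp.get(c, 0),
                 "fraction": samp.get(c, 0) / pop[c]} for c in sorted(pop)]
        total_pop = sum(pop.values())
        total_samp = sum(samp.values())
        rows.append({"cancer_type": "all", "population_n": total_pop,
                     "sample_n": total_samp,
                     "fraction": total_samp / total_pop if total_pop else 0.0})
        return pd.DataFrame(rows)


def fpc_half_width(sigma_h: float, N_h: int, n_h: int,
                   z_value: float = 1.96) -> float:
    """Half-width of the without-replacement CI for a stratum mean."""
    if n_h < 1:
        raise ValueError("n_h must be >= 1")
    if n_h > N_h:
        raise ValueError("n_h cannot exceed N_h")
    if sigma_h < 0:
        raise ValueError("sigma_h must be >= 0")
    if n_h == N_h:
        return 0.0
    return z_value * math.sqrt((N_h - n_h) / (N_h - 1)) * sigma_h / math.sqrt(n_h)


def fpc_confidence_interval(sample_mean: float, sigma_h: float, N_h: int,
                            n_h: int, z_value: float = 1.96
                            ) -> tuple[float, float]:
    """Symmetric FPC confidence interval about the sample mean."""
    hw = fpc_half_width(sigma_h, N_h, n_h, z_value)
    return sample_mean - hw, sample_mean + hw


def margin_of_error_size(pop_mean: float, sigma_h: float, N_h: int,
                         relative_margin: float = 0.01,
                         z_value: float = 1.96) -> int:
    """Smallest n whose FPC half-width is within a relative margin of the mean.

    Closed form: n0 = (z sigma / d)^2 with d the absolute margin, deflated by
    the finite-population factor to n0 N / (N - 1 + n0), then rounded up and
    capped at N.  Used to report the sizes a 1% margin of error would have
    required, against which the fixed 20% rate is compared.
    """
    if pop_mean <= 0:
        raise ValueError("pop_mean must be > 0 for a relative margin")
    if relative_margin <= 0:
        raise ValueError("relative_margin must be > 0")
    if sigma_h == 0:
        return 1
    d = relative_margin * pop_mean
    n0 = (z_value * sigma_h / d) ** 2
    n = n0 * N_h / (N_h - 1 + n0)
    return min(N_h, max(1, math.ceil(n - 1e-9)))


def allocate_sample_size(N_h: int, sampling_rate: float) -> int:
    """Proportional allocation with ceiling, so every stratum keeps >= 1 unit."""
    if N_h < 1:
        raise ValueError("N_h must be >= 1")
    return min(N_h, max(1, math.ceil(round(sampling_rate * N_h, 9))))


def _representative(pop_mean: float, ci_low: float, ci_high: float,
                    n_h: int, N_h: int) -> bool:
    # closed interval; census is representative by construction
    if n_h == N_h:
        return True
    eps = 1e-9 * max(1.0, abs(pop_mean))
    return (ci_low - eps) <= pop_mean <= (ci_high + eps)


def draw_candidate(stratum: StratumSummary, n_h: int,
                   rng: np.random.Generator, z_value: float = 1.96,
                   candidate_index: int = 0) -> CandidateSample:
    """One SRSWOR draw from a stratum, with its representativeness verdict."""
    if not 1 <= n_h <= stratum.N_h:
        raise ValueError(f"n_h={n_h} outside [1, N_h={stratum.N_h}]")
    idx = rng.choice(stratum.N_h, size=n_h, replace=False)
    mean = float(stratum.member_costs[idx].mean())
    lo, hi = fpc_confidence_interval(mean, stratum.sigma_h, stratum.N_h,
                                     n_h, z_value)
    return CandidateSample(
        stratum=stratum.key,
        member_ids=stratum.member_ids[idx],
        n_h=n_h,
        sample_mean=mean,
        ci_low=lo,
        ci_high=hi,
        representative=_representative(stratum.pop_mean, lo, hi, n_h,
                                       stratum.N_h),
        candidate_index=candidate_index,
    )


def _best_candidate(candidates: list[CandidateSample],
                    pop_mean: float) -> CandidateSample | None:
    reps = [c for c in candidates if c.representative]
    if not reps:
        return None
    # ties broken by lowest candidate index (stable min)
    return min(reps, key=lambda c: (abs(c.sample_mean - pop_mean),
                                    c.candidate_index))


def select_stratum_sample(stratum: StratumSummary, config: SamplerConfig,
                          rng: np.random.Generator) -> StratumSampleRecord:
    """Run the accept / resample / augment loop for one stratum."""
    n_h = allocate_sample_size(stratum.N_h, config.sampling_rate)
    initial_n = n_h
    attempts = 0
    log: list[tuple[int, int, float, bool]] = []

    while True:
        chosen: CandidateSample | None = None
        if config.always_best_of_k:
            candidates = []
            for i in range(config.max_candidates):
                c = draw_candidate(stratum, n_h, rng, config.z_value, i)
                attempts += 1
                log.append((i, n_h, c.sample_mean, c.representative))
                candidates.append(c)
            chosen = _best_candidate(candidates, stratum.pop_mean)
        else:
            first = draw_candidate(stratum, n_h, rng, config.z_value, 0)
            attempts += 1
            log.append((0, n_h, first.sample_mean, first.representative))
            if first.representative:
                chosen = first
            else:
                candidates = []
                for i in range(1, config.max_candidates + 1):
                    c = draw_candidate(stratum, n_h, rng, config.z_value, i)
                    attempts += 1
                    log.append((i, n_h, c.sample_mean, c.representative))
                    candidates.append(c)
                chosen = _best_candidate(candidates, stratum.pop_mean)
        if chosen is not None:
            return StratumSampleRecord(
                key=stratum.key, chosen=chosen, attempts=attempts,
                final_n_h=chosen.n_h, augmented=chosen.n_h > initial_n,
                candidate_log=log)
        if n_h >= stratum.N_h:  # census is always representative; unreachable
            raise AssertionError("census draw must be representative")
        n_h = min(stratum.N_h, n_h + config.augmentation_step)


def _stratum_rng(seed: int, key: StratumKey) -> np.random.Generator:
    digest = hashlib.sha256("|".join(map(str, key)).encode()).digest()
    sub = int.from_bytes(digest[:8], "big")
    return np.random.default_rng(np.random.SeedSequence([seed, sub]))


def sample_cohort(strata: Sequence[StratumSummary],
                  config: SamplerConfig) -> SamplingResult:
    """Sample every stratum with an independent substream per stratum."""
    per: dict[StratumKey, StratumSampleRecord] = {}
    ids: list[np.ndarray] = []
    for stratum in sorted(strata, key=lambda s: s.key):
        rng = _stratum_rng(config.seed, stratum.key)
        rec = select_stratum_sample(stratum, config, rng)
        per[stratum.key] = rec
        ids.append(rec.chosen.member_ids)
    cohort = (np.concatenate(ids) if ids else np.array([], dtype=int))
    if len(np.unique(cohort)) != len(cohort):
        raise AssertionError("cohort ids not unique across strata")
    return SamplingResult(per_stratum=per, cohort_ids=cohort, config=config)


def margin_of_error_report(strata: Sequence[StratumSummary],
                           config: SamplerConfig) -> pd.DataFrame:
    """Per-stratum margin-of-error sizes vs the proportional allocation.

    Flags strata where the fixed sampling rate falls short of the size the
    relative margin would require (possible in small, high-variance strata).
    """
    rows = []
    for s in strata:
        alloc = allocate_sample_size(s.N_h, config.sampling_rate)
        if s.pop_mean > 0:
            required = margin_of_error_size(
                s.pop_mean, s.sigma_h, s.N_h, config.relative_margin,
                config.z_value)
        else:
            required = s.N_h
        rows.append({**s.key._asdict(), "N_h": s.N_h,
                     "allocated_n": alloc, "required_n": required,
                     "rate_sufficient": alloc >= required})
    return pd.DataFrame(rows)
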