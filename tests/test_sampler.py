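"""FPC interval, allocation, candidate draws, accept/resample/augment loop."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from repsample.prep import StratumKey, StratumSummary
from repsample.sampler import (SamplerConfig, allocate_sample_size,
                               draw_candidate, fpc_confidence_interval,
                               fpc_half_width, margin_of_error_size,
                               sample_cohort, select_stratum_sample)


def _stratum(costs, key_suffix="a"):
    costs = np.asarray(costs, float)
    offset = 1000 * (ord(key_suffix[0]) % 100)  # distinct ids across strata
    return StratumSummary(
        key=StratumKey("stomach", 2015, "male", "60-69", "Seoul", key_suffix),
        N_h=len(costs),
        pop_mean=float(costs.mean()),
        sigma_h=float(costs.std(ddof=0)),
        member_ids=offset + np.arange(len(costs)),
        member_costs=costs,
    )


class TestFpcInterval:
    def test_worked_value(self):
        """ybar=50, sigma=10, N=100, n=20, z=1.96: half-width 3.9397."""
        lo, hi = fpc_confidence_interval(50.0, 10.0, 100, 20, 1.96)
        hw = 1.96 * math.sqrt((100 - 20) / 99) * 10 / math.sqrt(20)
        assert hw == pytest.approx(3.9397, abs=1e-4)
        assert lo == pytest.approx(50 - hw)
        assert hi == pytest.approx(50 + hw)

    def test_census_and_constant_stratum_degenerate(self):
        assert fpc_confidence_interval(50.0, 10.0, 100, 100) == (50.0, 50.0)
        assert fpc_confidence_interval(50.0, 0.0, 100, 20) == (50.0, 50.0)
        assert fpc_confidence_interval(7.0, 3.0, 1, 1) == (7.0, 7.0)

    def test_zero_sample_rejected(self):
        with pytest.raises(ValueError):
            fpc_confidence_interval(50.0, 10.0, 100, 0)

    @given(st.integers(min_value=2, max_value=500),
           st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
    def test_half_width_nonincreasing_in_n(self, N, sigma):
        widths = [fpc_half_width(sigma, N, n) for n in range(1, N + 1)]
        assert all(a >= b - 1e-12 for a, b in zip(widths, widths[1:]))
        assert widths[-1] == 0.0


class TestMarginOfErrorSize:
    def test_constant_stratum_needs_one(self):
        assert margin_of_error_size(100.0, 0.0, 10_000) == 1

    def test_closed_form_matches_scan_oracle(self):
        """mu=100, sigma=10, 1% margin, N=10,000: n0=384.16, deflated to 370."""
        n = margin_of_error_size(100.0, 10.0, 10_000, 0.01, 1.96)
        assert n == 370
        # independent oracle: scan for the smallest n meeting the margin
        d = 1.0
        scan = next(m for m in range(1, 10_001)
                    if fpc_half_width(10.0, 10_000, m, 1.96) <= d)
        assert n == scan

    @pytest.mark.parametrize("sigma,N", [(5.0, 50), (50.0, 200), (20.0, 37)])
    def test_minimality_contract(self, sigma, N):
        n = margin_of_error_size(100.0, sigma, N, 0.01, 1.96)
        d = 1.0
        assert 1 <= n <= N
        if n < N:
            assert fpc_half_width(sigma, N, n) <= d + 1e-9
        if n > 1:
            assert fpc_half_width(sigma, N, n - 1) > d

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            margin_of_error_size(0.0, 10.0, 100)


class TestAllocation:
    @pytest.mark.parametrize("N,rate,expected", [
        (100, 0.20, 20), (5, 0.20, 1), (6, 0.20, 2), (100, 1.0, 100),
        (1, 0.20, 1), (7, 0.5, 4),
    ])
    def test_ceiling_allocation(self, N, rate, expected):
        assert allocate_sample_size(N, rate) == expected

    @given(st.integers(min_value=1, max_value=10_000))
    def test_allocation_bounds(self, N):
        n = allocate_sample_size(N, 0.20)
        assert 1 <= n <= N
        assert n >= 0.20 * N - 1e-9


class TestDrawCandidate:
    def test_census_draw_is_whole_stratum(self, rng):
        s = _stratum([1.0, 2.0, 3.0])
        c = draw_candidate(s, 3, rng)
        assert sorted(c.member_ids) == sorted(s.member_ids)
        assert c.representative

    def test_same_rng_state_reproduces_draw(self):
        s = _stratum(np.arange(50.0))
        a = draw_candidate(s, 10, np.random.default_rng(5))
        b = draw_candidate(s, 10, np.random.default_rng(5))
        assert np.array_equal(a.member_ids, b.member_ids)
        assert a.sample_mean == b.sample_mean

    def test_oversized_draw_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_candidate(_stratum([1.0, 2.0]), 3, rng)

    def test_subset_uniformity(self, rng):
        """All C(5,2)=10 unordered pairs appear with frequency ~1/10."""
        s = _stratum([0.0, 1.0, 2.0, 3.0, 4.0])
        counts = {}
        n_draws = 10_000
        for _ in range(n_draws):
            c = draw_candidate(s, 2, rng)
            counts[frozenset(c.member_ids.tolist())] = \
                counts.get(frozenset(c.member_ids.tolist()), 0) + 1
        assert len(counts) == 10
        p = 1 / 10
        sd = math.sqrt(n_draws * p * (1 - p))
        for k, v in counts.items():
            assert abs(v - n_draws * p) < 3.5 * sd, k


class TestSelectStratumSample:
    def test_constant_costs_accept_first_draw(self, rng):
        s = _stratum([5.0] * 20)
        rec = select_stratum_sample(s, SamplerConfig(), rng)
        assert rec.attempts == 1
        assert rec.final_n_h == allocate_sample_size(20, 0.20)
        assert not rec.augmented

    def test_final_candidate_always_representative(self):
        """High-variance tiny stratum forced to n=1 may resample or augment,
        but the accepted candidate always carries the guarantee."""
        for seed in range(30):
            rng = np.random.default_rng(seed)
            s = _stratum([0.0, 0.0, 1000.0, 1000.0, 5000.0])
            rec = select_stratum_sample(s, SamplerConfig(), rng)
            assert rec.chosen.representative
            assert (rec.chosen.ci_low - 1e-6 <= s.pop_mean
                    <= rec.chosen.ci_high + 1e-6)

    def test_engineered_stratum_selects_balanced_pair(self):
        """Costs {0 x4, 100 x4} at n=2 under best-of-k selection: a {0,100}
        pair (mean 50 = pop mean) is the unique closest-mean choice, as
        exhaustive enumeration of all C(8,2) subsets confirms."""
        costs = [0.0] * 4 + [100.0] * 4
        s = _stratum(costs)
        # brute-force oracle over all C(8,2) subsets: the wide half-width
        # (~64.2) makes every pair representative, but only {0,100} attains
        # |mean - pop mean| = 0
        hw = 1.96 * math.sqrt((8 - 2) / 7) * s.sigma_h / math.sqrt(2)
        dists = {abs(np.mean(pair) - 50.0) for pair in
                 itertools.combinations(costs, 2)
                 if abs(np.mean(pair) - 50.0) <= hw}
        assert min(dists) == 0.0 and len(dists) > 1
        for seed in range(10):
            rec = select_stratum_sample(
                s, SamplerConfig(always_best_of_k=True),
                np.random.default_rng(seed))
            positions = np.searchsorted(s.member_ids, rec.chosen.member_ids)
            chosen_costs = sorted(s.member_costs[positions])
            assert rec.chosen.sample_mean == pytest.approx(50.0)
            assert chosen_costs == [0.0, 100.0]

    def test_closest_mean_among_representative_candidates(self):
        """When the first draw fails, the accepted candidate minimizes
        |mean - pop mean| over the representative candidates in the log."""
        rng = np.random.default_rng(0)
        s = _stratum(np.concatenate([np.zeros(6), np.full(6, 1000.0),
                                     [10_000.0]]))
        found = False
        for seed in range(200):
            rec = select_stratum_sample(s, SamplerConfig(max_candidates=10),
                                        np.random.default_rng(seed))
            final_round = [e for e in rec.candidate_log
                           if e[1] == rec.final_n_h and e[0] > 0]
            if final_round:  # first draw failed at the final size
                found = True
                reps = [e for e in final_round if e[3]]
                best = min(abs(e[2] - s.pop_mean) for e in reps)
                assert abs(rec.chosen.sample_mean - s.pop_mean) == \
                    pytest.approx(best)
        assert found


class TestSampleCohort:
    def test_empty_strata(self):
        result = sample_cohort([], SamplerConfig())
        assert result.cohort_ids.size == 0

    def test_deterministic_under_master_seed(self):
        strata = [_stratum(np.arange(30.0) * 7, k) for k in "abc"]
        a = sample_cohort(strata, SamplerConfig(seed=9))
        b = sample_cohort(strata, SamplerConfig(seed=9))
        assert np.array_equal(np.sort(a.cohort_ids), np.sort(b.cohort_ids))

    def test_adding_stratum_does_not_perturb_others(self):
        strata = [_stratum(np.arange(30.0) * 7, k) for k in "abc"]
        a = sample_cohort(strata, SamplerConfig(seed=9))
        b = sample_cohort(strata + [_stratum(np.arange(40.0), "d")],
                          SamplerConfig(seed=9))
        for k in list("abc"):
            key = StratumKey("stomach", 2015, "male", "60-69", "Seoul", k)
            assert np.array_equal(a.per_stratum[key].chosen.member_ids,
                                  b.per_stratum[key].chosen.member_ids)

    def test_constant_cost_composition(self):
        """With sigma=0 everywhere the cohort is exactly the ceiling
        allocation of every stratum."""
        strata = [_stratum([3.0] * n, str(n)) for n in (5, 7, 11, 40)]
        result = sample_cohort(strata, SamplerConfig(seed=0))
        expected = sum(math.ceil(0.2 * n) for n in (5, 7, 11, 40))
        assert result.cohort_ids.size == expected

    def test_unbiasedness_of_accepted_means(self):
        """Closest-mean selection shrinks toward the population mean but does
        not bias the accepted sample mean directionally."""
        s = _stratum(np.random.default_rng(3).lognormal(9.0, 0.8, size=100))
        n_h = allocate_sample_size(s.N_h, 0.20)
        means = []
        for seed in range(1000):
            rec = select_stratum_sample(s, SamplerConfig(seed=seed),
                                        np.random.default_rng(seed))
            means.append(rec.chosen.sample_mean)
        bias = abs(np.mean(means) - s.pop_mean)
        assert bias < 0.5 * s.sigma_h / math.sqrt(n_h)
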