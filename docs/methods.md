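# Methods

## The construction problem

A registry-linked cancer population (one row per patient: cancer type,
diagnosis year 2012–2019, sex, age at diagnosis, one of 17 regions, SEER
summary stage, annual medical cost, follow-up time and vital status) is to
be reduced to a ~20% sample cohort that can be released with weaker access
controls.  The release must be *representative*: per stratum for medical
costs, and per stratum and overall for survival.  `repsample` implements the
construction and its validation; a synthetic generator supplies populations
with the same joint structure, since the real data are access-restricted.

## Eligibility, stratification, suppression

Rows are excluded for (in tally order) a secondary-cancer flag, a missing
stratification field, or a male breast-cancer record; only the tally, not
eligibility, depends on the order.  Ages are recoded to six groups — 0–39,
four ten-year bands, 80+ ("<39 years" in narrative descriptions is read as
ages ≤ 39 so that the mapping is total, matching the release tables' "0-39"
row label).  Stratification uses the full 17-region classification; the
3-group metropolitan/city/rural recode is applied to *reports* only and is a
required configuration input, because no authoritative 17→3 table is
published (`configs/region3.yaml` is a sample).  Strata with fewer than five
patients are removed from the target population entirely (disclosure
control), and the pipeline reports eligible counts both before and after
suppression.

Per stratum h the cost summary keeps N_h, the population mean, and the
population standard deviation σ_h computed with the divide-by-N convention —
σ_h enters the representativeness interval as a *known population
parameter*, not an estimate.  Display tables use the sample (n−1) SD
convention, as release tables conventionally do.

## The representativeness criterion and sampling algorithm

Allocation is proportional with ceiling: n_h = min(N_h, ⌈rate · N_h⌉)
(rate 0.20 by default), so every stratum keeps at least one unit.  A SRSWOR
draw is representative when the stratum population mean lies in the closed
interval

    ybar_h ± z · sqrt((N_h − n_h)/(N_h − 1)) · σ_h / sqrt(n_h),   z = 1.96.

The algorithm per stratum: accept a representative first draw; otherwise
draw up to `max_candidates` (50) further independent candidates at the same
size and accept, among the representative ones, the candidate minimizing
|mean − population mean| (ties to the lowest candidate index); if none
qualifies, increase n_h by `augmentation_step` (1) and repeat.  At
n_h = N_h the sample is the stratum, the interval degenerates to the
population mean, and the draw is accepted — termination is structural, and
the accepted candidate always carries the CI guarantee.  A config switch
`always_best_of_k` selects the alternative reading in which the best of the
50 candidates is always used even when the first draw qualifies; note that
with wide intervals (small n_h, large σ_h) first-accept can keep a draw
whose mean is far from the population mean, whereas best-of-k cannot — the
test suite exercises both paths.

Randomness: one master seed; every stratum receives an independent
`numpy` substream keyed by a SHA-256 hash of its stratum key, so adding or
removing strata never perturbs the draws of the others, and the whole
pipeline is a pure function of its configuration.

The closed-form margin-of-error report inverts the half-width:
n0 = (zσ/d)² with d the absolute margin (1% of the mean by default),
deflated to n0·N/(N−1+n0), ceiled, capped at N.  It flags strata where the
20% allocation is below the size the margin would require (possible when
σ/mean is large in small strata) rather than resolving which of the two the
release procedure binds on, which is not documented.

## Survival validation

The reference per stratum is the Nelson–Aalen cumulative hazard
Λ(t) = Σ_{t_i ≤ t} d_i/n_i computed on the *full* stratum population
(sampled members included — the sample is a subset by design), flat beyond
the last event time.  The simple d/n form is implemented directly because it
is the estimator the expected-event calculation assumes; lifelines'
tie-smoothed variant serves as a cross-check in tests with smoothing
disabled.  The one-sample log-rank statistic is the classic normal
approximation O − E over √E with E = Σ Λ(t_i) over the sampled subjects'
follow-up times, two-sided.  Degenerate cases: E = O = 0 passes with p = 1;
E = 0 with O > 0 is undefined and reported as a flagged failure.  Ties put
events before censorings at equal times (subjects censored at t remain in
the risk set at t).

Because sample ⊂ population, O − E has less than nominal variance when the
sampling fraction is large, making the test conservative; the Monte-Carlo
calibration therefore uses a 3% sampling fraction (population 2,000, sample
60, exponential hazard 0.3/yr, administrative censoring at 5 years ≈ 78%
events) where the empirical size at α = 0.05 is ~0.04–0.05, and power
against a doubled sample hazard at 200 events is ~1.  Pass proportions are
reported per cancer on all strata and above a configurable
population-event floor (default 5), since it is not documented whether
published pass rates excluded low-event strata.  Kaplan–Meier estimation
goes through lifelines; cohort-level agreement is summarized as the sup
distance between population and sample curves on their pooled event grid.

## The synthetic registry generator

Defaults are the study conditions and are derived once from the published
release tables: per-cancer age/sex/stage/incidence-year weights are the
published population marginals (breast is female-only; liver has no
"in situ" stage), and annual cost is lognormal per cancer × age cell with
location/scale solved from the published mean ± SD (means ≈ 7,900–14,000
USD with SDs of the same order — SD ≈ mean motivates the lognormal).
Region-17 weights approximate Korean provincial population shares, since
only a 3-group recode is published.  Survival is piecewise-exponential with
rate = base(cancer) × stage multiplier × age multiplier; base rates
(stomach 0.05, breast 0.02, colorectal 0.06, liver 0.18 per person-year)
order prognosis breast > stomach ≈ colorectal > liver, and stage
multipliers (0.15, 0.5, 2, 8, 1.5 for in situ/localized/regional/distant/
unknown) produce stochastically ordered KM curves.  Diagnosis dates are
uniform within the year; follow-up is censored at December 31 of
`censor_cutoff_year` (default 2021).  Both the cutoff and the within-year
convention are parameters: published follow-up medians by diagnosis year
imply a shorter effective death-ascertainment window than the nominal one,
and the generator does not take a side.  Secondary-cancer flags and missing
stratification fields are injected at 2% each so the eligibility filter has
work to do.

What the generator does *not* emulate: cell-level correlation beyond
independent marginals (real registries concentrate patients in far fewer
strata per head), claims-level utilization, screening/checkup variables,
geography-realistic incidence, or cause-specific death.  Consequently,
passing tests show that the *construction* behaves as specified on
populations with the published marginal structure — not that any particular
published stratum count or cost value is reproduced.  One visible
consequence: at the 100,000-row validation scale the synthetic strata are
small (median ≈ 10), so ceiling allocation puts the realized overall
sampling fraction near 23%, the top of the plausible range, whereas the
full-size registry realizes 20.5–22.0%.

## Numerical choices

* Representativeness uses the closed interval with a relative tolerance of
  1e−9 on the population mean; a census draw is flagged representative
  without the float comparison (permutation of a sum can differ in the last
  ulp from the stored population mean).
* Proportional allocation rounds `rate × N_h` to 9 decimals before the
  ceiling, so binary artefacts like 0.2 × 100 = 20.000000000000004 do not
  inflate the allocation.
* Display rounding is decimal round-half-up at one decimal everywhere
  (banker's rounding would print 2.05 as 2.0); costs are stored in USD with
  the 1 USD = 1,300 KRW conversion available for display only.
* Validation-study problem sizes: 25,000 rows per cancer (100,000 total),
  2,000 null replicates and 500 power replicates for the log-rank
  calibration — sizes at which every checked band is stable across seeds.

## Known limitations

* The sampler optimizes cost-mean representativeness only; survival
  representativeness is verified afterwards, not enforced during selection
  (matching the construction it implements).
* The one-sample log-rank normal approximation is anti-conservative in
  strata with very few expected events; the event-floored pass summary is
  the more honest figure there.
* Rate ratios are count ratios; person-time denominators are not modelled.
* With `always_best_of_k` the accepted-mean distribution is shrunk toward
  the population mean; cost-based downstream variance estimates on the
  cohort are therefore mildly optimistic under either selection rule.
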