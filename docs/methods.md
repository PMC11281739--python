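# Methods

## Scope and data model

The package analyses elective hospital activity for back pain at the level
of an English commissioning locality: ~40 general practices, patients aged
18+, fiscal years labelled "2015/16"–"2019/20". Real extracts of this kind
are access-restricted, so the package's first stage is a synthetic
generator that reproduces the *statistical* structure the downstream
analyses assume; clinical coding (OPCS/HRG/ICD-10), geography lookup and
emergency/trauma activity are deliberately out of scope — deciles and
event classes arrive pre-assigned.

Three tables flow through the pipeline:

* **registers** — long format, one row per
  (practice, age band, sex, IMD decile) with a person count and the
  practice's deprivation score;
* **episodes** — one row per hospital contact: patient, age, sex,
  practice, IMD decile of residence, fiscal year, event class
  (attendance or procedure), intervention id;
* **portfolio** — one row per intervention: people treated per year,
  fixed cost, variable cost per person, QALY gain per person, evidence
  category (benefit / no evidence / no benefit / possible harm).

## Synthetic cohort model

Episode counts are Poisson per (practice *p*, band *b*, sex *x*, decile
*d*, year) stratum with mean

    base_rate x m(b, x) x exp(u_p) x g(d) x person_years

* `base_rate` (default 0.03 events/person-year) is the reference-stratum
  rate; the age-sex multipliers `m` form a smooth hump peaking near age 62
  (female rates 10% higher) — plausibility defaults, not calibrated to any
  real population.
* `u_p ~ Normal(0, practice_sigma^2)` is the practice effect
  (default σ = 0.45, a regime that yields several-fold rate variation
  across 40 practices).
* `g(d) = decile_rate_ratio^((10 - d) / 9)` is log-linear in decile, so
  decile 1 (most deprived) over decile 10 equals `decile_rate_ratio`
  (default 2.0).
* Procedures are `procedure_fraction` (default 0.25) of expected activity.
  Their ages are drawn from a normal whose mean falls by
  `age_shift_years` (default 2.0) per deprivation step from
  `procedure_age_mean` (default 62, sd 12): decile-1 procedures centre on
  age 44, giving the 40s-vs-60s modal contrast and a mean gap of
  9 x `age_shift_years` ≈ 18 years.
* Each practice draws its decile composition as a discretised normal
  around a random centre (sd `decile_mix_sd` = 3 deciles). The recorded
  practice deprivation score is the register-weighted mean decile — by
  construction a *noisy* proxy for patient-level deprivation, which is why
  practice-level correlation analyses can be null even when a patient-level
  gradient exists.
* Register age structure is proportional to the adult ESP weights and the
  sex split is 50/50; patients are single-episode unless
  `repeat_episode_rate > 0`.

All draws flow from one seed through fixed named substreams (registers /
episodes / portfolio), so outputs are bit-reproducible and adding a
generator never perturbs the others.

What the generator does **not** emulate: secular trends or seasonality,
correlated comorbidity, within-practice clinician effects, migration
between practices, and any real coding noise. Tests passing on this
synthetic structure demonstrate that the *analysis machinery* is correct
and recovers injected signals; they say nothing about effect sizes in real
hospital data.

## Standardisation and intervals

Direct standardisation applies each unit's stratum rates to the 2013
European Standard Population (19 five-year bands summing to 100,000); the
2013 revision is the default because the analysis window post-dates it,
and any weights table can be substituted. The same band weight is applied
to both sexes, and weights are normalised internally, so only their
relative sizes matter. Ages 18–19 sit in the "15–19" band with its full
weight — the simplest defensible adult alignment. A stratum with events
but no person-years is a data-integrity error; an empty stratum is skipped
with a logged warning.

Intervals are 95% throughout. Crude proportions use the Wilson score
interval (statsmodels); standardised rates use the Dobson interval — the
exact Poisson limits of the total count, rescaled by
`sqrt(var(DSR) / var(O))` — which behaves well at the small counts typical
of practice-level analysis. Both choices are pinned by tests: Monte-Carlo
coverage at p = 0.01, n = 5,000 must land in 93–97%, and interval width
must scale as 1/sqrt(n) within 10%. The method used is recorded on every
rate and in output metadata.

Multi-year pooling sums event counts over the selected years and
multiplies register person-years by the number of years pooled (registers
held constant per year unless per-year registers are supplied).

## Variation and equity conventions

* Fold-variation uses the minimum *positive* rate as denominator;
  zero-rate practices are listed as excluded rather than silently imputed
  or allowed to produce an infinite ratio.
* The deprivation correlation defaults to Spearman's rank coefficient with
  no p-value: the claim under test is monotone association, and the
  observational design does not support a formal test by default (Pearson
  and an optional trend test are selectable).
* "First episode of care" means the earliest procedure within the loaded
  window (no look-back beyond it); ties within a patient's first year are
  broken by record order with a logged count.
* The age-deprivation matrix uses decade bands (18–29 … 80+) and
  column-normalises within deprivation group; IMD decile 1 is always the
  most deprived.
* No shrinkage or funnel-plot adjustment is applied to small practices;
  rates are reported raw with their intervals.

A note on confounding that the generator makes visible: with a strong
practice effect (σ = 0.45) and only 40 practices, the decile-1/decile-10
contrast is partly absorbed by *which* practices serve deprived
populations — a single realisation can show a gradient well away from the
injected value. Recovery tests therefore switch practice effects off when
measuring gradient recovery, and the equity analysis should be read the
same way on real data: practice and neighbourhood effects are entangled at
this scale.

## STAR computation

Triangle identities are exact: `Q = n x q`, `C = F + n x c`, slope
`Q / C` (flagged infinite when `C = 0` and `Q != 0`). Cost per QALY is
rounded to the nearest pound for reporting; all totals are kept unrounded
internally. The frontier sorts by slope descending with deterministic
tie-breaks (lower cost, then id); interventions with no positive QALY gain
are stacked last in evidence-category order (no evidence, no benefit,
possible harm), so the curve is concave over the value-bearing segment —
a property tested by brute force against all stacking orders for n ≤ 6.

Reallocation semantics: stopping fraction *f* of an intervention removes
`f` of its people, QALYs and variable spend from the portfolio, but only
`f x releasable_cost_fraction x variable_spend` becomes budget available
for reinvestment — fixed costs, and the non-releasable share of variable
costs, are savings that cannot be redeployed. In `released_only` mode the
post-plan spend equals the baseline spend minus unreleased savings,
exactly; in `fixed_envelope` mode the post-plan spend must match the
envelope within £1 or the plan is rejected as infeasible, with the
shortfall reported. Disinvested interventions in the shipped baseline
carry zero QALYs, consistent with a baseline QALY total that is unchanged
by stopping them.

The shipped 29-intervention baseline portfolio is **synthetic**: the real
service-level finance table is not public, so a stand-in is constructed to
reproduce its published margins exactly (17,225 people, £4.5M, 4,571
QALYs, categories 16/9/3/1, and £270,000 of variable spend across the
disinvestment candidates). Costs there are modelled as fully variable; the
portfolio reader equally accepts explicit fixed/variable splits.

## Problem sizes and numerical choices

Test and acceptance runs use sizes chosen to make Monte-Carlo bands
comfortable on a single CPU: gradient recovery uses one 2.4M person-year
cohort (≥10^5 person-years per decile, tolerance ±10%); fold-variation and
correlation nulls use 200 replicates of the 40-practice system (50 in the
acceptance script); interval coverage uses 2,000 binomial draws; frontier
dominance uses 100 random instances with n ≤ 6. The modal-decade gap is
reported as the median over three replicate cohorts because the
least-deprived group's 50s/60s mode is close enough for a single finite
cohort to flip it occasionally. The null CI-overlap check expects ≥85% of
practice intervals to cover the pooled rate (nominal 95% coverage across
40 practices leaves headroom for a handful of misses).

## Known limitations

* QALY-per-person values are inputs, not estimates; no uncertainty is
  propagated through them and no discounting is applied.
* `n_people` counts treatment courses: one person receiving two
  interventions counts twice unless patient-linked data is supplied.
* Person-time is approximated by register counts (no mid-year migration).
* The synthetic generator's defaults are plausibility choices for an
  English locality, not a calibration to any real population; absolute
  rates from it should not be quoted, only recovered *relative* structure.
* Indirect standardisation (SMRs) and funnel-plot control limits are not
  provided.
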