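# backvalue

Population value-improvement analysis for elective back-pain care, of the
kind an English integrated-care system runs over Hospital Episode
Statistics: between-practice variation in age-sex standardised rates,
deprivation-equity gradients, and STAR (Socio-Technical Allocation of
Resources) value-for-money analysis with budget-neutral reallocation.
Because patient-level hospital data is access-restricted, the package
ships a synthetic episode generator with the statistical structure the
analyses assume, so every stage is runnable and testable end to end.

It is a library for analysts and health-economics researchers, used from
Python (see `examples/`), with a thin `backvalue` CLI for the same
operations from a shell.

## What it computes

**Directly standardised rates.** For strata *s* = (age band, sex) with
events *e_s* and person-years *d_s*, the rate per 10,000 standardised to
weights *w_s* (2013 European Standard Population by default) is

    DSR = 10,000 x Σ_s w_s (e_s / d_s) / Σ_s w_s

with Wilson 95% intervals for crude proportions and Dobson intervals
(anchored on the exact Poisson limits of the total count) for standardised
rates. Multi-year pooling sums counts and person-years.

**Variation and equity.** Fold-variation = max/min positive practice DSR
(zero-rate practices excluded and listed); Spearman correlation of practice
rates with practice deprivation scores; standardised procedure rates per
IMD decile of patient residence (decile 1 = most deprived); and the
column-normalised age distribution of each deprivation group's first
procedures, with modal age bands.

**STAR.** Each intervention *i* is a value-for-money triangle: QALY gain
`Q_i = n_i x q_i`, cost `C_i = F_i + n_i x c_i`, slope `Q_i / C_i`.
Triangles stacked in slope order, steepest first, form the efficiency
frontier; a reallocation plan stops fractions of low-value interventions,
releases the releasable share of their variable spend, and reinvests it,
with budget neutrality enforced to £1.

## Worked example

```sh
python examples/04_value_reallocation.py
```

prints

```
baseline: 29 interventions, 17,225 people, £4.5M, 4,571 QALYs
evidence categories: {'benefit': 16, 'no_evidence': 9, 'no_benefit': 3, 'possible_harm': 1}

reinvestment candidates (cost per QALY, £):
  digital_support      n=10,000  £  20,000     700 QALYs  £29/QALY
  back_pain_classes    n= 3,000  £ 150,000   2,010 QALYs  £75/QALY
  case_management      n=   200  £ 100,000     380 QALYs  £263/QALY
  TOTAL invested £270,000 -> 3,090 QALYs

after reallocation: 7,661 QALYs (+68%) within £4.5M — the same spend buys 3,090 extra QALYs.
```

The baseline portfolio (synthetic, constructed to the published margins)
gains 4,571 QALYs for £4.5M. Stopping the zero-QALY interventions —
imaging outside guidelines and injections with no evidence of benefit —
releases £270,000 of variable spend, which reinvested at £29–£263 per QALY
buys 3,090 QALYs: a 67.6% gain at constant spend.

`examples/02_standardised_rates_variation.py` shows the variation side: a
several-fold spread in standardised practice rates, widening as years are
pooled and CIs narrow, with only a weak correlation to practice
deprivation. `examples/03_deprivation_equity.py` shows the equity side:
higher procedure rates in more-deprived deciles and a modal age at first
procedure in the 40s for the most deprived against the 60s for the least.

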