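"""Crude and directly age-sex standardised rates per 10,000 with 95% CIs.

Direct standardisation weights stratum-specific rates by a standard
population's stratum weights; the default standard is the 2013 European
Standard Population (ESP), with the same band weight applied to each sex.
Rates are expressed per 10,000 population, the conventional scale for
small-area hospital-activity comparisons.

Confidence intervals: crude proportions use the Wilson score interval
(via statsmodels); standardised rates use the Dobson method, which anchors
the interval on the exact Poisson limits of the total observed count and
rescales by the ratio of the standardised-rate variance to the count
variance.  The method used is recorded on each result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.proportion import proportion_confint

from . import bands as _bands
from .errors import DataIntegrityError, InputError

__all__ = [
    "StandardPopulation",
    "StandardisedRate",
    "ESP_2013",
    "esp_weights_for",
    "crude_rate",
    "rate_ci",
    "direct_standardised_rate",
    "pool_years",
]

log = logging.getLogger(__name__)

PER = 10_000.0  # reporting scale


@dataclass(frozen=True)
class StandardPopulation:
    """A reference age distribution: band label -> weight (persons)."""

    name: str
    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        bad = [b for b, w in self.weights.items() if w <= 0]
        if bad:
            raise InputError(f"standard population {self.name!r}: "
                             f"non-positive weight for band(s) {bad}")


#: 2013 European Standard Population, 19 five-year bands totalling 100,000.
ESP_2013 = StandardPopulation("ESP2013", {
    "0-4": 5000, "5-9": 5500, "10-14": 5500, "15-19": 5500,
    "20-24": 6000, "25-29": 6000, "30-34": 6500, "35-39": 7000,
    "40-44": 7000, "45-49": 7000, "50-54": 7000, "55-59": 6500,
    "60-64": 6000, "65-69": 5500, "70-74": 5000, "75-79": 4000,
    "80-84": 2500, "85-89": 1500, "90+": 1000,
})


def esp_weights_for(age_bands: Iterable[str]) -> StandardPopulation:
    """ESP 2013 restricted to the given bands (e.g. the adult bands)."""
    missing = [b for b in age_bands if b not in ESP_2013.weights]
    if missing:
        raise InputError(f"bands not in ESP 2013: {missing}")
    return StandardPopulation(
        "ESP2013", {b: ESP_2013.weights[b] for b in age_bands}
    )


@dataclass(frozen=True)
class StandardisedRate:
    """A rate per 10,000 with its 95% CI, event count and denominator."""

    unit_id: str | None
    rate: float
    ci_low: float
    ci_high: float
    n_events: int
    denominator: float
    ci_method: str = "dobson"

    def __post_init__(self) -> None:
        if self.denominator <= 0:
            raise InputError("StandardisedRate: denominator must be positive")
        if not (0 <= self.ci_low <= self.rate <= self.ci_high):
            raise InputError(
                f"StandardisedRate: CI must bracket the rate "
                f"({self.ci_low}, {self.rate}, {self.ci_high})"
            )


def crude_rate(n_events: int, denominator: float) -> float:
    """Events per 10,000 person-years: ``10000 * n / d``."""
    if denominator <= 0:
        raise InputError(f"denominator must be positive, got {denominator}")
    if n_events < 0:
        raise InputError(f"n_events must be non-negative, got {n_events}")
    return PER * n_events / denominator


def _poisson_limits(n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (chi-square) limits for a Poisson count."""
    lo = 0.0 if n == 0 else chi2.ppf(alpha / 2, 2 * n) / 2.0
    hi = chi2.ppf(1 - alpha / 2, 2 * n + 2) / 2.0
    return lo, hi


def rate_ci(
    n_events: int,
    denominator: float,
    standardised: bool = False,
    stratum_events: Mapping | None = None,
    stratum_denoms: Mapping | None = None,
    std: StandardPopulation | None = None,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """95% interval for a rate per 10,000.

    Crude rates get a Wilson score interval on the event proportion,
    rescaled to per-10,000.  Standardised rates get the Dobson interval and
    require the stratum detail (events, denominators and the standard) used
    to compute the rate.  The lower bound is 0 when ``n_events == 0``.
    """
    if denominator <= 0:
        raise InputError(f"denominator must be positive, got {denominator}")
    if not standardised:
        lo, hi = proportion_confint(n_events, denominator, alpha=alpha,
                                    method="wilson")
        # Wilson's lower root is exactly 0 at zero events; clear float noise
        return (0.0 if n_events == 0 else float(lo) * PER), float(hi) * PER

    if stratum_events is None or stratum_denoms is None or std is None:
        raise InputError("standardised CI needs stratum_events, "
                         "stratum_denoms and std")
    w, e, d = _aligned_strata(stratum_events, stratum_denoms, std)
    wsum = w.sum()
    dsr = float((w * e / d).sum() / wsum)          # per person-year
    var = float((w**2 * e / d**2).sum() / wsum**2)
    O = int(e.sum())
    o_lo, o_hi = _poisson_limits(O, alpha)
    if O == 0:
        # no events anywhere: fall back on the Poisson upper bound spread
        # over the total person-years
        return 0.0, PER * o_hi / float(d.sum())
    scale = np.sqrt(var / O)
    lo = max(0.0, dsr + scale * (o_lo - O))
    hi = dsr + scale * (o_hi - O)
    return PER * lo, PER * hi


def _stratum_weight(std: StandardPopulation, key) -> float:
    band = key[0] if isinstance(key, tuple) else key
    if band not in std.weights:
        raise InputError(f"standard population {std.name!r} does not cover "
                         f"band {band!r}")
    return float(std.weights[band])


def _aligned_strata(
    stratum_events: Mapping, stratum_denoms: Mapping, std: StandardPopulation
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Align events/denominators over strata, applying the zero-handling
    rules: events without a denominator is a data-integrity error; an empty
    stratum (0 events, 0 person-years) is skipped with a warning."""
    keys, w, e, d = [], [], [], []
    all_keys = set(stratum_events) | set(stratum_denoms)
    for key in sorted(all_keys, key=str):
        ev = float(stratum_events.get(key, 0))
        den = float(stratum_denoms.get(key, 0))
        if den <= 0:
            if ev > 0:
                raise DataIntegrityError(
                    f"stratum {key!r} has {ev:g} events but no person-years"
                )
            log.warning("skipping empty stratum %r (no events, no denominator)",
                        key)
            continue
        keys.append(key)
        w.append(_stratum_weight(std, key))
        e.append(ev)
        d.append(den)
    if not keys:
        raise InputError("no non-empty strata to standardise")
    return np.array(w), np.array(e), np.array(d)


def direct_standardised_rate(
    stratum_events: Mapping,
    stratum_denoms: Mapping,
    std: StandardPopulation = ESP_2013,
    unit_id: str | None = None,
    alpha: float = 0.05,
) -> StandardisedRate:
    """ESP-weighted direct standardisation with a Dobson 95% CI.

    ``rate = 10000 * sum_s(w_s * e_s / d_s) / sum_s(w_s)`` where strata are
    (age band, sex) keys; the band's ESP weight applies identically to both
    sexes.  Weights are normalised internally, so their absolute scale is
    irrelevant.
    """
    w, e, d = _aligned_strata(stratum_events, stratum_denoms, std)
    rate = PER * float((w * e / d).sum() / w.sum())
    lo, hi = rate_ci(
        int(e.sum()), float(d.sum()), standardised=True,
        stratum_events=stratum_events, stratum_denoms=stratum_denoms,
        std=std, alpha=alpha,
    )
    return StandardisedRate(
        unit_id=unit_id, rate=rate, ci_low=min(lo, rate),
        ci_high=max(hi, rate), n_events=int(e.sum()),
        denominator=float(d.sum()), ci_method="dobson",
    )


def pool_years(
    episodes: pd.DataFrame,
    registers: pd.DataFrame,
    years: Iterable[str] | None = None,
    event_class: str = "all",
    by: str | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Pool episode counts and person-years over fiscal years.

    Counts are summed over the selected years; person-years are the register
    counts multiplied by the number of years pooled (registers are held
    constant per year).  Returns ``(events, person_years)`` indexed by
    (age_band, sex), prefixed by the grouping unit when ``by`` is
    ``"practice"`` or ``"decile"``.
    """
    present = set(episodes["fiscal_year"].unique())
    if years is None:
        years = sorted(present)
    years = list(years)
    if not years:
        raise InputError("years: empty selection")
    unknown = [y for y in years if y not in present]
    if unknown:
        raise InputError(f"unknown fiscal year label(s): {unknown}")

    eps = episodes[episodes["fiscal_year"].isin(years)]
    if event_class != "all":
        if event_class not in ("attendance", "procedure"):
            raise InputError(f"event_class must be all|attendance|procedure, "
                             f"got {event_class!r}")
        eps = eps[eps["event_class"] == event_class]

    band_order = _register_band_order(registers)
    eps = eps.assign(age_band=_bands.assign_bands(eps["age"].to_numpy(),
                                                  band_order))
    unit_col = {"practice": "practice_id", "decile": "imd_decile",
                None: None}.get(by, "invalid")
    if unit_col == "invalid":
        raise InputError(f"by must be practice|decile|None, got {by!r}")

    group = ([unit_col] if unit_col else []) + ["age_band", "sex"]
    events = eps.groupby(group, observed=True).size().astype(int)
    py = registers.groupby(group, observed=True)["count"].sum().astype(float) \
        * len(years)
    return events, py


def _register_band_order(registers: pd.DataFrame) -> list[str]:
    seen = list(dict.fromkeys(registers["age_band"]))
    return sorted(seen, key=lambda b: _bands.parse_band(b)[0])
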