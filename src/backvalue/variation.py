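"""Between-practice variation in standardised rates.

"Unwarranted variation" is proxied by the fold-variation — the ratio of the
highest to the lowest positive age-sex standardised rate across general
practices — together with its (lack of) association with practice-level
deprivation.  Zero-rate practices cannot meaningfully enter a ratio and are
excluded from the fold denominator but listed explicitly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .errors import DataIntegrityError, InputError
from .standardise import (
    StandardPopulation,
    StandardisedRate,
    direct_standardised_rate,
    esp_weights_for,
    pool_years,
)

__all__ = [
    "VariationSummary",
    "CorrelationResult",
    "practice_rates",
    "fold_variation",
    "deprivation_correlation",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationResult:
    coefficient: float  # NaN when undefined
    method: str
    note: str = ""


@dataclass(frozen=True)
class VariationSummary:
    n_units: int
    min_rate: float
    max_rate: float
    fold_variation: float
    excluded_units: tuple[str, ...] = ()
    deprivation_correlation: CorrelationResult | None = None
    note: str = ""


def _default_std(registers: pd.DataFrame) -> StandardPopulation:
    from .standardise import _register_band_order

    return esp_weights_for(_register_band_order(registers))


def practice_rates(
    episodes: pd.DataFrame,
    registers: pd.DataFrame,
    std: StandardPopulation | None = None,
    years: Iterable[str] | None = None,
    event_class: str = "all",
) -> list[StandardisedRate]:
    """One age-sex standardised rate per practice, sorted descending
    (bar-chart order).  Every practice in the registers appears, including
    those with zero events in the selected window."""
    known = set(registers["practice_id"].unique())
    unknown = set(episodes["practice_id"].unique()) - known
    if unknown:
        raise DataIntegrityError(
            f"episodes reference practice(s) absent from registers: "
            f"{sorted(unknown)}"
        )
    std = std or _default_std(registers)
    events, py = pool_years(episodes, registers, years=years,
                            event_class=event_class, by="practice")
    out = []
    for pid in sorted(known):
        denoms = {k[1:]: v for k, v in py.items() if k[0] == pid}
        evs = {k[1:]: v for k, v in events.items() if k[0] == pid}
        out.append(direct_standardised_rate(evs, denoms, std, unit_id=pid))
    return sorted(out, key=lambda r: (-r.rate, r.unit_id))


def fold_variation(rates: Sequence[StandardisedRate]) -> VariationSummary:
    """Max over min positive standardised rate across units.

    Zero-rate units are excluded from the denominator and listed in
    ``excluded_units``.  A single unit, or all-zero rates, yields a fold of
    1 / NaN respectively, flagged in ``note``.
    """
    if not rates:
        raise InputError("fold_variation: no rates supplied")
    positive = [r for r in rates if r.rate > 0]
    excluded = tuple(str(r.unit_id) for r in rates if r.rate == 0)
    if excluded:
        log.info("fold_variation: %d zero-rate unit(s) excluded: %s",
                 len(excluded), ", ".join(excluded))
    if not positive:
        return VariationSummary(
            n_units=len(rates), min_rate=0.0, max_rate=0.0,
            fold_variation=math.nan, excluded_units=excluded,
            note="no events: fold undefined",
        )
    mx = max(r.rate for r in positive)
    mn = min(r.rate for r in positive)
    note = "single unit: fold reported as 1" if len(positive) == 1 else ""
    return VariationSummary(
        n_units=len(rates), min_rate=mn, max_rate=mx,
        fold_variation=mx / mn if len(positive) > 1 else 1.0,
        excluded_units=excluded, note=note,
    )


def deprivation_correlation(
    rates: Sequence[StandardisedRate],
    registers: pd.DataFrame,
    method: str = "spearman",
) -> CorrelationResult:
    """Correlation between practice standardised rate and practice
    deprivation score (register-weighted mean decile; lower = more
    deprived).  Spearman by default — the relationship need not be linear;
    no p-value is attached."""
    scores = (
        registers[["practice_id", "deprivation_score"]]
        .drop_duplicates("practice_id")
        .set_index("practice_id")["deprivation_score"]
    )
    missing = [r.unit_id for r in rates if r.unit_id not in scores.index]
    if missing:
        raise InputError(f"no deprivation score for practice(s): {missing}")
    x = [float(scores[r.unit_id]) for r in rates]
    y = [r.rate for r in rates]
    if len(set(x)) < 2 or len(set(y)) < 2:
        return CorrelationResult(math.nan, method,
                                 note="constant input: correlation undefined")
    if method == "spearman":
        coef = stats.spearmanr(x, y).statistic
    elif method == "pearson":
        coef = stats.pearsonr(x, y).statistic
    else:
        raise InputError(f"method must be spearman|pearson, got {method!r}")
    return CorrelationResult(float(coef), method)
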