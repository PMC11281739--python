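"""Deprivation-equity analyses of procedure activity.

Two views of the same question — who gets a back-pain procedure, and when
in life:

* standardised procedure rates per IMD decile of patient residence
  (decile 1 = most deprived), and
* the age distribution of each deprivation group's *first* procedures,
  column-normalised to percentages with the modal age band highlighted.

The headline pattern in deprived populations is both a higher procedure
rate and a markedly younger age at first procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import bands as _bands
from .errors import InputError
from .standardise import (
    StandardPopulation,
    StandardisedRate,
    direct_standardised_rate,
    esp_weights_for,
    pool_years,
)

__all__ = [
    "AgeDeprivationMatrix",
    "DECADE_BANDS",
    "decile_rates",
    "first_procedure_per_patient",
    "age_deprivation_matrix",
]

log = logging.getLogger(__name__)

#: Decade bands for the age-by-deprivation table ("in their 40s" etc.).
DECADE_BANDS: tuple[str, ...] = (
    "18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80+",
)


@dataclass(frozen=True)
class AgeDeprivationMatrix:
    """Column-normalised percentage of first procedures by age band
    (rows) and deprivation group (columns), plus each group's modal band."""

    cells: pd.DataFrame
    modal_band: dict
    grouping: str
    empty_groups: tuple = ()

    def modal_gap_decades(self) -> int:
        """Modal-band gap (in row steps) between the most- and
        least-deprived non-empty groups."""
        groups = [g for g in self.cells.columns if g not in self.empty_groups]
        if len(groups) < 2:
            return 0
        lo, hi = groups[0], groups[-1]
        rows = list(self.cells.index)
        return rows.index(self.modal_band[hi]) - rows.index(self.modal_band[lo])


def _check_deciles(values: Iterable[int], what: str) -> None:
    bad = sorted({int(v) for v in values} - set(range(1, 11)))
    if bad:
        raise InputError(f"{what}: IMD decile(s) outside 1..10: {bad}")


def decile_rates(
    episodes: pd.DataFrame,
    decile_denominators: pd.DataFrame,
    std: StandardPopulation | None = None,
    years: Iterable[str] | None = None,
) -> list[StandardisedRate]:
    """One age-sex standardised *procedure* rate per IMD decile 1..10.

    ``decile_denominators`` is any register-style frame with columns
    ``imd_decile, age_band, sex, count`` (the practice-level synthetic
    registers qualify and are aggregated over practices).
    """
    _check_deciles(episodes["imd_decile"], "episodes")
    _check_deciles(decile_denominators["imd_decile"], "denominators")
    if std is None:
        from .standardise import _register_band_order

        std = esp_weights_for(_register_band_order(decile_denominators))
    events, py = pool_years(episodes, decile_denominators, years=years,
                            event_class="procedure", by="decile")
    out = []
    for d in range(1, 11):
        denoms = {k[1:]: v for k, v in py.items() if k[0] == d}
        evs = {k[1:]: v for k, v in events.items() if k[0] == d}
        if not denoms:
            raise InputError(f"no denominators for IMD decile {d}")
        out.append(direct_standardised_rate(evs, denoms, std, unit_id=str(d)))
    return out


def first_procedure_per_patient(episodes: pd.DataFrame) -> pd.DataFrame:
    """Earliest procedure episode per patient within the loaded window.

    Ordering is by fiscal-year label then original record order; the number
    of patients whose first year contained multiple procedures (ties broken
    by record order) is logged.
    """
    procs = episodes[episodes["event_class"] == "procedure"]
    if procs.empty:
        return procs.copy()
    ordered = procs.sort_values(
        ["patient_id", "fiscal_year"], kind="stable"
    ).reset_index(drop=False)
    first = ordered.drop_duplicates("patient_id", keep="first")
    first_year = first.set_index("patient_id")["fiscal_year"]
    in_first_year = ordered["fiscal_year"].eq(
        ordered["patient_id"].map(first_year)
    )
    n_ties = int((ordered[in_first_year].groupby("patient_id").size() > 1).sum())
    if n_ties:
        log.info("first_procedure_per_patient: %d patient(s) had multiple "
                 "procedures in their first year; earliest record kept", n_ties)
    return first.set_index("index").sort_index().rename_axis(None)


def _group_deciles(deciles: np.ndarray, grouping: str) -> np.ndarray:
    if grouping == "decile":
        return deciles
    if grouping == "quintile":
        return (deciles + 1) // 2
    raise InputError(f"deprivation_grouping must be decile|quintile, "
                     f"got {grouping!r}")


def age_deprivation_matrix(
    first_episodes: pd.DataFrame,
    age_bands: Sequence[str] = DECADE_BANDS,
    deprivation_grouping: str = "decile",
) -> AgeDeprivationMatrix:
    """Percentage of each deprivation group's first procedures by age band.

    Columns are deprivation groups ordered most- to least-deprived and each
    sums to 100% (empty groups are flagged, not errored).  ``modal_band``
    records each group's most common age band.
    """
    _check_deciles(first_episodes["imd_decile"], "first_episodes")
    n_groups = 10 if deprivation_grouping == "decile" else 5
    groups = _group_deciles(first_episodes["imd_decile"].to_numpy(),
                            deprivation_grouping)
    bands = _bands.assign_bands(first_episodes["age"].to_numpy(), age_bands)
    counts = (
        pd.crosstab(pd.Series(bands, name="age_band"),
                    pd.Series(groups, name="group"))
        .reindex(index=list(age_bands), columns=range(1, n_groups + 1),
                 fill_value=0)
    )
    totals = counts.sum(axis=0)
    empty = tuple(int(g) for g in totals.index[totals == 0])
    if empty:
        log.warning("age_deprivation_matrix: empty deprivation group(s) %s",
                    empty)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = counts / totals * 100.0
    modal = {
        int(g): (counts[g].idxmax() if totals[g] > 0 else None)
        for g in counts.columns
    }
    return AgeDeprivationMatrix(cells=pct, modal_band=modal,
                                grouping=deprivation_grouping,
                                empty_groups=empty)
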