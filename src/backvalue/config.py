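"""Simulation configuration.

:class:`SimulationConfig` collects every knob of the synthetic
hospital-episode generator.  Defaults describe a mid-sized English
commissioning area: 40 general practices observed over five fiscal years,
with between-practice variation on the log-rate scale, a deprivation rate
gradient across IMD deciles (decile 1 = most deprived), and a
deprivation-dependent downward shift in age at procedure.
"""

from __future__ import annotations

import math
from typing import Literal

import pydantic
from pydantic import BaseModel, Field, model_validator

from . import bands as _bands
from .errors import ConfigurationError

#: Default adult age bands, aligned with the five-year bands of the 2013
#: European Standard Population.  Ages 18-19 fall in the "15-19" band.
DEFAULT_AGE_BANDS: tuple[str, ...] = (
    "15-19", "20-24", "25-29", "30-34", "35-39", "40-44", "45-49",
    "50-54", "55-59", "60-64", "65-69", "70-74", "75-79", "80-84",
    "85-89", "90+",
)

DEFAULT_YEARS: tuple[str, ...] = (
    "2015/16", "2016/17", "2017/18", "2018/19", "2019/20",
)

EVIDENCE_CATEGORIES = ("benefit", "no_evidence", "no_benefit", "possible_harm")


def default_age_sex_multipliers(
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS,
) -> dict[str, dict[str, float]]:
    """Plausible adult age-sex rate multipliers for elective back-pain care.

    A smooth hump peaking around age 62 (elective spinal activity is
    concentrated in late working age and early retirement), with a modestly
    higher female rate.  The reference stratum (multiplier 1.0) is the peak
    male band.  These are plausibility defaults, not calibrated values.
    """
    out: dict[str, dict[str, float]] = {}
    for band in age_bands:
        mid = _bands.band_midpoint(band)
        shape = math.exp(-(((mid - 62.0) / 24.0) ** 2))
        out[band] = {"M": round(shape, 4), "F": round(1.1 * shape, 4)}
    return out


class PortfolioRow(BaseModel):
    """One row of the intervention portfolio specification."""

    name: str
    n_treated: int = Field(ge=0)
    fixed_cost: float = Field(ge=0.0)
    variable_cost_per_person: float = Field(ge=0.0)
    qaly_per_person: float  # may be zero or negative (possible harm)
    evidence_category: Literal[
        "benefit", "no_evidence", "no_benefit", "possible_harm"
    ] = "benefit"


def default_portfolio_spec() -> list[PortfolioRow]:
    """The three candidate reinvestment interventions of the worked example:
    digital support, community back-pain classes, and case management for
    complex back pain."""
    return [
        PortfolioRow(name="digital_support", n_treated=10_000, fixed_cost=0.0,
                     variable_cost_per_person=2.0, qaly_per_person=0.07),
        PortfolioRow(name="back_pain_classes", n_treated=3_000, fixed_cost=0.0,
                     variable_cost_per_person=50.0, qaly_per_person=0.67),
        PortfolioRow(name="case_management", n_treated=200, fixed_cost=0.0,
                     variable_cost_per_person=500.0, qaly_per_person=1.90),
    ]


class SimulationConfig(BaseModel):
    """Parameters of the synthetic register/episode/portfolio generator.

    Rates are events per person-year in the reference stratum (peak male
    band, least-deprived decile, practice effect zero).  `decile_rate_ratio`
    is the rate ratio of decile 1 (most deprived) over decile 10;
    `age_shift_years` is the mean reduction in age at procedure per one-step
    increase in deprivation (so the decile-1 vs decile-10 mean-age gap is
    nine times this value).
    """

    model_config = pydantic.ConfigDict(validate_assignment=True)

    seed: int = 0
    n_practices: int = Field(default=40, gt=0)
    years: tuple[str, ...] = DEFAULT_YEARS
    age_bands: tuple[str, ...] = DEFAULT_AGE_BANDS
    base_rate: float = Field(default=0.03, gt=0.0)
    age_sex_multipliers: dict[str, dict[str, float]] | None = None
    practice_sigma: float = Field(default=0.45, ge=0.0)
    decile_rate_ratio: float = Field(default=2.0, ge=1.0)
    age_shift_years: float = Field(default=2.0, ge=0.0)
    register_size_range: tuple[int, int] = (4_000, 12_000)
    procedure_fraction: float = Field(default=0.25, ge=0.0, le=1.0)
    portfolio_spec: list[PortfolioRow] = Field(
        default_factory=default_portfolio_spec
    )
    # Secondary generator knobs ------------------------------------------
    #: sd (in decile units) of each practice's decile mixture around its
    #: centre; larger values make practice deprivation score a noisier
    #: proxy for patient deprivation.
    decile_mix_sd: float = Field(default=3.0, gt=0.0)
    #: mean age at procedure in the least-deprived decile, and its sd.
    procedure_age_mean: float = Field(default=62.0, gt=18.0)
    procedure_age_sd: float = Field(default=12.0, gt=0.0)
    #: expected extra (repeat) episodes per patient; 0 = single-episode.
    repeat_episode_rate: float = Field(default=0.0, ge=0.0)

    @model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        try:
            _bands.validate_bands(self.age_bands)
        except ConfigurationError:
            raise
        if not self.years:
            raise ConfigurationError("years: at least one fiscal year required")
        lo, hi = self.register_size_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(
                f"register_size_range: need 0 < min <= max, got ({lo}, {hi})"
            )
        if self.age_sex_multipliers is not None:
            for band in self.age_bands:
                if band not in self.age_sex_multipliers:
                    raise ConfigurationError(
                        f"age_sex_multipliers: missing band {band!r}"
                    )
                for sex in ("F", "M"):
                    if sex not in self.age_sex_multipliers[band]:
                        raise ConfigurationError(
                            f"age_sex_multipliers: band {band!r} missing sex {sex!r}"
                        )
        return self

    def multipliers(self) -> dict[str, dict[str, float]]:
        """Resolved age-sex multipliers (defaults filled in)."""
        if self.age_sex_multipliers is not None:
            return self.age_sex_multipliers
        return default_age_sex_multipliers(self.age_bands)
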