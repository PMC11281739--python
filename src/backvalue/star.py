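"""STAR (Socio-Technical Allocation of Resources) value computation.

Each intervention is summarised as a value-for-money triangle: population
QALY gain (number treated x mean QALY gain per person) on the vertical
axis, total cost (fixed + number treated x variable cost per person) on
the horizontal, and value for money as the slope of the hypotenuse.
Triangles stacked in slope order, steepest first, form the efficiency
frontier.  A reallocation plan stops or scales down low-value
interventions, releases the releasable share of their variable spend, and
reinvests it in higher-value interventions within a budget envelope.

Arithmetic identities (total cost, total QALYs, cumulative sums, budget
conservation) hold exactly at the pound/QALY scales used here.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

from .errors import InputError, PlanInfeasibleError

__all__ = [
    "Intervention",
    "ValueTriangle",
    "FrontierPoint",
    "Disinvestment",
    "ReallocationPlan",
    "PortfolioSummary",
    "EVIDENCE_CATEGORIES",
    "value_triangle",
    "cost_per_qaly",
    "build_frontier",
    "portfolio_summary",
    "apply_reallocation",
    "default_reallocation_plan",
]

log = logging.getLogger(__name__)

EVIDENCE_CATEGORIES = ("benefit", "no_evidence", "no_benefit", "possible_harm")
#: Placement order, after all positive-value triangles, on the frontier.
_TAIL_ORDER = {"no_evidence": 0, "no_benefit": 1, "possible_harm": 2,
               "benefit": 0}


@dataclass(frozen=True)
class Intervention:
    """A portfolio entry: who is treated, at what cost, for what gain."""

    id: str
    name: str
    n_treated: float
    fixed_cost: float
    variable_cost_per_person: float
    qaly_per_person: float
    evidence_category: str = "benefit"
    provider: str | None = None

    def __post_init__(self) -> None:
        if self.n_treated < 0:
            raise InputError(f"{self.id}: n_treated must be >= 0")
        if self.fixed_cost < 0 or self.variable_cost_per_person < 0:
            raise InputError(f"{self.id}: costs must be >= 0")
        if self.evidence_category not in EVIDENCE_CATEGORIES:
            raise InputError(
                f"{self.id}: evidence_category {self.evidence_category!r} "
                f"not in {EVIDENCE_CATEGORIES}"
            )

    @property
    def total_cost(self) -> float:
        return self.fixed_cost + self.n_treated * self.variable_cost_per_person

    @property
    def variable_cost(self) -> float:
        return self.n_treated * self.variable_cost_per_person

    @property
    def total_qaly(self) -> float:
        return self.n_treated * self.qaly_per_person


@dataclass(frozen=True)
class ValueTriangle:
    intervention_id: str
    total_cost: float
    total_qaly: float
    slope: float  # QALYs per pound; inf flagged when cost is 0


@dataclass(frozen=True)
class FrontierPoint:
    rank: int
    intervention_id: str
    cumulative_cost: float
    cumulative_qaly: float


@dataclass(frozen=True)
class Disinvestment:
    intervention_id: str
    fraction_stopped: float
    releasable_cost_fraction: float

    def __post_init__(self) -> None:
        for name in ("fraction_stopped", "releasable_cost_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{self.intervention_id}: {name} must be "
                                 f"in [0, 1], got {v}")


@dataclass(frozen=True)
class ReallocationPlan:
    disinvestments: tuple[Disinvestment, ...] = ()
    reinvestments: tuple[Intervention, ...] = ()
    budget_mode: Literal["released_only", "fixed_envelope"] = "released_only"
    envelope: float | None = None  # pounds, fixed_envelope mode only

    def __post_init__(self) -> None:
        if self.budget_mode == "fixed_envelope" and self.envelope is None:
            raise InputError("fixed_envelope mode requires an envelope (£)")


@dataclass(frozen=True)
class PortfolioSummary:
    n_interventions: int
    n_people: float  # treatment-course counting: sum of n_treated
    total_cost: float
    total_qaly: float
    category_counts: dict


def value_triangle(iv: Intervention) -> ValueTriangle:
    """The value-for-money triangle of one intervention."""
    cost, qaly = iv.total_cost, iv.total_qaly
    if cost > 0:
        slope = qaly / cost
    elif qaly != 0:
        log.warning("value_triangle: %s has zero cost but %g QALYs; "
                    "slope flagged infinite", iv.id, qaly)
        slope = math.inf
    else:
        slope = 0.0
    return ValueTriangle(iv.id, cost, qaly, slope)


def cost_per_qaly(iv: Intervention) -> int | None:
    """Total cost over total QALY gain, rounded to the nearest pound;
    None (not applicable) when the intervention yields no QALYs."""
    if iv.total_qaly <= 0:
        return None
    return round(iv.total_cost / iv.total_qaly)


def build_frontier(
    triangles: Sequence[ValueTriangle],
    categories: dict | None = None,
) -> list[FrontierPoint]:
    """Stack triangles in slope order, steepest first.

    Ties break on lower cost, then id.  Triangles with no positive QALY
    gain go last; when evidence categories are supplied they order that
    tail (no evidence, then no benefit, then possible harm).
    """
    if not triangles:
        raise InputError("build_frontier: no triangles")
    categories = categories or {}

    def key(t: ValueTriangle):
        positive = t.total_qaly > 0
        tail = _TAIL_ORDER.get(categories.get(t.intervention_id, "benefit"), 0)
        return (
            0 if positive else 1,
            tail if not positive else 0,
            -t.slope if positive else -t.slope,
            t.total_cost,
            t.intervention_id,
        )

    out, c, q = [], 0.0, 0.0
    for rank, t in enumerate(sorted(triangles, key=key), start=1):
        c += t.total_cost
        q += t.total_qaly
        out.append(FrontierPoint(rank, t.intervention_id, c, q))
    return out


def portfolio_summary(portfolio: Sequence[Intervention]) -> PortfolioSummary:
    """Totals across the portfolio.  ``n_people`` counts treatment courses
    (one person receiving two interventions counts twice)."""
    ids = [iv.id for iv in portfolio]
    dupes = sorted({i for i in ids if ids.count(i) > 1})
    if dupes:
        raise InputError(f"duplicate intervention id(s): {dupes}")
    counts = {c: 0 for c in EVIDENCE_CATEGORIES}
    for iv in portfolio:
        counts[iv.evidence_category] += 1
    return PortfolioSummary(
        n_interventions=len(portfolio),
        n_people=sum(iv.n_treated for iv in portfolio),
        total_cost=sum(iv.total_cost for iv in portfolio),
        total_qaly=sum(iv.total_qaly for iv in portfolio),
        category_counts=counts,
    )


def apply_reallocation(
    baseline: Sequence[Intervention],
    plan: ReallocationPlan,
    tolerance: float = 1.0,
) -> tuple[list[Intervention], PortfolioSummary, dict]:
    """Evaluate a budget-neutral reallocation plan.

    Stopping fraction ``f`` of an intervention removes ``f`` of its
    variable spend (and of its QALYs and people) from the portfolio; only
    ``f * releasable_cost_fraction * variable_cost`` becomes budget
    available for reinvestment — fixed costs, and the non-releasable share
    of variable costs, are savings that cannot be redeployed.  In
    ``fixed_envelope`` mode the post-plan spend must match the envelope to
    within ``tolerance`` pounds.

    Returns the new portfolio, its summary, and a deltas dict (absolute and
    percentage change in QALYs and people, plus the budget ledger).
    """
    before = portfolio_summary(baseline)
    by_id = {iv.id: iv for iv in baseline}
    unknown = [d.intervention_id for d in plan.disinvestments
               if d.intervention_id not in by_id]
    if unknown:
        raise InputError(f"disinvestment id(s) not in baseline: {unknown}")

    released = 0.0
    unreleased = 0.0
    new_portfolio: list[Intervention] = []
    stopped = {d.intervention_id: d for d in plan.disinvestments}
    for iv in baseline:
        d = stopped.get(iv.id)
        if d is None:
            new_portfolio.append(iv)
            continue
        f = d.fraction_stopped
        released += f * d.releasable_cost_fraction * iv.variable_cost
        unreleased += f * (1.0 - d.releasable_cost_fraction) * iv.variable_cost
        kept = replace(iv, n_treated=iv.n_treated * (1.0 - f))
        if kept.n_treated > 0 or kept.fixed_cost > 0:
            new_portfolio.append(kept)

    reinvest_spend = sum(iv.total_cost for iv in plan.reinvestments)
    if plan.budget_mode == "released_only":
        available = released
    else:
        spend_after_disinvest = sum(iv.total_cost for iv in new_portfolio)
        available = plan.envelope - spend_after_disinvest
    if reinvest_spend > available + tolerance:
        raise PlanInfeasibleError(
            f"reinvestment spend £{reinvest_spend:,.0f} exceeds available "
            f"budget £{available:,.0f} by £{reinvest_spend - available:,.0f}"
        )
    new_portfolio.extend(plan.reinvestments)
    after = portfolio_summary(new_portfolio)

    if plan.budget_mode == "fixed_envelope":
        imbalance = after.total_cost - plan.envelope
        if abs(imbalance) > tolerance:
            raise PlanInfeasibleError(
                f"post-plan spend £{after.total_cost:,.0f} misses the "
                f"envelope £{plan.envelope:,.0f} by £{imbalance:,.0f}"
            )

    def _pct(new: float, old: float) -> float:
        return math.nan if old == 0 else 100.0 * (new - old) / old

    deltas = {
        "qaly_before": before.total_qaly,
        "qaly_after": after.total_qaly,
        "qaly_change": after.total_qaly - before.total_qaly,
        "qaly_change_pct": _pct(after.total_qaly, before.total_qaly),
        "people_before": before.n_people,
        "people_after": after.n_people,
        "people_change": after.n_people - before.n_people,
        "people_change_pct": _pct(after.n_people, before.n_people),
        "cost_before": before.total_cost,
        "cost_after": after.total_cost,
        "released_budget": released,
        "unreleased_savings": unreleased,
        "reinvested_spend": reinvest_spend,
    }
    return new_portfolio, after, deltas


def default_reallocation_plan(
    reinvestments: Sequence[Intervention] | None = None,
) -> ReallocationPlan:
    """The worked-example plan: stop imaging outside guidelines and the
    no-benefit injections (all variable spend releasable, £270,000 in
    total) and reinvest in digital support, community back-pain classes
    and case management for complex back pain."""
    if reinvestments is None:
        from .config import SimulationConfig
        from .synth import generate_portfolio

        reinvestments = generate_portfolio(SimulationConfig())
    stop = ("mri_outside_guidelines", "xray_spine", "facet_injection",
            "joint_injection", "trigger_point_injection")
    return ReallocationPlan(
        disinvestments=tuple(
            Disinvestment(i, fraction_stopped=1.0, releasable_cost_fraction=1.0)
            for i in stop
        ),
        reinvestments=tuple(reinvestments),
        budget_mode="released_only",
    )
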