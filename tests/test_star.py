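"""STAR value triangles, frontier, portfolio totals and reallocation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from backvalue import (
    Disinvestment,
    InputError,
    Intervention,
    PlanInfeasibleError,
    ReallocationPlan,
    SimulationConfig,
    apply_reallocation,
    build_frontier,
    cost_per_qaly,
    default_reallocation_plan,
    generate_portfolio,
    portfolio_summary,
    synthetic_baseline_portfolio,
    value_triangle,
)

DIGITAL = Intervention("digital", "Digital support", 10_000, 0.0, 2.0, 0.07)
CLASSES = Intervention("classes", "Back pain classes", 3_000, 0.0, 50.0, 0.67)
CASEMGMT = Intervention("casemgmt", "Case management", 200, 0.0, 500.0, 1.90)


class TestValueTriangle:
    @pytest.mark.parametrize("iv,cost,qaly", [
        (DIGITAL, 20_000, 700),
        (CLASSES, 150_000, 2_010),
        (CASEMGMT, 100_000, 380),
    ])
    def test_worked_example_rows(self, iv, cost, qaly):
        t = value_triangle(iv)
        assert t.total_cost == pytest.approx(cost)
        assert t.total_qaly == pytest.approx(qaly)
        assert t.slope == pytest.approx(qaly / cost)

    def test_empty_intervention(self):
        t = value_triangle(Intervention("x", "x", 0, 500.0, 10.0, 1.0))
        assert t.total_qaly == 0 and t.total_cost == 500.0

    def test_zero_cost_nonzero_qaly_flagged_infinite(self, caplog):
        with caplog.at_level("WARNING"):
            t = value_triangle(Intervention("free", "free", 10, 0.0, 0.0, 0.5))
        assert math.isinf(t.slope)
        assert "free" in caplog.text


class TestCostPerQaly:
    @pytest.mark.parametrize("iv,expected", [
        (DIGITAL, 29), (CLASSES, 75), (CASEMGMT, 263),
        (Intervention("unit", "u", 1, 0.0, 100.0, 1.0), 100),
    ])
    def test_rounded_to_nearest_pound(self, iv, expected):
        assert cost_per_qaly(iv) == expected

    def test_no_qalys_is_not_applicable(self):
        assert cost_per_qaly(Intervention("x", "x", 10, 0.0, 5.0, 0.0)) is None


class TestFrontier:
    def test_single_triangle(self):
        pts = build_frontier([value_triangle(DIGITAL)])
        assert len(pts) == 1
        assert (pts[0].cumulative_cost, pts[0].cumulative_qaly) == \
            pytest.approx((20_000, 700))

    def test_worked_example_order_and_endpoint(self):
        pts = build_frontier([value_triangle(iv)
                              for iv in (CASEMGMT, DIGITAL, CLASSES)])
        assert [p.intervention_id for p in pts] == [
            "digital", "classes", "casemgmt"
        ]
        assert pts[-1].cumulative_cost == pytest.approx(270_000)
        assert pts[-1].cumulative_qaly == pytest.approx(3_090)

    def test_concavity(self):
        pts = build_frontier([value_triangle(iv)
                              for iv in (CASEMGMT, DIGITAL, CLASSES)])
        xs = [0.0] + [p.cumulative_cost for p in pts]
        ys = [0.0] + [p.cumulative_qaly for p in pts]
        slopes = [(y1 - y0) / (x1 - x0)
                  for x0, x1, y0, y1 in zip(xs, xs[1:], ys, ys[1:])]
        assert slopes == sorted(slopes, reverse=True)

    def test_zero_qaly_interventions_placed_last_in_category_order(self):
        ivs = [
            Intervention("harm", "h", 10, 0.0, 10.0, 0.0, "possible_harm"),
            Intervention("nobenefit", "nb", 10, 0.0, 10.0, 0.0, "no_benefit"),
            Intervention("good", "g", 10, 0.0, 10.0, 0.5, "benefit"),
            Intervention("noevidence", "ne", 10, 0.0, 10.0, 0.0, "no_evidence"),
        ]
        pts = build_frontier([value_triangle(iv) for iv in ivs],
                             categories={iv.id: iv.evidence_category
                                         for iv in ivs})
        assert [p.intervention_id for p in pts] == [
            "good", "noevidence", "nobenefit", "harm"
        ]

    def test_dominates_every_permutation(self):
        """Brute-force oracle: for random instances with n <= 6 positive
        triangles, the slope-ordered cumulative curve lies weakly above
        every permutation's curve at every cost breakpoint."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(2, 7))
            tris = [value_triangle(Intervention(
                f"i{k}", f"i{k}", float(rng.integers(10, 1000)), 0.0,
                float(rng.uniform(1, 100)), float(rng.uniform(0.01, 2.0)),
            )) for k in range(n)]
            pts = build_frontier(tris)
            fx = np.array([0.0] + [p.cumulative_cost for p in pts])
            fy = np.array([0.0] + [p.cumulative_qaly for p in pts])
            for perm in itertools.permutations(tris):
                px = np.cumsum([0.0] + [t.total_cost for t in perm])
                py = np.cumsum([0.0] + [t.total_qaly for t in perm])
                grid = np.union1d(fx, px)
                assert np.all(
                    np.interp(grid, fx, fy) >= np.interp(grid, px, py) - 1e-6
                )


class TestPortfolioSummary:
    def test_empty_portfolio_zeroes(self):
        s = portfolio_summary([])
        assert (s.n_people, s.total_cost, s.total_qaly) == (0, 0, 0)

    def test_worked_example_totals(self):
        s = portfolio_summary([DIGITAL, CLASSES, CASEMGMT])
        assert s.total_cost == pytest.approx(270_000)
        assert s.total_qaly == pytest.approx(3_090)
        assert s.n_people == 13_200

    def test_duplicate_ids_rejected(self):
        with pytest.raises(InputError, match="digital"):
            portfolio_summary([DIGITAL, DIGITAL])

    def test_synthetic_baseline_category_tally(self):
        s = portfolio_summary(synthetic_baseline_portfolio())
        assert s.category_counts == {"benefit": 16, "no_evidence": 9,
                                     "no_benefit": 3, "possible_harm": 1}
        assert sum(s.category_counts.values()) == 29


class TestReallocation:
    def test_empty_plan_is_identity(self):
        base = synthetic_baseline_portfolio()
        new, summary, deltas = apply_reallocation(base, ReallocationPlan())
        assert new == list(base)
        assert deltas["qaly_change"] == 0
        assert deltas["people_change"] == 0

    def test_headline_reallocation(self):
        """Baseline 4,571 QALYs; stopping the zero-QALY disinvestment
        candidates releases £270,000 which buys 3,090 QALYs: 7,661 in all,
        a 67% increase within the same £4.5M spend."""
        base = synthetic_baseline_portfolio()
        _, summary, deltas = apply_reallocation(base,
                                                default_reallocation_plan())
        assert deltas["qaly_before"] == pytest.approx(4_571)
        assert summary.total_qaly == pytest.approx(7_661)
        assert deltas["qaly_change_pct"] == pytest.approx(67.6, abs=0.1)
        assert summary.total_cost == pytest.approx(4_500_000, abs=1.0)
        assert summary.n_people > 25_000

    def test_locked_fixed_costs_release_nothing(self):
        iv = Intervention("locked", "locked", 100, 0.0, 10.0, 0.0,
                          "no_benefit")
        keep = Intervention("keep", "keep", 10, 0.0, 1.0, 1.0)
        plan = ReallocationPlan(disinvestments=(
            Disinvestment("locked", 1.0, 0.0),
        ))
        _, summary, deltas = apply_reallocation([iv, keep], plan)
        assert deltas["released_budget"] == 0.0
        assert deltas["unreleased_savings"] == pytest.approx(1000.0)
        assert deltas["qaly_change"] == pytest.approx(-iv.total_qaly)

    def test_infeasible_plan_reports_shortfall(self):
        base = [Intervention("a", "a", 10, 0.0, 10.0, 0.0, "no_benefit")]
        plan = ReallocationPlan(
            disinvestments=(Disinvestment("a", 1.0, 1.0),),
            reinvestments=(Intervention("big", "big", 1000, 0.0, 10.0, 0.5),),
        )
        with pytest.raises(PlanInfeasibleError, match="9,900"):
            apply_reallocation(base, plan)

    def test_unknown_disinvestment_id_rejected(self):
        plan = ReallocationPlan(disinvestments=(Disinvestment("ghost", 1, 1),))
        with pytest.raises(InputError, match="ghost"):
            apply_reallocation(synthetic_baseline_portfolio(), plan)

    def test_fixed_envelope_neutrality_enforced(self):
        base = synthetic_baseline_portfolio()
        plan = default_reallocation_plan()
        ok = ReallocationPlan(plan.disinvestments, plan.reinvestments,
                              "fixed_envelope", 4_500_000.0)
        _, summary, _ = apply_reallocation(base, ok)
        assert abs(summary.total_cost - 4_500_000.0) <= 1.0
        bad = ReallocationPlan(plan.disinvestments, (),
                               "fixed_envelope", 4_500_000.0)
        with pytest.raises(PlanInfeasibleError):
            apply_reallocation(base, bad)

    @given(
        fracs=st.lists(st.tuples(st.floats(0, 1), st.floats(0, 1)),
                       min_size=1, max_size=5),
    )
    def test_budget_conservation(self, fracs):
        """released_only: post-plan spend = baseline spend - unreleased
        savings, exactly, when reinvestment consumes all released budget."""
        base = [Intervention(f"d{k}", f"d{k}", 100, 50.0, 10.0, 0.0,
                             "no_evidence") for k in range(len(fracs))]
        dis = tuple(Disinvestment(f"d{k}", f, r)
                    for k, (f, r) in enumerate(fracs))
        released = sum(f * r * 1000.0 for f, r in fracs)
        reinvest = ((Intervention("new", "new", 1, 0.0, released, 1.0),)
                    if released > 0 else ())
        plan = ReallocationPlan(dis, reinvest)
        _, summary, deltas = apply_reallocation(base, plan, tolerance=1e-6)
        before = sum(iv.total_cost for iv in base)
        assert summary.total_cost == pytest.approx(
            before - deltas["unreleased_savings"], abs=1e-6
        )

    @given(q=st.floats(0.07, 5.0))
    def test_better_reinvestment_never_loses_qalys(self, q):
        base = synthetic_baseline_portfolio()
        plan = default_reallocation_plan()
        boosted = tuple(
            iv if iv.id != "digital_support"
            else Intervention(iv.id, iv.name, iv.n_treated, iv.fixed_cost,
                              iv.variable_cost_per_person, q)
            for iv in plan.reinvestments
        )
        _, s1, _ = apply_reallocation(base, plan)
        _, s2, _ = apply_reallocation(
            base, ReallocationPlan(plan.disinvestments, boosted)
        )
        assert s2.total_qaly >= s1.total_qaly


class TestGeneratedPortfolio:
    def test_config_spec_round_trips_to_interventions(self):
        port = generate_portfolio(SimulationConfig())
        assert [cost_per_qaly(iv) for iv in port] == [29, 75, 263]
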