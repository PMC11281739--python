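"""STAR value-for-money triangles, the efficiency frontier, and a
budget-neutral reallocation.

Starts from a synthetic 29-intervention baseline matching the published
margins (17,225 people, £4.5M, 4,571 QALYs, categories 16/9/3/1), stops the
zero-QALY disinvestment candidates (releasing £270,000 of variable spend),
and reinvests in digital support, back-pain classes and case management.
"""

from backvalue import (
    apply_reallocation,
    build_frontier,
    cost_per_qaly,
    default_reallocation_plan,
    portfolio_summary,
    synthetic_baseline_portfolio,
    value_triangle,
)

baseline = synthetic_baseline_portfolio()
base = portfolio_summary(baseline)
print(f"baseline: {base.n_interventions} interventions, "
      f"{base.n_people:,.0f} people, £{base.total_cost / 1e6:.1f}M, "
      f"{base.total_qaly:,.0f} QALYs")
print(f"evidence categories: {base.category_counts}")

plan = default_reallocation_plan()
print("\nreinvestment candidates (cost per QALY, £):")
for iv in plan.reinvestments:
    t = value_triangle(iv)
    print(f"  {iv.name:<20} n={iv.n_treated:>6,.0f}  "
          f"£{t.total_cost:>8,.0f}  {t.total_qaly:>6,.0f} QALYs  "
          f"£{cost_per_qaly(iv)}/QALY")

frontier = build_frontier([value_triangle(iv) for iv in plan.reinvestments])
end = frontier[-1]
print(f"  TOTAL invested £{end.cumulative_cost:,.0f} -> "
      f"{end.cumulative_qaly:,.0f} QALYs")

new_portfolio, post, deltas = apply_reallocation(baseline, plan)
print(f"\nafter reallocation: {post.total_qaly:,.0f} QALYs "
      f"({deltas['qaly_change_pct']:+.0f}%) within "
      f"£{post.total_cost / 1e6:.1f}M — the same spend buys "
      f"{deltas['qaly_change']:,.0f} extra QALYs.")
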