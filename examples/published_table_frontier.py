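"""Pairwise ICERs, efficiency frontier and threshold pricing from the
published seven-arm per-patient totals.

The published base-case table (discounted cost and QALYs per patient for
each third-line TRD strategy) is itself a valid input to the comparison
routines: this script recomputes every decision quantity from those
totals alone.
"""

import trdcea as t

outcomes = {
    name: t.StrategyOutcome.from_totals(name, cost, qaly)
    for name, (cost, qaly) in t.REFERENCE_TOTALS.items()
}

print("Pairwise comparisons vs augmentation (the reference arm):")
for name in t.STRATEGY_NAMES:
    if name == "AUG":
        continue
    c = t.icer(outcomes[name], outcomes["AUG"])
    print(f"  {c}")

print("\nEfficiency frontier (ascending cost):")
fr = t.efficiency_frontier(list(outcomes.values()))
for name in fr.order:
    o = outcomes[name]
    seq = fr.sequential_icers.get(name)
    extra = f", ICER vs previous {seq:,.0f} US$/QALY" if seq is not None else ""
    print(f"  {name:10s} {o.cost:8,.0f} US$  {o.qaly:.3f} QALYs"
          f"  [{fr.labels[name]}]{extra}")

nmb = t.net_monetary_benefit(outcomes["ESK+AD"], outcomes["AUG"], 50_000)
print(f"\nNMB of esketamine vs augmentation at WTP 50,000: {nmb:,.0f} US$")
print("  (negative: the QALY gain is worth less than the extra cost)")

threshold = t.cost_threshold_solve(outcomes["AUG"], outcomes["ESK+AD"].qaly, 50_000)
print(f"Esketamine-arm total cost for ICER = WTP: {threshold:,.0f} US$")
print("  (the per-patient cost at which esketamine becomes cost-effective)")
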