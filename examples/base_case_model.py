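"""Full cohort-model run on the packaged synthetic base case.

Builds the seven-arm parameter set (three treatment lines, five health
states per line plus death), propagates each cohort over 65 four-week
cycles, and prints discounted totals with the time patients spend in
each state.  The synthetic inputs reproduce the qualitative structure of
the Hong Kong comparison, not its printed totals.
"""

import trdcea as t

ps = t.base_case_parameter_set()
settings = t.default_settings()
print(f"Strategies: {', '.join(ps.strategy_names)}")
print(f"{settings.n_cycles} cycles of {settings.cycle_weeks} weeks, "
      f"{settings.annual_discount_rate:.0%}/year discount\n")

outcomes = t.run_all_strategies(ps, settings)
print(f"{'strategy':<10s} {'cost US$':>9s} {'QALYs':>7s}   years in remission")
for name, o in outcomes.items():
    print(f"{name:<10s} {o.cost:>9,.0f} {o.qaly:>7.3f}   "
          f"{o.time_in_state_years['remission']:.2f}")

fr = t.efficiency_frontier(list(outcomes.values()))
print(f"\nFrontier: {' -> '.join(fr.frontier)}")
for name, icer in fr.sequential_icers.items():
    print(f"  {name} vs previous: {icer:,.0f} US$/QALY")
print("\nStrategies off the frontier are dominated: another arm (or a mix"
      "\nof two) delivers more QALYs at lower cost.")
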