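# Methods

## Model structure

The model is a discrete-time Markov cohort simulation over
`5L + 1` states: for each of `L` treatment lines (default 3), the five
health states Treatment, Response, Remission, Nonresponse and Relapse,
plus one absorbing Death state. The cohort starts fully in line-1
Treatment. Within a line the permitted moves are

- Treatment → Response, Remission, Nonresponse (residual mass stays in
  Treatment, i.e. assessment continues),
- Response → Remission (consolidation) or Relapse (residual stays),
- Remission → Relapse (residual stays),
- Nonresponse and Relapse → next line's Treatment in the ensuing cycle,
  with certainty among survivors.

This is the minimal within-line graph consistent with the state
definitions (response = ≥50% symptom reduction; remission = score below
an absolute threshold; relapse = symptom recurrence after
response/remission); alternative arrows can be added by extending the
transition table. After the last modelled line fails, patients remain
in that line's Nonresponse state — a treatment-failure management state
accruing background costs and nonresponse utility — the conservative
convention for "what happens after the modelled sequence is exhausted".

All-cause mortality applies first in every living state each cycle
(probability `m` per cycle); the remaining transition probabilities act
on survivors, i.e. each parameterised flow is multiplied by `1 − m`.
Death occupancy is therefore nondecreasing and every row of the
transition matrix sums to 1 (checked to 1e−9 at assembly).

## Time grid, conversion and discounting

The base case uses 4-week cycles over a 5-year horizon:
`floor(5 × 52 / 4) = 65` cycles, with `weeks_per_year` fixed at 52 (the
simplest convention; the difference from 52.18 is negligible at 3%/yr
discounting). Transition inputs are stored as the originally observed
proportion `r` over `t` weeks of follow-up and converted per cycle
under constant hazard, `p = 1 − exp(ln(1 − r)/t · c)`; the inverse
recovers `r` exactly, and `p₈ = 1 − (1 − p₄)²` holds by construction,
so a cycle-length change (the 8-week scenario) re-derives every
probability consistently rather than rescaling matrices.

Cycle `t` accrues the cost and utility of the state occupied at its
start — transitions take effect at cycle boundaries — discounted by
`(1 + r)^(−t·c/52)`. There is no half-cycle correction by default (an
optional flag applies start/end averaging); with zero mortality,
person-time therefore equals the horizon exactly on the native grid and
agrees across cycle lengths up to one cycle's truncation
(`floor(260/8) = 32` eight-week cycles cover 4.92 of 5 years).

## Strategies, effects and costs

Seven arms are registered: AUG (reference), COM, PSY alone, PSY+AD,
ESK+AD, rTMS+AD, ECT+AD. Effectiveness is anchored: per-line baseline
transitions describe oral-AD monotherapy, and each arm applies relative
risks to treatment→response, treatment→remission and remission→relapse
on the probability scale, clamped at 1 (`min(p·RR, 1)`). The
probability scale is the package's choice — a rate-scale application
would differ only in the third decimal at these magnitudes — and
missing line-specific RRs inherit the line-1 value; the packaged inputs
instead set downstream RRs to 1 explicitly (identical subsequent care
in every arm), confining each strategy's identity to its index line.

Cost components per strategy and line, in US$ per 4-week base cycle:
drug acquisition, administration/monitoring, procedure cost per session
× sessions per cycle, and background healthcare utilisation per health
state. Acquisition and administration continue through Response and
Remission while the index treatment is maintained (per-strategy flag,
on by default, reflecting maintenance dosing); procedures accrue only
in the Treatment state (acute courses). Under an 8-week cycle,
time-proportional components (acquisition, background) scale by
`c/4` while visit-linked components (administration, procedure
sessions) stay per-cycle — the package's convention where the evidence
is silent. Currency is US$ internally; HKD-denominated files are
divided by 7.80 at load time. Time-varying cost edits (e.g. halving
esketamine costs from cycle 2 in the biweekly-dosing scenario) are
multiplicative schedule entries resolved during accrual.

## Economic settings

| parameter | default | units | rationale |
|---|---|---|---|
| WTP | 50,000 | US$/QALY | ≈1× Hong Kong GDP per capita |
| discount rate | 0.03 | /year | standard payer-perspective practice |
| cycle length | 4 | weeks | minimum interval to assess response |
| horizon | 5 | years | matches available trial follow-up |

## Sensitivity analysis

**DSA.** Each parameter moves to the low and high ends of its declared
interval (the bounds stored with its sampling distribution) while all
others stay at base; rows are ranked by `|ICER_high − ICER_low|` for
the chosen arm pair. The ICER is reported as the signed ratio even in
dominance quadrants so spreads remain well defined.

**PSA.** All parameters are sampled jointly and independently (no
correlation structure is specified; a hook exists in the key-addressed
sampler): beta for probabilities and utilities, gamma for costs,
lognormal for relative risks, each moment-matched to its point estimate
and 95% interval (sd = width/3.92; lognormal matched on the median and
ratio-scale interval). Every parameter draws from its own substream
keyed by (master seed, CRC-32 of the parameter key), so adding or
removing a parameter never perturbs another's draws. Extreme joint RR
draws can push a state's outgoing probabilities past 1; the engine
raises by default, and the PSA path proportionally rescales the
offending state's flows for that draw, counting occurrences (zero on
the packaged inputs at the tested sizes).

**CEAC.** At each WTP on the grid (default 0–400,000 US$/QALY in steps
of 80), the probability a strategy is cost-effective is the fraction of
draws in which it attains the maximal NMB, exact ties splitting mass
equally (a measure-zero event under continuous distributions, the
deterministic answer under degenerate ones — so curves are exact step
functions switching at the frontier's sequential ICERs in that limit).
The crossover WTP at which a strategy first strictly leads is grid
search refined by bisection on the draws to US$1.

## Frontier conventions

Strategies sort by ascending cost, ties broken by higher QALY (standard
CEA convention). Strict dominance removes any point with a cheaper,
no-less-effective competitor; extended dominance then iteratively
removes interior points until sequential ICERs strictly increase,
yielding the lower-left convex hull (verified against a brute-force
mixture-enumeration oracle in the tests). Internal arithmetic is
unrounded; reports round costs to integer US$ and QALYs to three
decimals. South-west comparisons (cheaper and less effective) report
the reversed ratio with an explicit label.

## Synthetic inputs

Study-specific inputs load from JSON or long-format CSV through a
validated schema. Because the evaluation this package reimplements
published only per-patient totals (not its full input appendix), the
packaged base case is a hand-tuned synthetic input set: STAR*D-style
line-specific baselines (remission proportions falling from 0.28 to
0.13 over 12-week follow-up across lines, relapse rising 0.45→0.70 per
year), literature-scale relative risks (e.g. esketamine
remission→relapse RR 0.55 reflecting maintenance-trial relapse
reduction; ECT the strongest acute RRs), Hong Kong-scale unit costs
(esketamine US$780/cycle acquisition + supervised administration;
labor-intensive rTMS and ECT session costs; utilities 0.85/0.72/0.60/
0.57/0.55 for remission/response/treatment/nonresponse/relapse; annual
mortality 1.2%). It is calibrated so the *qualitative* seven-arm
structure emerges — combination therapy cheapest nondominated,
augmentation and psychotherapy-alone dominated, rTMS strictly dominated
by esketamine, ECT most costly and most effective, strictly increasing
frontier ICERs — and its published totals are *not* targeted; loading
the original appendix values through the same schema is the route to a
quantitative reproduction. Consequently, tests passing on the synthetic
base case demonstrate correct machinery and the right qualitative
economics, not agreement with any printed cost or QALY.

The seeded random generator (`FixtureConfig`) draws every input within
realistic ranges, enforcing line monotonicity and the utility ordering
remission ≥ response ≥ nonresponse, and attaches distributions whose
means equal the drawn point estimates; it exists for property testing
(conservation, dominance-ordering and validation invariants over many
seeds), not to emulate any particular population.

## Problem sizes

The test suite runs the full 65-cycle model across 100 random input
sets, checks cohort propagation against a 100,000-agent individual-level
microsimulation at three Monte-Carlo standard errors per state, and
exercises the probabilistic machinery at 400–4,000 draws; the
reproduction script uses 2,000 draws for the acceptability quantities.
These sizes give Monte-Carlo error well inside the tolerances asserted
while keeping the whole suite under a minute on one CPU; the engine
evaluates one strategy in under a millisecond, so 10,000-draw analyses
(the conventional PSA size, and the CLI default) remain routine.

## Limitations

- No age structure, no state- or age-dependent excess mortality, and no
  treatment-specific utility decrements (dissociation with esketamine,
  cognitive effects of ECT): utilities attach to health states only.
- Constant treatment effects over time; no adherence, discontinuation
  or dose-adjustment dynamics; no sequential-pathway modelling of
  esketamine after other failures.
- Anchored indirect comparisons inherit the heterogeneity of their
  source populations; the synthetic inputs inherit it notionally.
- PSA independence across parameters is an assumption, not a finding;
  correlated sampling requires supplying joint draws through the
  key-addressed interface.
- The 8-week-cycle scenario re-runs *all* arms on the common grid so
  ICERs compare like with like; an esketamine-only grid change is
  possible by running arms under different settings, but mixed-grid
  ICERs conflate structural and treatment effects.
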