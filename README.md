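# trdcea

Markov cohort cost-effectiveness analysis of third-line treatment
strategies for treatment-resistant depression (TRD).

## The problem

TRD — depression that has failed at least two adequate antidepressant
regimens — is managed with a heterogeneous mix of third-line options:
augmenting an oral antidepressant (AD) with an antipsychotic or lithium
(AUG), combining two ADs (COM), psychotherapy alone or with an AD (PSY,
PSY+AD), esketamine nasal spray plus an AD (ESK+AD), repetitive
transcranial magnetic stimulation (rTMS+AD) and electroconvulsive
therapy (ECT+AD). These differ radically in cost structure
(drug-intensive vs labor-intensive) and in durability of benefit, so
which one represents good value for a healthcare payer is an empirical
question. `trdcea` implements the decision-analytic machinery for
answering it: a multi-line Markov cohort model plus the full
cost-effectiveness apparatus around it.

## The model

A closed cohort enters line 1 (the third line of therapy since
diagnosis) in a **Treatment** state and moves between five health states
per line — Treatment, Response, Remission, Nonresponse, Relapse — plus a
single absorbing Death state, in 4-week cycles over a 5-year horizon.
Nonresponse or relapse starts the next treatment line in the ensuing
cycle; failure of the last modelled line leaves patients in a managed
nonresponse state. Baseline per-line transitions describe the oral-AD
anchor, with response/remission falling and relapse rising line by line
(deepening treatment resistance); each strategy modifies them through
relative risks (RR) from anchored indirect comparisons. Event
proportions observed over *t* weeks convert to per-cycle probabilities
under constant hazard, `p = 1 − exp(ln(1 − r)/t · c)` for cycle length
*c*.

Each cycle accrues state-specific costs (drug acquisition,
administration/monitoring, procedure sessions, background utilisation)
and utility-weighted person-time, discounted at 3%/year. Per-strategy
totals feed:

- **ICER** = ΔCost/ΔQALY with dominance classification,
- the **efficiency frontier** (lower-left convex hull of (QALY, cost)
  points; strict and extended dominance, sequential ICERs),
- **NMB** = WTP × ΔQALY − ΔCost at a willingness-to-pay threshold
  (US$50,000/QALY base case),
- one-way **DSA** (tornado), joint **PSA** with beta/gamma/lognormal
  parameter distributions, **CEAC**s and the WTP at which a strategy
  first leads them,
- eight **scenario analyses** including a closed-form solve for the
  esketamine-arm cost at which its ICER equals the WTP threshold.

## Worked example

The comparison routines accept any per-patient totals, including a
published results table. Running
`python examples/published_table_frontier.py` on the seven-arm Hong Kong
totals shipped with the package prints:

```
Pairwise comparisons vs augmentation (the reference arm):
  COM vs AUG: dominant
  PSY alone vs AUG: dominated
  PSY+AD vs AUG: ICER 173,226 US$/QALY
  ESK+AD vs AUG: ICER 234,109 US$/QALY
  rTMS+AD vs AUG: ICER 351,756 US$/QALY
  ECT+AD vs AUG: ICER 277,853 US$/QALY

Efficiency frontier (ascending cost):
  COM          16,163 US$  2.903 QALYs  [nondominated]
  AUG          16,185 US$  2.895 QALYs  [strictly dominated]
  PSY alone    19,538 US$  2.879 QALYs  [strictly dominated]
  PSY+AD       21,555 US$  2.926 QALYs  [nondominated], ICER vs previous 234,435 US$/QALY
  ESK+AD       29,061 US$  2.950 QALYs  [nondominated], ICER vs previous 312,750 US$/QALY
  rTMS+AD      30,607 US$  2.936 QALYs  [strictly dominated]
  ECT+AD       46,471 US$  3.004 QALYs  [nondominated], ICER vs previous 322,407 US$/QALY

NMB of esketamine vs augmentation at WTP 50,000: -10,126 US$
Esketamine-arm total cost for ICER = WTP: 18,935 US$
```

Combination therapy dominates augmentation (cheaper and more
effective); esketamine sits on the frontier but with an ICER far above
US$50,000/QALY, and would need its total arm cost to fall to US$18,935
(~35%) to be cost-effective at that threshold.

The other examples run the full engine on the packaged synthetic base
case (`examples/base_case_model.py`), the tornado/PSA/CEAC machinery
(`examples/sensitivity_analysis.py`) and the eight scenarios
(`examples/scenario_analysis.py`).

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
cea fixture --out params.json          # write a synthetic input set
cea validate --params params.json
cea run --params params.json --out results/
cea dsa --params params.json --out results/
cea psa --params params.json --n 10000 --seed 1 --out results/
cea ceac --params params.json --wtp-grid 0:400000:80 --out results/
cea scenario --params params.json --ids 1-8 --out results/
```

Every command writes plain CSV plus a `manifest.json` recording input
digests, settings and seeds.

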