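"""Cohort state-transition engine.

The model follows a closed cohort of adults with treatment-resistant
depression through up to ``L`` successive treatment lines.  Each line has
five health states — Treatment, Response, Remission, Nonresponse, Relapse —
and a single absorbing Death state closes the state space (``5L + 1``
states).  The cohort starts fully in line-1 Treatment, transitions at
cycle boundaries, and accrues costs and quality-adjusted life-years
cycle by cycle with annual discounting.

Within-line dynamics: Treatment may move to Response, Remission or
Nonresponse (residual mass stays in Treatment); Response may consolidate
into Remission or relapse; Remission may relapse.  Nonresponse and Relapse
initiate the next treatment line in the ensuing cycle; after the last
modelled line fails, patients remain in that line's Nonresponse state as a
treatment-failure management state.  All-cause mortality applies to every
living state first each cycle, with the remaining transition probabilities
scaled over survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    BASE_CYCLE_WEEKS,
    HEALTH_STATES,
    EconomicSettings,
    ParameterSet,
    StrategyInputs,
    ValidationError,
    apply_relative_risk,
)

__all__ = [
    "StateSpace",
    "CohortTrace",
    "StrategyOutcome",
    "ModelError",
    "discount_factor",
    "build_transition_matrix",
    "run_cohort",
    "accrue_outcomes",
    "run_strategy",
    "run_all_strategies",
]

#: Cost components whose per-cycle value is proportional to the time the
#: cycle covers (drug supply, background utilisation); visit-linked
#: components (administration/monitoring, procedure sessions) are per
#: cycle regardless of its length.
_TIME_PROPORTIONAL = ("drug_acquisition", "background")


class ModelError(RuntimeError):
    """Internal inconsistency detected while assembling or running the model."""


class StateSpace:
    """Fixed enumeration of model states.

    Order: for each line ``k = 1..L``, the five health states in
    ``HEALTH_STATES`` order; the absorbing Death state is last.  Labels
    read ``"L1:treatment"``, ..., ``"death"``.
    """

    def __init__(self, n_lines: int):
        if n_lines < 1:
            raise ValidationError(f"n_lines must be >= 1, got {n_lines}")
        self.n_lines = n_lines
        self.labels: list[str] = [
            f"L{k}:{s}" for k in range(1, n_lines + 1) for s in HEALTH_STATES
        ] + ["death"]
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def death(self) -> int:
        return self.n - 1

    def index(self, line: int, state: str) -> int:
        return self._index[f"L{line}:{state}"]

    def line_state(self, i: int) -> tuple[int, str] | None:
        """(line, state) of a living state index, or None for Death."""
        if i == self.death:
            return None
        return i // len(HEALTH_STATES) + 1, HEALTH_STATES[i % len(HEALTH_STATES)]


@dataclass
class CohortTrace:
    """Per-cycle state occupancy of one strategy's cohort.

    ``occupancy[t]`` is the distribution at the *start* of cycle ``t``;
    rows run from cycle 0 to the end of the horizon inclusive.
    """

    strategy: str
    space: StateSpace
    occupancy: np.ndarray  # (n_cycles + 1, n_states)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1


@dataclass
class StrategyOutcome:
    """Discounted per-patient totals for one strategy, with breakdowns."""

    strategy: str
    cost: float
    qaly: float
    cost_undiscounted: float = 0.0
    qaly_undiscounted: float = 0.0
    cost_components: dict[str, float] = field(default_factory=dict)
    time_in_state_years: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_totals(cls, strategy: str, cost: float, qaly: float) -> "StrategyOutcome":
        """Wrap externally supplied per-patient totals (e.g. a published
        results table) for use with the comparison/frontier routines."""
        return cls(strategy=strategy, cost=cost, qaly=qaly,
                   cost_undiscounted=cost, qaly_undiscounted=qaly)


def discount_factor(
    cycle_index: int, annual_rate: float, cycle_weeks: float, weeks_per_year: float = 52.0
) -> float:
    """Discount factor applied to cycle ``cycle_index`` (0-based):
    ``(1 + r)^(-t * cycle_weeks / weeks_per_year)``."""
    if cycle_index < 0:
        raise ValidationError(f"cycle_index must be >= 0, got {cycle_index}")
    if annual_rate < 0:
        raise ValidationError(f"annual_rate must be >= 0, got {annual_rate}")
    return (1.0 + annual_rate) ** (-cycle_index * cycle_weeks / weeks_per_year)


def _effective_probability(
    ps: ParameterSet,
    strategy: StrategyInputs,
    line: int,
    transition: str,
    cycle_weeks: float,
) -> float:
    p = ps.lines[line - 1].transitions[transition].per_cycle(cycle_weeks)
    eff = strategy.effect_for(line, transition)
    if eff is not None:
        p = apply_relative_risk(p, eff.rr)
    return p


def build_transition_matrix(
    strategy: str | StrategyInputs,
    ps: ParameterSet,
    settings: EconomicSettings,
    infeasible: str = "error",
) -> np.ndarray:
    """Assemble the row-stochastic per-cycle transition matrix for one
    strategy over the full (line x state) + Death space.

    Mortality is applied first each cycle; the remaining transition
    probabilities act on survivors (scaled by ``1 - m``).  Nonresponse and
    Relapse in line ``k < L`` route to Treatment of line ``k + 1``; in the
    last line they collect in that line's Nonresponse state.

    Parameters
    ----------
    infeasible : {"error", "rescale"}
        What to do when a state's effective outgoing probabilities exceed
        unity (possible under extreme joint relative-risk draws): raise a
        :class:`ModelError`, or proportionally rescale that state's
        outgoing transitions to sum to 1 (used by the probabilistic
        sensitivity analysis).
    """
    strat = ps.strategies[strategy] if isinstance(strategy, str) else strategy
    space = StateSpace(ps.n_lines)
    cw = settings.cycle_weeks
    m = ps.mortality.per_cycle(cw)
    L = ps.n_lines

    P = np.zeros((space.n, space.n))
    P[space.death, space.death] = 1.0

    def outgoing(line: int, pairs: list[tuple[str, int]], src: int) -> None:
        """Fill one living state's row: mortality, then survivor flows."""
        probs = [
            _effective_probability(ps, strat, line, ttype, cw) for ttype, _ in pairs
        ]
        total = sum(probs)
        if total > 1.0 + 1e-12:
            if infeasible == "rescale":
                probs = [p / total for p in probs]
                total = 1.0
            else:
                raise ModelError(
                    f"strategy {strat.name}, line {line}: outgoing probabilities "
                    f"from state {space.labels[src]} sum to {total:.6f} > 1"
                )
        P[src, space.death] = m
        for p, (_, dst) in zip(probs, pairs):
            P[src, dst] = (1.0 - m) * p
        P[src, src] += (1.0 - m) * (1.0 - total)

    for k in range(1, L + 1):
        t_idx = space.index(k, "treatment")
        outgoing(
            k,
            [
                ("treatment_to_response", space.index(k, "response")),
                ("treatment_to_remission", space.index(k, "remission")),
                ("treatment_to_nonresponse", space.index(k, "nonresponse")),
            ],
            t_idx,
        )
        outgoing(
            k,
            [
                ("response_to_remission", space.index(k, "remission")),
                ("response_to_relapse", space.index(k, "relapse")),
            ],
            space.index(k, "response"),
        )
        outgoing(
            k,
            [("remission_to_relapse", space.index(k, "relapse"))],
            space.index(k, "remission"),
        )
        # Treatment-line failure: start the next line's treatment in the
        # ensuing cycle, or settle in the last line's management state.
        nr, rl = space.index(k, "nonresponse"), space.index(k, "relapse")
        if k < L:
            nxt = space.index(k + 1, "treatment")
            P[nr, space.death] = m
            P[nr, nxt] = 1.0 - m
            P[rl, space.death] = m
            P[rl, nxt] = 1.0 - m
        else:
            P[nr, space.death] = m
            P[nr, nr] = 1.0 - m
            P[rl, space.death] = m
            P[rl, nr] = 1.0 - m

    rowsums = P.sum(axis=1)
    if np.any(np.abs(rowsums - 1.0) > 1e-9):
        bad = int(np.argmax(np.abs(rowsums - 1.0)))
        raise ModelError(
            f"transition matrix row {space.labels[bad]} sums to {rowsums[bad]!r}"
        )
    return P


def run_cohort(
    strategy: str | StrategyInputs,
    ps: ParameterSet,
    settings: EconomicSettings,
    infeasible: str = "error",
) -> CohortTrace:
    """Propagate the cohort from full line-1 Treatment occupancy through
    the horizon; returns the per-cycle occupancy trace."""
    strat = ps.strategies[strategy] if isinstance(strategy, str) else strategy
    space = StateSpace(ps.n_lines)
    P = build_transition_matrix(strat, ps, settings, infeasible=infeasible)
    n_cycles = settings.n_cycles
    occ = np.zeros((n_cycles + 1, space.n))
    occ[0, space.index(1, "treatment")] = 1.0
    for t in range(n_cycles):
        occ[t + 1] = occ[t] @ P
    if np.any(occ < -1e-12) or np.any(occ > 1 + 1e-12):
        raise ModelError("occupancy left [0, 1] during propagation")
    return CohortTrace(strategy=strat.name, space=space, occupancy=occ)


def _state_cost_components(
    strat: StrategyInputs, ps: ParameterSet, space: StateSpace, cycle_scale: float
) -> dict[str, np.ndarray]:
    """Per-state per-cycle cost vectors by component (US$), before any
    time-varying schedule.  ``cycle_scale`` = cycle_weeks / base cycle."""
    comps = {
        name: np.zeros(space.n)
        for name in ("drug_acquisition", "administration_monitoring", "procedure",
                     "background")
    }
    for i in range(space.n - 1):
        line, state = space.line_state(i)  # type: ignore[misc]
        cc = strat.costs[line]
        comps["background"][i] = cc.background_utilization[state] * cycle_scale
        on_treatment = state == "treatment"
        on_maintenance = (
            strat.maintenance_in_response_remission
            and state in ("response", "remission")
        )
        if on_treatment or on_maintenance:
            comps["drug_acquisition"][i] = cc.drug_acquisition * cycle_scale
            comps["administration_monitoring"][i] = cc.administration_monitoring
        if on_treatment:
            comps["procedure"][i] = cc.procedure_per_cycle
    return comps


def accrue_outcomes(
    trace: CohortTrace, ps: ParameterSet, settings: EconomicSettings
) -> StrategyOutcome:
    """Accumulate discounted costs and QALYs over a cohort trace.

    Cycle ``t`` accrues the cost and utility of the state occupied at its
    start (transitions take effect at cycle boundaries), discounted with
    :func:`discount_factor`.  With the optional half-cycle correction the
    mean of start- and end-of-cycle occupancy is used instead.
    """
    strat = ps.strategies[trace.strategy]
    space = trace.space
    cw = settings.cycle_weeks
    cycle_years = settings.cycle_years
    cycle_scale = cw / BASE_CYCLE_WEEKS

    for state in HEALTH_STATES:
        if state not in ps.utilities.values:
            raise ModelError(f"missing utility for occupied state {state}")

    u = np.zeros(space.n)
    for i in range(space.n - 1):
        _, state = space.line_state(i)  # type: ignore[misc]
        u[i] = ps.utilities[state]

    comps = _state_cost_components(strat, ps, space, cycle_scale)

    # Time-varying cost schedule: multiplicative factors per component
    # from a given cycle onward, possibly restricted to one line.
    def schedule_factor(t: int, component: str, i: int) -> float:
        f = 1.0
        line_state = space.line_state(i)
        for entry in strat.cost_schedule:
            if entry.component != component or t < entry.from_cycle:
                continue
            if entry.line is not None and (
                line_state is None or line_state[0] != entry.line
            ):
                continue
            f *= entry.factor
        return f

    scheduled = {e.component for e in strat.cost_schedule}

    n_cycles = trace.n_cycles
    dfs = np.array(
        [
            discount_factor(t, settings.annual_discount_rate, cw, settings.weeks_per_year)
            for t in range(n_cycles)
        ]
    )
    if settings.half_cycle_correction:
        occ = 0.5 * (trace.occupancy[:-1] + trace.occupancy[1:])
    else:
        occ = trace.occupancy[:-1]

    qaly_per_cycle = occ @ u * cycle_years
    qaly = float(qaly_per_cycle @ dfs)
    qaly_undisc = float(qaly_per_cycle.sum())

    cost = 0.0
    cost_undisc = 0.0
    cost_components: dict[str, float] = {}
    for name, vec in comps.items():
        if name in scheduled:
            per_cycle = np.empty(n_cycles)
            for t in range(n_cycles):
                factors = np.array(
                    [schedule_factor(t, name, i) for i in range(space.n)]
                )
                per_cycle[t] = occ[t] @ (vec * factors)
        else:
            per_cycle = occ @ vec
        c_disc = float(per_cycle @ dfs)
        cost_components[name] = c_disc
        cost += c_disc
        cost_undisc += float(per_cycle.sum())

    time_in_state: dict[str, float] = {}
    for state in HEALTH_STATES:
        idx = [space.index(k, state) for k in range(1, space.n_lines + 1)]
        time_in_state[state] = float(occ[:, idx].sum() * cycle_years)

    return StrategyOutcome(
        strategy=trace.strategy,
        cost=cost,
        qaly=qaly,
        cost_undiscounted=cost_undisc,
        qaly_undiscounted=qaly_undisc,
        cost_components=cost_components,
        time_in_state_years=time_in_state,
    )


def run_strategy(
    strategy: str,
    ps: ParameterSet,
    settings: EconomicSettings,
    infeasible: str = "error",
) -> StrategyOutcome:
    """Run the cohort for one strategy and accrue its outcomes."""
    trace = run_cohort(strategy, ps, settings, infeasible=infeasible)
    return accrue_outcomes(trace, ps, settings)


def run_all_strategies(
    ps: ParameterSet,
    settings: EconomicSettings,
    strategies: list[str] | None = None,
    infeasible: str = "error",
) -> dict[str, StrategyOutcome]:
    """Run every (or the listed) strategy under common settings."""
    names = strategies if strategies is not None else ps.strategy_names
    return {name: run_strategy(name, ps, settings, infeasible=infeasible) for name in names}
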