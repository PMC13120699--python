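"""Shared fixtures: the packaged base-case input set, a hand-checkable
two-line toy model, and an independent individual-level microsimulation
used as an oracle for the cohort propagation."""

from __future__ import annotations

import numpy as np
import pytest

import trdcea as t


@pytest.fixture(scope="session")
def base_ps() -> t.ParameterSet:
    return t.base_case_parameter_set()


@pytest.fixture(scope="session")
def settings() -> t.EconomicSettings:
    return t.default_settings()


@pytest.fixture(scope="session")
def base_outcomes(base_ps, settings) -> dict[str, t.StrategyOutcome]:
    return t.run_all_strategies(base_ps, settings)


@pytest.fixture(scope="session")
def published_outcomes() -> dict[str, t.StrategyOutcome]:
    """The published per-patient totals wrapped as outcomes."""
    return {
        name: t.StrategyOutcome.from_totals(name, cost, qaly)
        for name, (cost, qaly) in t.REFERENCE_TOTALS.items()
    }


def make_toy_ps(
    mortality_p: float = 0.01,
    rr: tuple[float, float, float] = (1.5, 1.2, 0.5),
) -> t.ParameterSet:
    """Two-line, one-strategy model with per-cycle probabilities given
    directly (follow-up = cycle length), small enough to assemble its
    11-state transition matrix by hand."""

    def est(p: float) -> t.TransitionEstimate:
        return t.TransitionEstimate("probability", p, 4.0)

    lines = [
        t.LineInputs(1, {
            "treatment_to_response": est(0.2),
            "treatment_to_remission": est(0.1),
            "treatment_to_nonresponse": est(0.3),
            "response_to_remission": est(0.15),
            "response_to_relapse": est(0.05),
            "remission_to_relapse": est(0.08),
        }),
        t.LineInputs(2, {
            "treatment_to_response": est(0.1),
            "treatment_to_remission": est(0.05),
            "treatment_to_nonresponse": est(0.4),
            "response_to_remission": est(0.1),
            "response_to_relapse": est(0.1),
            "remission_to_relapse": est(0.12),
        }),
    ]
    background = {s: 100.0 for s in t.HEALTH_STATES}
    costs = {
        k: t.CostComponents(
            drug_acquisition=50.0,
            administration_monitoring=20.0,
            background_utilization=dict(background),
        )
        for k in (1, 2)
    }
    strat = t.StrategyInputs(
        name="S",
        effects={
            "treatment_to_response": t.EffectEstimate(rr[0]),
            "treatment_to_remission": t.EffectEstimate(rr[1]),
            "remission_to_relapse": t.EffectEstimate(rr[2]),
        },
        costs=costs,
    )
    return t.ParameterSet(
        strategies={"S": strat},
        lines=lines,
        utilities=t.UtilitySet(
            {"treatment": 0.6, "response": 0.7, "remission": 0.85,
             "nonresponse": 0.55, "relapse": 0.5}
        ),
        mortality=t.TransitionEstimate("probability", mortality_p, 4.0),
    )


@pytest.fixture()
def toy_ps() -> t.ParameterSet:
    return make_toy_ps()


def microsimulate(
    P: np.ndarray, start: int, n_agents: int, n_cycles: int, seed: int
) -> np.ndarray:
    """Individual-level simulation of the same transition structure:
    each agent samples its next state from its current row's categorical
    distribution each cycle.  Returns occupancy fractions of shape
    (n_cycles + 1, n_states)."""
    rng = np.random.default_rng(seed)
    n_states = P.shape[0]
    cum = P.cumsum(axis=1)
    states = np.full(n_agents, start, dtype=np.int64)
    occ = np.zeros((n_cycles + 1, n_states))
    occ[0] = np.bincount(states, minlength=n_states) / n_agents
    for cycle in range(1, n_cycles + 1):
        u = rng.random(n_agents)
        states = (cum[states] < u[:, None]).sum(axis=1)
        occ[cycle] = np.bincount(states, minlength=n_states) / n_agents
    return occ
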