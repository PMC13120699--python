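"""Synthetic model inputs.

Real applications of this model feed it a study-specific input table
(line-specific baseline transitions, strategy relative risks, unit costs,
utilities, mortality, distributional assumptions).  This module generates
complete, validated :class:`~trdcea.parameters.ParameterSet` instances
with that structure so every pipeline stage is testable without external
data:

* :func:`base_case_parameter_set` — a hand-tuned deterministic input set
  whose strategy ordering reproduces the qualitative base-case pattern of
  the seven-arm Hong Kong comparison (combination therapy cheapest
  nondominated arm; rTMS strictly dominated by esketamine; ECT most
  costly and most effective).  The printed per-patient totals of that
  analysis are *not* targeted — reproducing them requires its full input
  appendix, which loads through the same schema.
* :func:`generate_parameter_set` — seeded random input sets within
  realistic ranges, for property testing.
* :data:`REFERENCE_TOTALS` — the published per-patient discounted totals
  of the seven-arm comparison, used as printed-table inputs by the
  examples and the reproduction script.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .parameters import (
    HEALTH_STATES,
    RR_TRANSITIONS,
    CostComponents,
    DistributionSpec,
    EconomicSettings,
    EffectEstimate,
    LineInputs,
    ParameterSet,
    StrategyInputs,
    TransitionEstimate,
    UtilitySet,
    ValidationError,
    flatten_parameters,
    get_param,
    validate_parameter_set,
)

__all__ = [
    "STRATEGY_NAMES",
    "REFERENCE_TOTALS",
    "FixtureConfig",
    "default_settings",
    "base_case_parameter_set",
    "generate_parameter_set",
    "degenerate_distributions",
]

#: Canonical strategy roster: augmentation (oral antidepressant plus
#: antipsychotic or lithium; the reference comparator), antidepressant
#: combination, psychotherapy alone, psychotherapy plus antidepressant,
#: esketamine nasal spray plus antidepressant, repetitive transcranial
#: magnetic stimulation plus antidepressant, electroconvulsive therapy
#: plus antidepressant.
STRATEGY_NAMES = (
    "AUG",
    "COM",
    "PSY alone",
    "PSY+AD",
    "ESK+AD",
    "rTMS+AD",
    "ECT+AD",
)

#: Published per-patient discounted totals (cost US$, QALYs) for the
#: seven third-line TRD strategies in the Hong Kong public-payer
#: base case (5-year horizon, 3%/year discounting).  These serve as
#: printed-table *inputs* to the comparison and frontier routines in the
#: examples and the reproduction script.
REFERENCE_TOTALS: dict[str, tuple[float, float]] = {
    "AUG": (16_185.0, 2.895),
    "COM": (16_163.0, 2.903),
    "PSY alone": (19_538.0, 2.879),
    "PSY+AD": (21_555.0, 2.926),
    "ESK+AD": (29_061.0, 2.950),
    "rTMS+AD": (30_607.0, 2.936),
    "ECT+AD": (46_471.0, 3.004),
}


def default_settings() -> EconomicSettings:
    """Base-case economic settings: WTP US$50,000/QALY, 3%/year discount,
    4-week cycles, 5-year horizon."""
    return EconomicSettings()


# ---------------------------------------------------------------------------
# Hand-tuned base-case fixture
# ---------------------------------------------------------------------------

# Baseline (oral-antidepressant anchor) transition inputs per line, as
# (rate, follow-up weeks).  Response/remission decline and relapse rises
# with line index, echoing increasing treatment resistance across
# successive STAR*D-style levels.
_BASE_TRANSITIONS = {
    1: {
        "treatment_to_response": (0.28, 12.0),
        "treatment_to_remission": (0.28, 12.0),
        "treatment_to_nonresponse": (0.30, 12.0),
        "response_to_remission": (0.40, 26.0),
        "response_to_relapse": (0.25, 26.0),
        "remission_to_relapse": (0.45, 52.0),
    },
    2: {
        "treatment_to_response": (0.20, 12.0),
        "treatment_to_remission": (0.16, 12.0),
        "treatment_to_nonresponse": (0.42, 12.0),
        "response_to_remission": (0.35, 26.0),
        "response_to_relapse": (0.30, 26.0),
        "remission_to_relapse": (0.60, 52.0),
    },
    3: {
        "treatment_to_response": (0.16, 12.0),
        "treatment_to_remission": (0.13, 12.0),
        "treatment_to_nonresponse": (0.48, 12.0),
        "response_to_remission": (0.30, 26.0),
        "response_to_relapse": (0.35, 26.0),
        "remission_to_relapse": (0.70, 52.0),
    },
}

# Line-1 relative risks versus the oral-antidepressant anchor:
# (treatment->response, treatment->remission, remission->relapse).
# Subsequent lines use identical downstream care in every arm (RR = 1).
_BASE_RRS = {
    "AUG": (1.40, 1.40, 0.85),
    "COM": (1.40, 1.45, 0.82),
    "PSY alone": (1.10, 1.05, 0.80),
    "PSY+AD": (1.45, 1.50, 0.72),
    "ESK+AD": (1.55, 1.60, 0.55),
    "rTMS+AD": (1.52, 1.55, 0.88),
    "ECT+AD": (1.95, 2.05, 0.58),
}

# Relative half-widths of the 95% intervals around each relative risk.
# The esketamine remission->relapse estimate carries the widest interval,
# reflecting reliance on a single maintenance trial.
_RR_CI = {
    ("ESK+AD", "remission_to_relapse"): (0.40, 0.76),
}
_RR_REL_CI = (0.85, 1.18)

# Line-1 cost components per 4-week cycle (US$): acquisition,
# administration/monitoring, procedure cost per session, sessions/cycle.
_BASE_COSTS = {
    "AUG": (40.0, 60.0, 0.0, 0.0),
    "COM": (30.0, 60.0, 0.0, 0.0),
    "PSY alone": (0.0, 30.0, 180.0, 8.0),
    "PSY+AD": (15.0, 60.0, 180.0, 8.0),
    "ESK+AD": (520.0, 260.0, 0.0, 0.0),
    "rTMS+AD": (15.0, 60.0, 350.0, 20.0),
    "ECT+AD": (15.0, 60.0, 2000.0, 8.0),
}

# Common downstream-line pharmacotherapy costs (all arms).
_LATER_LINE_COSTS = (45.0, 60.0, 0.0, 0.0)

# Background healthcare utilisation per state per 4-week cycle (US$),
# identical across strategies and lines.
_BACKGROUND = {
    "treatment": 180.0,
    "response": 120.0,
    "remission": 80.0,
    "nonresponse": 260.0,
    "relapse": 320.0,
}

_UTILITIES = {
    "treatment": 0.60,
    "response": 0.72,
    "remission": 0.85,
    "nonresponse": 0.57,
    "relapse": 0.55,
}

_ANNUAL_MORTALITY = 0.012  # all-cause, TRD population


def _attach_psa_distributions(ps: ParameterSet) -> None:
    """Assign a sampling distribution (with deterministic bounds) to every
    varied scalar: beta for probabilities and utilities, gamma for costs,
    lognormal for relative risks.  Zero-valued costs, session counts and
    unity downstream relative risks stay fixed (not varied)."""
    flat = flatten_parameters(ps)
    psa: dict[str, DistributionSpec] = {}
    for key, value in flat.items():
        parts = key.split(":")
        if parts[0] == "line" and parts[-1] == "value":
            lo, hi = max(value * 0.8, 1e-6), min(value * 1.2, 0.99)
            psa[key] = DistributionSpec.beta_from_mean_ci(value, lo, hi)
        elif key == "mortality:value":
            psa[key] = DistributionSpec.beta_from_mean_ci(
                value, value * 0.8, value * 1.2
            )
        elif parts[0] == "utility":
            lo, hi = max(value * 0.9, 0.0), min(value * 1.1, 0.99)
            psa[key] = DistributionSpec.beta_from_mean_ci(value, lo, hi)
        elif parts[0] == "strategy" and "rr" in parts:
            if "line" in parts:
                continue  # downstream unity RRs are structural, not varied
            name, ttype = parts[1], parts[-1]
            eff = ps.strategies[name].effects[ttype]
            if eff.ci_low is None or eff.ci_high is None:
                continue
            psa[key] = DistributionSpec.lognormal_from_ci(
                eff.rr, eff.ci_low, eff.ci_high
            )
        elif parts[0] == "strategy" and "cost" in parts:
            if value <= 0 or parts[-1] == "procedure_sessions_per_cycle":
                continue
            psa[key] = DistributionSpec.gamma_from_mean_ci(
                value, value * 0.75, value * 1.25
            )
        elif parts[0] == "named_cost":
            continue
    ps.psa_distributions = psa


def base_case_parameter_set() -> ParameterSet:
    """The packaged deterministic base-case input set (see module
    docstring for what its calibration does and does not target)."""
    lines = [
        LineInputs(
            line_index=k,
            transitions={
                t: TransitionEstimate("rate", r, fw)
                for t, (r, fw) in _BASE_TRANSITIONS[k].items()
            },
        )
        for k in sorted(_BASE_TRANSITIONS)
    ]

    strategies: dict[str, StrategyInputs] = {}
    for name in STRATEGY_NAMES:
        rr_resp, rr_rem, rr_rel = _BASE_RRS[name]
        effects = {}
        for ttype, rr in (
            ("treatment_to_response", rr_resp),
            ("treatment_to_remission", rr_rem),
            ("remission_to_relapse", rr_rel),
        ):
            lo, hi = _RR_CI.get(
                (name, ttype), (rr * _RR_REL_CI[0], rr * _RR_REL_CI[1])
            )
            effects[ttype] = EffectEstimate(rr, lo, hi)
        # Downstream lines: identical subsequent care in every arm.
        effects_by_line = {
            k: {
                t: EffectEstimate(1.0)
                for t in ("treatment_to_response", "treatment_to_remission",
                          "remission_to_relapse")
            }
            for k in (2, 3)
        }
        acq, adm, proc, sess = _BASE_COSTS[name]
        costs = {
            1: CostComponents(
                drug_acquisition=acq,
                administration_monitoring=adm,
                procedure_cost_per_session=proc,
                procedure_sessions_per_cycle=sess,
                background_utilization=dict(_BACKGROUND),
            )
        }
        for k in (2, 3):
            a2, m2, p2, s2 = _LATER_LINE_COSTS
            costs[k] = CostComponents(
                drug_acquisition=a2,
                administration_monitoring=m2,
                procedure_cost_per_session=p2,
                procedure_sessions_per_cycle=s2,
                background_utilization=dict(_BACKGROUND),
            )
        strategies[name] = StrategyInputs(
            name=name,
            effects=effects,
            effects_by_line=effects_by_line,
            costs=costs,
            maintenance_in_response_remission=True,
        )

    ps = ParameterSet(
        strategies=strategies,
        lines=lines,
        utilities=UtilitySet(dict(_UTILITIES)),
        mortality=TransitionEstimate("rate", _ANNUAL_MORTALITY, 52.0),
        named_costs={"esk_nurse_led_admin_per_cycle": 100.0},
    )
    _attach_psa_distributions(ps)
    violations = validate_parameter_set(ps)
    if violations:  # pragma: no cover - guards the packaged fixture itself
        raise ValidationError("base-case fixture invalid:\n  " + "\n  ".join(violations))
    return ps


# ---------------------------------------------------------------------------
# Random fixture generation
# ---------------------------------------------------------------------------


@dataclass
class FixtureConfig:
    """Ranges for seeded random input-set generation.

    Baseline response/remission decline and relapse rises with line index
    (multiplicative per-line factors), echoing increasing treatment
    resistance; utilities are drawn in decreasing order remission >=
    response >= nonresponse; probabilities/utilities receive beta
    distributions, costs gamma, relative risks lognormal.
    """

    seed: int = 0
    n_lines: int = 3
    response_rate: tuple[float, float] = (0.24, 0.32)  # line 1, over 12 weeks
    remission_rate: tuple[float, float] = (0.24, 0.32)
    nonresponse_rate: tuple[float, float] = (0.28, 0.38)
    consolidation_rate: tuple[float, float] = (0.30, 0.50)  # response->remission, 26 w
    early_relapse_rate: tuple[float, float] = (0.20, 0.30)  # response->relapse, 26 w
    relapse_rate: tuple[float, float] = (0.40, 0.55)  # remission->relapse, 52 w
    line_decline: tuple[float, float] = (0.60, 0.90)  # response/remission per line
    line_worsen: tuple[float, float] = (1.10, 1.35)  # nonresponse/relapse per line
    rr_response: tuple[float, float] = (1.0, 1.7)
    rr_remission: tuple[float, float] = (1.0, 1.7)
    rr_relapse: tuple[float, float] = (0.5, 1.0)
    acquisition_cost: tuple[float, float] = (10.0, 500.0)
    administration_cost: tuple[float, float] = (30.0, 250.0)
    background_scale: tuple[float, float] = (0.7, 1.3)  # on the base profile
    annual_mortality: tuple[float, float] = (0.008, 0.020)
    strategy_names: tuple[str, ...] = STRATEGY_NAMES


def generate_parameter_set(config: FixtureConfig) -> ParameterSet:
    """Generate a complete validated input set from seeded draws within
    the configured ranges.  Output is a pure function of the config."""
    rng = np.random.default_rng(config.seed)

    def u(lohi: tuple[float, float]) -> float:
        return float(rng.uniform(*lohi))

    lines: list[LineInputs] = []
    resp, rem = u(config.response_rate), u(config.remission_rate)
    nonresp = u(config.nonresponse_rate)
    consol, early_rel = u(config.consolidation_rate), u(config.early_relapse_rate)
    relapse = u(config.relapse_rate)
    for k in range(1, config.n_lines + 1):
        if k > 1:
            decline = u(config.line_decline)
            worsen = u(config.line_worsen)
            resp *= decline
            rem *= decline
            consol *= decline
            nonresp = min(nonresp * worsen, 0.90)
            early_rel = min(early_rel * worsen, 0.90)
            relapse = min(relapse * worsen, 0.95)
        lines.append(
            LineInputs(
                line_index=k,
                transitions={
                    "treatment_to_response": TransitionEstimate("rate", resp, 12.0),
                    "treatment_to_remission": TransitionEstimate("rate", rem, 12.0),
                    "treatment_to_nonresponse": TransitionEstimate("rate", nonresp, 12.0),
                    "response_to_remission": TransitionEstimate("rate", consol, 26.0),
                    "response_to_relapse": TransitionEstimate("rate", early_rel, 26.0),
                    "remission_to_relapse": TransitionEstimate("rate", relapse, 52.0),
                },
            )
        )

    bg_scale = u(config.background_scale)
    background = {s: c * bg_scale for s, c in _BACKGROUND.items()}

    strategies: dict[str, StrategyInputs] = {}
    for name in config.strategy_names:
        effects = {}
        for ttype, lohi in (
            ("treatment_to_response", config.rr_response),
            ("treatment_to_remission", config.rr_remission),
            ("remission_to_relapse", config.rr_relapse),
        ):
            rr = u(lohi)
            effects[ttype] = EffectEstimate(rr, rr * 0.85, rr * 1.18)
        effects_by_line = {
            k: {
                t: EffectEstimate(1.0)
                for t in ("treatment_to_response", "treatment_to_remission",
                          "remission_to_relapse")
            }
            for k in range(2, config.n_lines + 1)
        }
        costs = {
            1: CostComponents(
                drug_acquisition=u(config.acquisition_cost),
                administration_monitoring=u(config.administration_cost),
                background_utilization=dict(background),
            )
        }
        for k in range(2, config.n_lines + 1):
            costs[k] = CostComponents(
                drug_acquisition=45.0,
                administration_monitoring=60.0,
                background_utilization=dict(background),
            )
        strategies[name] = StrategyInputs(
            name=name,
            effects=effects,
            effects_by_line=effects_by_line,
            costs=costs,
        )

    # Utilities drawn in decreasing severity order.
    u_rem = float(rng.uniform(0.78, 0.90))
    u_resp = float(rng.uniform(0.64, u_rem - 0.02))
    u_treat = float(rng.uniform(0.55, u_resp - 0.02))
    u_nonresp = float(rng.uniform(0.50, u_treat))
    u_relapse = float(rng.uniform(0.45, u_nonresp))
    utilities = UtilitySet(
        {
            "treatment": u_treat,
            "response": u_resp,
            "remission": u_rem,
            "nonresponse": u_nonresp,
            "relapse": u_relapse,
        }
    )

    ps = ParameterSet(
        strategies=strategies,
        lines=lines,
        utilities=utilities,
        mortality=TransitionEstimate("rate", u(config.annual_mortality), 52.0),
        named_costs={"esk_nurse_led_admin_per_cycle": 100.0},
    )
    _attach_psa_distributions(ps)
    violations = validate_parameter_set(ps)
    if violations:
        raise ValidationError(
            "generated parameter set invalid (infeasible config ranges):\n  "
            + "\n  ".join(violations)
        )
    return ps


def degenerate_distributions(ps: ParameterSet) -> ParameterSet:
    """Copy of ``ps`` with every sampling distribution collapsed to a
    point mass at the parameter's current value; a probabilistic run on
    the result reproduces the deterministic run exactly.  Idempotent."""
    out = ps.copy()
    out.psa_distributions = {
        key: DistributionSpec.fixed(get_param(out, key))
        for key in out.psa_distributions
    }
    return out
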