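"""Scenario analyses: declarative transforms of the model inputs.

Eight standard scenarios probe the esketamine arm's cost-effectiveness
under alternative dosing, delivery, pricing, discounting and time-grid
assumptions.  Each scenario is a :class:`ScenarioSpec` — an ordered list
of primitive edits applied to copies of the parameter set and settings —
except scenario 8, which is the closed-form cost-threshold solver
:func:`cost_threshold_solve`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .engine import StrategyOutcome, run_all_strategies
from .parameters import (
    COST_COMPONENTS,
    CostScheduleEntry,
    EconomicSettings,
    ParameterSet,
    ValidationError,
    validate_parameter_set,
)

__all__ = [
    "ScaleCost",
    "SetCost",
    "SetCycleWeeks",
    "SetDiscount",
    "SetHorizon",
    "ScenarioSpec",
    "apply_scenario",
    "standard_scenarios",
    "cost_threshold_solve",
    "run_scenario_suite",
]


@dataclass
class ScaleCost:
    """Multiply one cost component of one strategy by ``factor``; with
    ``from_cycle > 0`` the factor applies only from that (0-based) cycle
    onward, as a time-varying schedule entry."""

    strategy: str
    component: str
    factor: float
    from_cycle: int = 0
    line: int | None = None  # None = all lines


@dataclass
class SetCost:
    """Replace one cost component of one strategy/line with a value; a
    string ``"named:<key>"`` resolves against ``ParameterSet.named_costs``."""

    strategy: str
    component: str
    value: float | str
    line: int = 1


@dataclass
class SetCycleWeeks:
    weeks: int


@dataclass
class SetDiscount:
    rate: float


@dataclass
class SetHorizon:
    years: float


Edit = ScaleCost | SetCost | SetCycleWeeks | SetDiscount | SetHorizon


@dataclass
class ScenarioSpec:
    """One scenario: an id, a human-readable description, and the ordered
    primitive edits that realise it."""

    id: int
    description: str
    edits: list[Edit] = field(default_factory=list)


def _resolve_value(ps: ParameterSet, value: float | str) -> float:
    if isinstance(value, str):
        if not value.startswith("named:"):
            raise ValidationError(f"cost value reference must be 'named:<key>', got {value!r}")
        key = value.split(":", 1)[1]
        if key not in ps.named_costs:
            raise ValidationError(f"named cost {key!r} not present in parameter set")
        return ps.named_costs[key]
    return float(value)


def apply_scenario(
    spec: ScenarioSpec, ps: ParameterSet, settings: EconomicSettings
) -> tuple[ParameterSet, EconomicSettings]:
    """Apply a scenario's edits to copies of the inputs; the base inputs
    are never mutated, so the base case remains reproducible alongside
    every scenario run.  The transformed parameter set is revalidated."""
    out_ps = ps.copy()
    out_settings = EconomicSettings(**vars(settings))
    for edit in spec.edits:
        if isinstance(edit, ScaleCost):
            if edit.strategy not in out_ps.strategies:
                raise ValidationError(f"scenario {spec.id}: unknown strategy {edit.strategy!r}")
            strat = out_ps.strategies[edit.strategy]
            if edit.component not in COST_COMPONENTS:
                raise ValidationError(
                    f"scenario {spec.id}: unknown cost component {edit.component!r}"
                )
            if edit.from_cycle > 0:
                strat.cost_schedule.append(
                    CostScheduleEntry(edit.from_cycle, edit.component, edit.factor,
                                      edit.line)
                )
            else:
                lines = [edit.line] if edit.line is not None else list(strat.costs)
                for k in lines:
                    cc = strat.costs[k]
                    setattr(cc, edit.component,
                            getattr(cc, edit.component) * edit.factor)
        elif isinstance(edit, SetCost):
            strat = out_ps.strategies[edit.strategy]
            if edit.component not in COST_COMPONENTS:
                raise ValidationError(
                    f"scenario {spec.id}: unknown cost component {edit.component!r}"
                )
            setattr(strat.costs[edit.line], edit.component,
                    _resolve_value(out_ps, edit.value))
        elif isinstance(edit, SetCycleWeeks):
            out_settings.cycle_weeks = edit.weeks
        elif isinstance(edit, SetDiscount):
            out_settings.annual_discount_rate = edit.rate
        elif isinstance(edit, SetHorizon):
            out_settings.horizon_years = edit.years
        else:
            raise ValidationError(f"scenario {spec.id}: unknown edit {edit!r}")

    violations = validate_parameter_set(out_ps, out_settings.cycle_weeks)
    if violations:
        raise ValidationError(
            f"scenario {spec.id} produced an invalid parameter set:\n  "
            + "\n  ".join(violations)
        )
    return out_ps, out_settings


def standard_scenarios(esk: str = "ESK+AD") -> dict[int, ScenarioSpec]:
    """The seven transform scenarios (scenario 8 is the closed-form
    threshold solver, handled by :func:`run_scenario_suite`).

    1. Esketamine dosing thinned from weekly to biweekly after week 9:
       drug-acquisition and administration/monitoring costs halve from the
       third cycle onward (the first full cycle after the week-9 boundary
       on a 4-week grid).
    2. 8-week model cycles; every per-cycle probability is re-derived from
       its underlying rate, so transition opportunities thin consistently.
    3. Specialist-outpatient-clinic / psychiatric-day-hospital delivery
       replaced by a nurse-led intranasal administration and monitoring
       protocol (named cost ``esk_nurse_led_admin_per_cycle``).
    4. Esketamine dose reduced from 84 mg to 56 mg per session: with
       device-based linear pricing (three vs two 28 mg devices) the
       acquisition cost scales by 2/3.
    5. Annual discount rate 3.5% for costs and outcomes.
    6. 75% reduction in the esketamine acquisition price.
    7. 20-year (lifetime) analytic horizon.
    """
    return {
        1: ScenarioSpec(
            1,
            "Biweekly esketamine dosing after week 9",
            [
                ScaleCost(esk, "drug_acquisition", 0.5, from_cycle=2, line=1),
                ScaleCost(esk, "administration_monitoring", 0.5, from_cycle=2, line=1),
            ],
        ),
        2: ScenarioSpec(2, "8-week model cycle (extended follow-up interval)",
                        [SetCycleWeeks(8)]),
        3: ScenarioSpec(
            3,
            "Nurse-led intranasal administration and monitoring",
            [SetCost(esk, "administration_monitoring",
                     "named:esk_nurse_led_admin_per_cycle", line=1)],
        ),
        4: ScenarioSpec(4, "56 mg esketamine dose (2/3 device pricing)",
                        [ScaleCost(esk, "drug_acquisition", 2.0 / 3.0, line=1)]),
        5: ScenarioSpec(5, "3.5% annual discount rate", [SetDiscount(0.035)]),
        6: ScenarioSpec(6, "75% esketamine acquisition price reduction",
                        [ScaleCost(esk, "drug_acquisition", 0.25, line=1)]),
        7: ScenarioSpec(7, "20-year (lifetime) horizon", [SetHorizon(20.0)]),
    }


def cost_threshold_solve(
    reference: StrategyOutcome, target_qaly: float, wtp: float
) -> float:
    """Total target-arm cost at which its ICER versus the reference equals
    the willingness-to-pay threshold exactly, assuming unchanged
    effectiveness and linear cost scaling:
    ``cost = reference_cost + wtp x (target_qaly - reference_qaly)``.

    Raises
    ------
    ValidationError
        If the target yields no QALY gain over the reference (no finite
        cost makes the ICER equal a finite positive threshold).
    """
    if wtp < 0:
        raise ValidationError(f"wtp must be >= 0, got {wtp}")
    if target_qaly <= reference.qaly:
        raise ValidationError(
            f"target QALYs ({target_qaly}) must exceed reference QALYs "
            f"({reference.qaly}) for a finite cost threshold"
        )
    return reference.cost + wtp * (target_qaly - reference.qaly)


def run_scenario_suite(
    ps: ParameterSet,
    settings: EconomicSettings,
    specs: dict[int, ScenarioSpec] | None = None,
    target: str = "ESK+AD",
    reference: str = "AUG",
    include_threshold: bool = True,
) -> pd.DataFrame:
    """Run the base case (scenario 0) and every scenario; return one row
    per scenario per strategy with discounted totals and the ICER of the
    target arm versus the reference, plus (scenario 8) the solved
    threshold cost at the base-case WTP."""
    if specs is None:
        specs = standard_scenarios(esk=target)

    rows: list[dict] = []

    def add_block(scenario_id: int, description: str, ps_s: ParameterSet,
                  settings_s: EconomicSettings) -> dict[str, StrategyOutcome]:
        outcomes = run_all_strategies(ps_s, settings_s)
        t, r = outcomes[target], outcomes[reference]
        dq = t.qaly - r.qaly
        icer_vs_ref = (t.cost - r.cost) / dq if dq != 0 else float("nan")
        for name, o in outcomes.items():
            rows.append(
                {
                    "scenario": scenario_id,
                    "description": description,
                    "strategy": name,
                    "cost": o.cost,
                    "qaly": o.qaly,
                    "icer_target_vs_ref": icer_vs_ref,
                }
            )
        return outcomes

    base_outcomes = add_block(0, "Base case", ps, settings)

    for sid in sorted(specs):
        ps_s, settings_s = apply_scenario(specs[sid], ps, settings)
        add_block(sid, specs[sid].description, ps_s, settings_s)

    if include_threshold:
        threshold = cost_threshold_solve(
            base_outcomes[reference], base_outcomes[target].qaly, settings.wtp
        )
        rows.append(
            {
                "scenario": 8,
                "description": (
                    f"Target-arm total cost for ICER = WTP ({settings.wtp:,.0f})"
                ),
                "strategy": target,
                "cost": threshold,
                "qaly": base_outcomes[target].qaly,
                "icer_target_vs_ref": settings.wtp,
            }
        )

    return pd.DataFrame(rows)
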