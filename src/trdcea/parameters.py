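"""Model inputs for the treatment-resistant-depression cost-effectiveness model.

This module defines every quantity the cohort model consumes — economic
settings, per-line baseline transition estimates, per-strategy relative
risks anchored on oral-antidepressant monotherapy, cost components, health
state utilities, mortality, and the distributional assumptions used by the
probabilistic sensitivity analysis — together with loading, saving,
conversion and validation utilities.

Conventions
-----------
* Currency is US dollars throughout; inputs expressed in Hong Kong dollars
  are divided by ``HKD_PER_USD`` (7.80) at load time.
* Cost components are entered per *base* model cycle of 4 weeks
  (``BASE_CYCLE_WEEKS``).  When the engine runs on a different cycle
  length, time-proportional components are rescaled; see ``engine``.
* Transition inputs are stored as the originally observed rate (or
  probability) plus its follow-up duration, and converted to per-cycle
  probabilities on demand with :func:`rate_to_probability`, so a change of
  cycle length re-derives every probability consistently.
"""

from __future__ import annotations

import copy
import csv
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "HEALTH_STATES",
    "TRANSITION_TYPES",
    "RR_TRANSITIONS",
    "COST_COMPONENTS",
    "BASE_CYCLE_WEEKS",
    "HKD_PER_USD",
    "EconomicSettings",
    "TransitionEstimate",
    "EffectEstimate",
    "LineInputs",
    "CostComponents",
    "CostScheduleEntry",
    "UtilitySet",
    "DistributionSpec",
    "StrategyInputs",
    "ParameterSet",
    "ValidationError",
    "rate_to_probability",
    "probability_to_rate",
    "apply_relative_risk",
    "validate_parameter_set",
    "load_parameter_set",
    "save_parameter_set",
    "load_settings",
    "flatten_parameters",
    "get_param",
    "set_param",
    "parameter_rng",
]

#: Health states within each treatment line, in fixed enumeration order.
HEALTH_STATES = ("treatment", "response", "remission", "nonresponse", "relapse")

#: Transition types parameterised per treatment line.  Residual probability
#: mass stays in the originating state.
TRANSITION_TYPES = (
    "treatment_to_response",
    "treatment_to_remission",
    "treatment_to_nonresponse",
    "response_to_remission",
    "response_to_relapse",
    "remission_to_relapse",
)

#: Transitions to which strategy-specific relative risks may be applied.
RR_TRANSITIONS = (
    "treatment_to_response",
    "treatment_to_remission",
    "response_to_remission",
    "response_to_relapse",
    "remission_to_relapse",
)

#: Scalar per-cycle cost components of a treatment strategy.
COST_COMPONENTS = (
    "drug_acquisition",
    "administration_monitoring",
    "procedure_cost_per_session",
    "procedure_sessions_per_cycle",
)

#: Cycle length (weeks) at which per-cycle cost inputs are defined.
BASE_CYCLE_WEEKS = 4

#: Fixed exchange rate used to convert Hong Kong dollar inputs.
HKD_PER_USD = 7.80


class ValidationError(ValueError):
    """Raised when an input value violates its domain."""


# ---------------------------------------------------------------------------
# Economic settings
# ---------------------------------------------------------------------------


@dataclass
class EconomicSettings:
    """Analysis-level settings: WTP threshold, discounting, time grid.

    Parameters
    ----------
    wtp : float
        Willingness-to-pay threshold in US$ per QALY (base case 50,000,
        about one times Hong Kong GDP per capita).
    annual_discount_rate : float
        Annual discount rate applied to both costs and health outcomes
        (base case 0.03).
    cycle_weeks : int
        Model cycle length in weeks (4 in the base case; 8 in the
        extended-follow-up structural scenario).
    horizon_years : float
        Analytic time horizon in years (base case 5; 20 for the
        lifetime-horizon scenario).
    weeks_per_year : float
        Time-conversion constant, fixed at 52.
    currency_conversion : float
        HKD per US$, used only when loading HKD-denominated files.
    half_cycle_correction : bool
        Whether to average start- and end-of-cycle occupancy when
        accruing outcomes.  Off by default.
    """

    wtp: float = 50_000.0
    annual_discount_rate: float = 0.03
    cycle_weeks: int = 4
    horizon_years: float = 5.0
    weeks_per_year: float = 52.0
    currency_conversion: float = HKD_PER_USD
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.wtp < 0:
            raise ValidationError(f"wtp must be >= 0, got {self.wtp}")
        if not 0 <= self.annual_discount_rate < 1:
            raise ValidationError(
                f"annual_discount_rate must be in [0, 1), got {self.annual_discount_rate}"
            )
        if self.cycle_weeks not in (4, 8):
            raise ValidationError(f"cycle_weeks must be 4 or 8, got {self.cycle_weeks}")
        if self.horizon_years <= 0:
            raise ValidationError(f"horizon_years must be > 0, got {self.horizon_years}")

    @property
    def n_cycles(self) -> int:
        """Number of full model cycles within the horizon."""
        return int(math.floor(self.horizon_years * self.weeks_per_year / self.cycle_weeks))

    @property
    def cycle_years(self) -> float:
        """Length of one cycle in years."""
        return self.cycle_weeks / self.weeks_per_year


# ---------------------------------------------------------------------------
# Rate/probability conversion and relative risks
# ---------------------------------------------------------------------------


def rate_to_probability(r: float, followup_weeks: float, cycle_weeks: float) -> float:
    """Convert an event proportion observed over ``followup_weeks`` into a
    per-cycle probability under a constant-hazard assumption.

    ``p = 1 - exp(ln(1 - r) / t * c)`` with ``t`` the follow-up duration and
    ``c`` the cycle length, both in weeks.  When ``t == c`` the formula is the
    identity.

    Raises
    ------
    ValidationError
        If ``r`` is outside ``[0, 1)`` or a duration is nonpositive.
    """
    if not 0 <= r < 1:
        raise ValidationError(f"rate must be in [0, 1), got {r}")
    if followup_weeks <= 0:
        raise ValidationError(f"followup_weeks must be > 0, got {followup_weeks}")
    if cycle_weeks <= 0:
        raise ValidationError(f"cycle_weeks must be > 0, got {cycle_weeks}")
    return 1.0 - math.exp(math.log(1.0 - r) / followup_weeks * cycle_weeks)


def probability_to_rate(p: float, followup_weeks: float, cycle_weeks: float) -> float:
    """Inverse of :func:`rate_to_probability`: recover the proportion over
    ``followup_weeks`` from a per-cycle probability."""
    if not 0 <= p < 1:
        raise ValidationError(f"probability must be in [0, 1), got {p}")
    return 1.0 - math.exp(math.log(1.0 - p) / cycle_weeks * followup_weeks)


def apply_relative_risk(p_base: float, rr: float) -> float:
    """Apply a relative risk on the probability scale, clamping at 1."""
    if rr <= 0:
        raise ValidationError(f"relative risk must be > 0, got {rr}")
    if not 0 <= p_base <= 1:
        raise ValidationError(f"baseline probability must be in [0, 1], got {p_base}")
    return min(p_base * rr, 1.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class TransitionEstimate:
    """A transition input as originally observed: a rate or probability
    ``value`` over ``followup_weeks`` weeks of follow-up."""

    kind: str  # "rate" or "probability"
    value: float
    followup_weeks: float

    def __post_init__(self) -> None:
        if self.kind not in ("rate", "probability"):
            raise ValidationError(f"kind must be 'rate' or 'probability', got {self.kind!r}")
        if not 0 <= self.value < 1:
            raise ValidationError(f"transition value must be in [0, 1), got {self.value}")
        if self.followup_weeks <= 0:
            raise ValidationError(f"followup_weeks must be > 0, got {self.followup_weeks}")

    def per_cycle(self, cycle_weeks: float) -> float:
        """Per-cycle probability under the given cycle length."""
        return rate_to_probability(self.value, self.followup_weeks, cycle_weeks)


@dataclass
class EffectEstimate:
    """Relative risk of a transition versus the oral-antidepressant
    monotherapy anchor, with interval bounds for sensitivity analyses."""

    rr: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if self.rr <= 0:
            raise ValidationError(f"rr must be > 0, got {self.rr}")


@dataclass
class LineInputs:
    """Baseline (anchor) transition estimates for one treatment line.

    Line 1 is the third line of therapy since diagnosis; successive lines
    reflect increasing treatment resistance (STAR*D-style level anchoring).
    """

    line_index: int
    transitions: dict[str, TransitionEstimate]


@dataclass
class CostComponents:
    """Per-cycle cost components of one strategy on one line (US$ per
    4-week base cycle; see module docstring for cycle-length scaling)."""

    drug_acquisition: float = 0.0
    administration_monitoring: float = 0.0
    procedure_cost_per_session: float = 0.0
    procedure_sessions_per_cycle: float = 0.0
    background_utilization: dict[str, float] = field(default_factory=dict)

    @property
    def procedure_per_cycle(self) -> float:
        return self.procedure_cost_per_session * self.procedure_sessions_per_cycle


@dataclass
class CostScheduleEntry:
    """A time-varying multiplier on one cost component of one line, active
    from cycle index ``from_cycle`` (0-based) onward."""

    from_cycle: int
    component: str
    factor: float
    line: int | None = None  # None = all lines


@dataclass
class UtilitySet:
    """Health-state utility weights (QALY per year in the state), shared
    across strategies and lines."""

    values: dict[str, float]

    def __getitem__(self, state: str) -> float:
        return self.values[state]


@dataclass
class DistributionSpec:
    """Sampling distribution of one parameter for probabilistic analysis,
    plus the deterministic low/high bounds used for one-way analysis.

    Families: ``beta(alpha, beta)`` for probabilities/utilities,
    ``gamma(shape, scale)`` for costs, ``lognormal(mu, sigma)`` for
    relative risks, ``uniform(low, high)``, and ``fixed(value)``.
    """

    family: str
    params: dict[str, float]
    low: float | None = None
    high: float | None = None

    _FAMILIES = ("beta", "gamma", "lognormal", "uniform", "fixed")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ValidationError(f"unsupported distribution family {self.family!r}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "beta":
            return rng.beta(self.params["alpha"], self.params["beta"], size=n)
        if self.family == "gamma":
            return rng.gamma(self.params["shape"], self.params["scale"], size=n)
        if self.family == "lognormal":
            return rng.lognormal(self.params["mu"], self.params["sigma"], size=n)
        if self.family == "uniform":
            return rng.uniform(self.params["low"], self.params["high"], size=n)
        return np.full(n, self.params["value"])

    @property
    def mean(self) -> float:
        if self.family == "beta":
            a, b = self.params["alpha"], self.params["beta"]
            return a / (a + b)
        if self.family == "gamma":
            return self.params["shape"] * self.params["scale"]
        if self.family == "lognormal":
            return math.exp(self.params["mu"] + self.params["sigma"] ** 2 / 2)
        if self.family == "uniform":
            return (self.params["low"] + self.params["high"]) / 2
        return self.params["value"]

    # -- moment-matching constructors -------------------------------------

    @classmethod
    def beta_from_mean_ci(cls, mean: float, low: float, high: float) -> "DistributionSpec":
        """Beta distribution moment-matched to a mean and 95% interval
        (sd taken as interval width / 3.92)."""
        sd = max((high - low) / 3.92, 1e-9)
        var = sd * sd
        common = mean * (1 - mean) / var - 1
        common = max(common, 1e-6)
        return cls("beta", {"alpha": mean * common, "beta": (1 - mean) * common},
                   low=low, high=high)

    @classmethod
    def gamma_from_mean_ci(cls, mean: float, low: float, high: float) -> "DistributionSpec":
        """Gamma distribution moment-matched to a mean and 95% interval."""
        sd = max((high - low) / 3.92, 1e-9)
        shape = (mean / sd) ** 2
        scale = sd * sd / mean
        return cls("gamma", {"shape": shape, "scale": scale}, low=low, high=high)

    @classmethod
    def lognormal_from_ci(cls, mean: float, low: float, high: float) -> "DistributionSpec":
        """Lognormal with median ``mean`` and 95% interval ``(low, high)``
        on the ratio scale; the standard parameterisation for relative
        risks."""
        sigma = max((math.log(high) - math.log(low)) / 3.92, 1e-9)
        return cls("lognormal", {"mu": math.log(mean), "sigma": sigma}, low=low, high=high)

    @classmethod
    def fixed(cls, value: float) -> "DistributionSpec":
        return cls("fixed", {"value": value})


@dataclass
class StrategyInputs:
    """One treatment arm: relative-risk effects versus the anchor, cost
    components per line, and cost-accrual behaviour.

    ``effects`` holds line-1 relative risks; ``effects_by_line`` overrides
    them for specific later lines.  A transition absent from both maps uses
    RR = 1 — i.e. missing line-specific effects inherit the line-1 value.
    """

    name: str
    effects: dict[str, EffectEstimate] = field(default_factory=dict)
    effects_by_line: dict[int, dict[str, EffectEstimate]] = field(default_factory=dict)
    costs: dict[int, CostComponents] = field(default_factory=dict)
    maintenance_in_response_remission: bool = True
    cost_schedule: list[CostScheduleEntry] = field(default_factory=list)

    def effect_for(self, line: int, transition: str) -> EffectEstimate | None:
        """Relative risk applicable to ``transition`` on ``line``; later
        lines inherit line-1 effects unless overridden."""
        by_line = self.effects_by_line.get(line)
        if by_line is not None and transition in by_line:
            return by_line[transition]
        return self.effects.get(transition)


@dataclass
class ParameterSet:
    """Complete model input set: the seven-strategy registry, per-line
    baseline transitions, utilities, mortality and PSA distributions."""

    strategies: dict[str, StrategyInputs]
    lines: list[LineInputs]
    utilities: UtilitySet
    mortality: TransitionEstimate
    psa_distributions: dict[str, DistributionSpec] = field(default_factory=dict)
    named_costs: dict[str, float] = field(default_factory=dict)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def strategy_names(self) -> list[str]:
        return list(self.strategies)

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# Parameter addressing (used by DSA/PSA and scenario edits)
# ---------------------------------------------------------------------------


def flatten_parameters(ps: ParameterSet) -> dict[str, float]:
    """Flatten every scalar model input into a ``key -> value`` mapping.

    Keys:
    ``line:{k}:{transition}:value``, ``mortality:value``,
    ``utility:{state}``, ``strategy:{name}:rr:{transition}``,
    ``strategy:{name}:line:{k}:rr:{transition}``,
    ``strategy:{name}:line:{k}:cost:{component}``,
    ``strategy:{name}:line:{k}:cost:background:{state}``,
    ``named_cost:{name}``.
    """
    out: dict[str, float] = {}
    for line in ps.lines:
        for ttype, est in line.transitions.items():
            out[f"line:{line.line_index}:{ttype}:value"] = est.value
    out["mortality:value"] = ps.mortality.value
    for state, u in ps.utilities.values.items():
        out[f"utility:{state}"] = u
    for name, strat in ps.strategies.items():
        for ttype, eff in strat.effects.items():
            out[f"strategy:{name}:rr:{ttype}"] = eff.rr
        for line_idx, effs in strat.effects_by_line.items():
            for ttype, eff in effs.items():
                out[f"strategy:{name}:line:{line_idx}:rr:{ttype}"] = eff.rr
        for line_idx, cc in strat.costs.items():
            for comp in COST_COMPONENTS:
                out[f"strategy:{name}:line:{line_idx}:cost:{comp}"] = getattr(cc, comp)
            for state, v in cc.background_utilization.items():
                out[f"strategy:{name}:line:{line_idx}:cost:background:{state}"] = v
    for cname, v in ps.named_costs.items():
        out[f"named_cost:{cname}"] = v
    return out


def _locate(ps: ParameterSet, key: str):
    """Resolve a flat key to (container, attribute-or-index) for get/set."""
    parts = key.split(":")
    if parts[0] == "line":
        line = next(l for l in ps.lines if l.line_index == int(parts[1]))
        return line.transitions[parts[2]], "value"
    if parts[0] == "mortality":
        return ps.mortality, "value"
    if parts[0] == "utility":
        return ps.utilities.values, parts[1]
    if parts[0] == "named_cost":
        return ps.named_costs, parts[1]
    if parts[0] == "strategy":
        strat = ps.strategies[parts[1]]
        rest = parts[2:]
        if rest[0] == "rr":
            return strat.effects[rest[1]], "rr"
        if rest[0] == "line":
            line_idx = int(rest[1])
            if rest[2] == "rr":
                return strat.effects_by_line[line_idx][rest[3]], "rr"
            if rest[2] == "cost":
                cc = strat.costs[line_idx]
                if rest[3] == "background":
                    return cc.background_utilization, rest[4]
                return cc, rest[3]
    raise KeyError(f"unrecognised parameter key {key!r}")


def get_param(ps: ParameterSet, key: str) -> float:
    obj, attr = _locate(ps, key)
    if isinstance(obj, dict):
        return obj[attr]
    return getattr(obj, attr)


def set_param(ps: ParameterSet, key: str, value: float) -> None:
    """Set a scalar model input in place by its flat key."""
    obj, attr = _locate(ps, key)
    if isinstance(obj, dict):
        obj[attr] = value
    else:
        setattr(obj, attr, value)


def parameter_rng(master_seed: int, key: str) -> np.random.Generator:
    """Independent generator for one parameter: a substream keyed by the
    master seed and a stable hash of the parameter key, so adding or
    removing a parameter never perturbs another parameter's draws."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed), zlib.crc32(key.encode())])
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_parameter_set(
    ps: ParameterSet, cycle_weeks: float = BASE_CYCLE_WEEKS
) -> list[str]:
    """Check every domain invariant; return a list of violation messages
    (empty iff the set is valid).  Violations are data, not exceptions."""
    v: list[str] = []

    if not ps.strategies:
        v.append("strategies: registry is empty")
    if len(ps.lines) < 1:
        v.append("lines: at least one treatment line required")

    line_indices = [l.line_index for l in ps.lines]
    if line_indices != list(range(1, len(ps.lines) + 1)):
        v.append(f"lines: indices must be 1..L contiguous, got {line_indices}")

    for line in ps.lines:
        for ttype in TRANSITION_TYPES:
            if ttype not in line.transitions:
                v.append(f"line {line.line_index}: missing transition {ttype}")
        for ttype, est in line.transitions.items():
            if not 0 <= est.value < 1:
                v.append(
                    f"line {line.line_index}:{ttype}: value {est.value} outside [0, 1)"
                )
            if est.followup_weeks <= 0:
                v.append(
                    f"line {line.line_index}:{ttype}: followup_weeks "
                    f"{est.followup_weeks} must be > 0"
                )

    if not 0 <= ps.mortality.value < 1:
        v.append(f"mortality: value {ps.mortality.value} outside [0, 1)")

    for state in HEALTH_STATES:
        if state not in ps.utilities.values:
            v.append(f"utilities: missing state {state}")
    for state, u in ps.utilities.values.items():
        if not -1 <= u <= 1:
            v.append(f"utility:{state}: {u} outside [-1, 1]")
    uv = ps.utilities.values
    if all(s in uv for s in ("remission", "response", "nonresponse")):
        if not (uv["remission"] >= uv["response"] >= uv["nonresponse"]):
            v.append(
                "utilities: ordering remission >= response >= nonresponse violated "
                f"({uv['remission']}, {uv['response']}, {uv['nonresponse']})"
            )

    for name, strat in ps.strategies.items():
        if strat.name != name:
            v.append(f"strategy {name}: registry key differs from name {strat.name!r}")
        all_effects: list[tuple[str, EffectEstimate]] = list(strat.effects.items())
        for effs in strat.effects_by_line.values():
            all_effects.extend(effs.items())
        for ttype, eff in all_effects:
            if ttype not in RR_TRANSITIONS:
                v.append(f"strategy {name}: RR on non-adjustable transition {ttype}")
            if eff.rr <= 0:
                v.append(f"strategy {name}:rr:{ttype}: RR {eff.rr} must be > 0")
            if eff.ci_low is not None and eff.ci_high is not None:
                if not eff.ci_low <= eff.rr <= eff.ci_high:
                    v.append(
                        f"strategy {name}:rr:{ttype}: CI ({eff.ci_low}, {eff.ci_high}) "
                        f"does not bracket RR {eff.rr}"
                    )
        for line in ps.lines:
            if line.line_index not in strat.costs:
                v.append(f"strategy {name}: missing costs for line {line.line_index}")
                continue
            cc = strat.costs[line.line_index]
            for comp in COST_COMPONENTS:
                if getattr(cc, comp) < 0:
                    v.append(
                        f"strategy {name}:line:{line.line_index}:cost:{comp}: "
                        f"{getattr(cc, comp)} must be >= 0"
                    )
            for state in HEALTH_STATES:
                if state not in cc.background_utilization:
                    v.append(
                        f"strategy {name}:line:{line.line_index}: missing background "
                        f"cost for state {state}"
                    )
                elif cc.background_utilization[state] < 0:
                    v.append(
                        f"strategy {name}:line:{line.line_index}:cost:background:"
                        f"{state}: must be >= 0"
                    )

        # Effective outgoing probabilities (baseline x RR, before mortality)
        # must leave nonnegative residual mass in every living state.
        for line in ps.lines:
            if line.line_index not in strat.costs:
                continue
            if not all(t in line.transitions for t in TRANSITION_TYPES):
                continue
            out_by_state = {
                "treatment": (
                    "treatment_to_response",
                    "treatment_to_remission",
                    "treatment_to_nonresponse",
                ),
                "response": ("response_to_remission", "response_to_relapse"),
                "remission": ("remission_to_relapse",),
            }
            for state, ttypes in out_by_state.items():
                total = 0.0
                for ttype in ttypes:
                    p = line.transitions[ttype].per_cycle(cycle_weeks)
                    eff = strat.effect_for(line.line_index, ttype)
                    if eff is not None:
                        p = apply_relative_risk(p, eff.rr)
                    total += p
                if total > 1 + 1e-12:
                    v.append(
                        f"strategy {name}:line:{line.line_index}: outgoing "
                        f"probabilities from {state} sum to {total:.4f} > 1"
                    )

    flat = flatten_parameters(ps)
    for key, spec in ps.psa_distributions.items():
        if key not in flat:
            v.append(f"psa_distributions: key {key!r} not present in parameter set")
            continue
        if spec.low is not None and spec.high is not None and spec.low > spec.high:
            v.append(f"psa_distributions:{key}: low {spec.low} > high {spec.high}")

    return v


# ---------------------------------------------------------------------------
# Serialisation: JSON (nested) and CSV (long format)
# ---------------------------------------------------------------------------


def _transition_to_json(est: TransitionEstimate) -> dict:
    return {"kind": est.kind, "value": est.value, "followup_weeks": est.followup_weeks}


def _effect_to_json(eff: EffectEstimate) -> dict:
    d: dict = {"rr": eff.rr}
    if eff.ci_low is not None:
        d["ci_low"] = eff.ci_low
    if eff.ci_high is not None:
        d["ci_high"] = eff.ci_high
    return d


def parameter_set_to_json(ps: ParameterSet) -> dict:
    """Nested JSON-serialisable representation (canonical on-disk schema)."""
    return {
        "schema_version": 1,
        "currency": "USD",
        "mortality": _transition_to_json(ps.mortality),
        "utilities": dict(ps.utilities.values),
        "named_costs": dict(ps.named_costs),
        "lines": [
            {
                "line_index": line.line_index,
                "transitions": {
                    t: _transition_to_json(est) for t, est in line.transitions.items()
                },
            }
            for line in ps.lines
        ],
        "strategies": {
            name: {
                "effects": {t: _effect_to_json(e) for t, e in s.effects.items()},
                "effects_by_line": {
                    str(k): {t: _effect_to_json(e) for t, e in effs.items()}
                    for k, effs in s.effects_by_line.items()
                },
                "maintenance_in_response_remission": s.maintenance_in_response_remission,
                "costs": {
                    str(k): {
                        "drug_acquisition": cc.drug_acquisition,
                        "administration_monitoring": cc.administration_monitoring,
                        "procedure_cost_per_session": cc.procedure_cost_per_session,
                        "procedure_sessions_per_cycle": cc.procedure_sessions_per_cycle,
                        "background_utilization": dict(cc.background_utilization),
                    }
                    for k, cc in s.costs.items()
                },
                "cost_schedule": [
                    {
                        "from_cycle": e.from_cycle,
                        "component": e.component,
                        "factor": e.factor,
                        "line": e.line,
                    }
                    for e in s.cost_schedule
                ],
            }
            for name, s in ps.strategies.items()
        },
        "psa_distributions": {
            key: {
                "family": d.family,
                "params": dict(d.params),
                "low": d.low,
                "high": d.high,
            }
            for key, d in ps.psa_distributions.items()
        },
    }


def parameter_set_from_json(doc: Mapping) -> ParameterSet:
    scale = 1.0
    if doc.get("currency", "USD") == "HKD":
        scale = 1.0 / HKD_PER_USD

    def _trans(d: Mapping) -> TransitionEstimate:
        return TransitionEstimate(d["kind"], d["value"], d["followup_weeks"])

    def _eff(d: Mapping) -> EffectEstimate:
        return EffectEstimate(d["rr"], d.get("ci_low"), d.get("ci_high"))

    lines = [
        LineInputs(
            line_index=ld["line_index"],
            transitions={t: _trans(td) for t, td in ld["transitions"].items()},
        )
        for ld in doc["lines"]
    ]
    strategies: dict[str, StrategyInputs] = {}
    for name, sd in doc["strategies"].items():
        strategies[name] = StrategyInputs(
            name=name,
            effects={t: _eff(e) for t, e in sd.get("effects", {}).items()},
            effects_by_line={
                int(k): {t: _eff(e) for t, e in effs.items()}
                for k, effs in sd.get("effects_by_line", {}).items()
            },
            maintenance_in_response_remission=sd.get(
                "maintenance_in_response_remission", True
            ),
            costs={
                int(k): CostComponents(
                    drug_acquisition=cd["drug_acquisition"] * scale,
                    administration_monitoring=cd["administration_monitoring"] * scale,
                    procedure_cost_per_session=cd["procedure_cost_per_session"] * scale,
                    procedure_sessions_per_cycle=cd["procedure_sessions_per_cycle"],
                    background_utilization={
                        s: c * scale for s, c in cd["background_utilization"].items()
                    },
                )
                for k, cd in sd["costs"].items()
            },
            cost_schedule=[
                CostScheduleEntry(
                    e["from_cycle"], e["component"], e["factor"], e.get("line")
                )
                for e in sd.get("cost_schedule", [])
            ],
        )
    psa = {
        key: DistributionSpec(d["family"], dict(d["params"]), d.get("low"), d.get("high"))
        for key, d in doc.get("psa_distributions", {}).items()
    }
    return ParameterSet(
        strategies=strategies,
        lines=lines,
        utilities=UtilitySet(dict(doc["utilities"])),
        mortality=_trans(doc["mortality"]),
        psa_distributions=psa,
        named_costs={k: v * scale for k, v in doc.get("named_costs", {}).items()},
    )


_CSV_COLUMNS = (
    "strategy",
    "line",
    "parameter",
    "value",
    "low",
    "high",
    "dist_family",
    "dist_p1",
    "dist_p2",
)

# Ordered (p1, p2) names per distribution family for the 2-column CSV layout.
_DIST_PARAM_ORDER = {
    "beta": ("alpha", "beta"),
    "gamma": ("shape", "scale"),
    "lognormal": ("mu", "sigma"),
    "uniform": ("low", "high"),
    "fixed": ("value", None),
}


def _csv_rows(ps: ParameterSet) -> Iterable[dict]:
    """Long-format rows.  Each scalar input is one row; the PSA
    distribution and DSA bounds ride on the row whose key matches."""
    psa = ps.psa_distributions

    def row(strategy: str, line, parameter: str, value: float, key: str | None = None):
        r = {c: "" for c in _CSV_COLUMNS}
        r.update(strategy=strategy, line=line if line is not None else "",
                 parameter=parameter, value=repr(float(value)))
        if key is not None and key in psa:
            d = psa[key]
            r["dist_family"] = d.family
            p1, p2 = _DIST_PARAM_ORDER[d.family]
            r["dist_p1"] = repr(float(d.params[p1]))
            r["dist_p2"] = repr(float(d.params[p2])) if p2 else ""
            if d.low is not None:
                r["low"] = repr(float(d.low))
            if d.high is not None:
                r["high"] = repr(float(d.high))
        return r

    for line in ps.lines:
        k = line.line_index
        for ttype, est in line.transitions.items():
            yield row("", k, f"{ttype}.{est.kind}", est.value,
                      key=f"line:{k}:{ttype}:value")
            yield row("", k, f"{ttype}.followup_weeks", est.followup_weeks)
    yield row("", None, f"mortality.{ps.mortality.kind}", ps.mortality.value,
              key="mortality:value")
    yield row("", None, "mortality.followup_weeks", ps.mortality.followup_weeks)
    for state, u in ps.utilities.values.items():
        yield row("", None, f"utility.{state}", u, key=f"utility:{state}")
    for cname, v in ps.named_costs.items():
        yield row("", None, f"named_cost.{cname}", v, key=f"named_cost:{cname}")
    for name, s in ps.strategies.items():
        yield row(name, None, "maintenance_in_response_remission",
                  float(s.maintenance_in_response_remission))
        if s.cost_schedule:
            raise ValidationError(
                "CSV format does not carry time-varying cost schedules; "
                "use the JSON format"
            )
        for ttype, eff in s.effects.items():
            r = row(name, None, f"rr.{ttype}", eff.rr, key=f"strategy:{name}:rr:{ttype}")
            if not r["low"] and eff.ci_low is not None:
                r["low"] = repr(float(eff.ci_low))
            if not r["high"] and eff.ci_high is not None:
                r["high"] = repr(float(eff.ci_high))
            yield r
        for line_idx, effs in s.effects_by_line.items():
            for ttype, eff in effs.items():
                r = row(name, line_idx, f"rr.{ttype}", eff.rr,
                        key=f"strategy:{name}:line:{line_idx}:rr:{ttype}")
                if not r["low"] and eff.ci_low is not None:
                    r["low"] = repr(float(eff.ci_low))
                if not r["high"] and eff.ci_high is not None:
                    r["high"] = repr(float(eff.ci_high))
                yield r
        for line_idx, cc in s.costs.items():
            for comp in COST_COMPONENTS:
                yield row(name, line_idx, f"cost.{comp}", getattr(cc, comp),
                          key=f"strategy:{name}:line:{line_idx}:cost:{comp}")
            for state, v in cc.background_utilization.items():
                yield row(name, line_idx, f"cost.background.{state}", v,
                          key=f"strategy:{name}:line:{line_idx}:cost:background:{state}")


def _parameter_set_from_csv_rows(rows: list[dict]) -> ParameterSet:
    lines: dict[int, LineInputs] = {}
    strategies: dict[str, StrategyInputs] = {}
    utilities: dict[str, float] = {}
    named_costs: dict[str, float] = {}
    psa: dict[str, DistributionSpec] = {}
    mortality_parts: dict[str, float] = {}

    pending_transitions: dict[tuple[int, str], dict] = {}
    pending_ci: dict[str, tuple[float | None, float | None]] = {}

    def maybe_float(s: str) -> float | None:
        return float(s) if s not in ("", None) else None

    def record_dist(key: str, r: dict) -> None:
        fam = r.get("dist_family", "")
        low, high = maybe_float(r.get("low", "")), maybe_float(r.get("high", ""))
        if fam:
            p1n, p2n = _DIST_PARAM_ORDER[fam]
            params = {p1n: float(r["dist_p1"])}
            if p2n:
                params[p2n] = float(r["dist_p2"])
            psa[key] = DistributionSpec(fam, params, low, high)
        if low is not None or high is not None:
            pending_ci[key] = (low, high)

    def get_strategy(name: str) -> StrategyInputs:
        if name not in strategies:
            strategies[name] = StrategyInputs(name=name)
        return strategies[name]

    for r in rows:
        strat, line_s, param = r["strategy"], r["line"], r["parameter"]
        value = float(r["value"])
        line_idx = int(float(line_s)) if line_s not in ("", None) else None
        if not strat:
            if param.startswith("mortality."):
                field_name = param.split(".", 1)[1]
                mortality_parts[field_name] = value
                if field_name in ("rate", "probability"):
                    mortality_parts["kind"] = field_name  # type: ignore[assignment]
                    record_dist("mortality:value", r)
            elif param.startswith("utility."):
                state = param.split(".", 1)[1]
                utilities[state] = value
                record_dist(f"utility:{state}", r)
            elif param.startswith("named_cost."):
                cname = param.split(".", 1)[1]
                named_costs[cname] = value
                record_dist(f"named_cost:{cname}", r)
            else:  # baseline transition rows, keyed by line
                assert line_idx is not None, f"transition row without line: {param}"
                ttype, field_name = param.rsplit(".", 1)
                slot = pending_transitions.setdefault((line_idx, ttype), {})
                if field_name in ("rate", "probability"):
                    slot["kind"] = field_name
                    slot["value"] = value
                    record_dist(f"line:{line_idx}:{ttype}:value", r)
                else:
                    slot[field_name] = value
        else:
            s = get_strategy(strat)
            if param == "maintenance_in_response_remission":
                s.maintenance_in_response_remission = bool(value)
            elif param.startswith("rr."):
                ttype = param.split(".", 1)[1]
                key = (
                    f"strategy:{strat}:rr:{ttype}"
                    if line_idx is None
                    else f"strategy:{strat}:line:{line_idx}:rr:{ttype}"
                )
                record_dist(key, r)
                ci = pending_ci.get(key, (None, None))
                eff = EffectEstimate(value, ci[0], ci[1])
                if line_idx is None:
                    s.effects[ttype] = eff
                else:
                    s.effects_by_line.setdefault(line_idx, {})[ttype] = eff
            elif param.startswith("cost."):
                assert line_idx is not None, f"cost row without line: {param}"
                cc = s.costs.setdefault(line_idx, CostComponents())
                rest = param.split(".", 1)[1]
                if rest.startswith("background."):
                    state = rest.split(".", 1)[1]
                    cc.background_utilization[state] = value
                    record_dist(
                        f"strategy:{strat}:line:{line_idx}:cost:background:{state}", r
                    )
                else:
                    setattr(cc, rest, value)
                    record_dist(f"strategy:{strat}:line:{line_idx}:cost:{rest}", r)

    for (line_idx, ttype), slot in pending_transitions.items():
        line = lines.setdefault(line_idx, LineInputs(line_idx, {}))
        line.transitions[ttype] = TransitionEstimate(
            slot["kind"], slot["value"], slot["followup_weeks"]
        )

    mortality = TransitionEstimate(
        str(mortality_parts.get("kind", "rate")),
        mortality_parts["rate" if mortality_parts.get("kind", "rate") == "rate"
                        else "probability"],
        mortality_parts["followup_weeks"],
    )
    return ParameterSet(
        strategies=strategies,
        lines=[lines[k] for k in sorted(lines)],
        utilities=UtilitySet(utilities),
        mortality=mortality,
        psa_distributions=psa,
        named_costs=named_costs,
    )


def save_parameter_set(ps: ParameterSet, path: str | Path) -> Path:
    """Write a parameter set to ``path``; format chosen by extension
    (``.json`` nested, ``.csv`` long format)."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(parameter_set_to_json(ps), indent=1))
    elif path.suffix == ".csv":
        with path.open("w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=_CSV_COLUMNS)
            writer.writeheader()
            for r in _csv_rows(ps):
                writer.writerow(r)
    else:
        raise ValidationError(f"unsupported parameter file extension: {path.suffix}")
    return path


def load_parameter_set(path: str | Path, validate: bool = True) -> ParameterSet:
    """Load a parameter set from a JSON or CSV file.

    Raises
    ------
    ValidationError
        If ``validate`` and any domain invariant is violated; the message
        lists every violation.
    """
    path = Path(path)
    if path.suffix == ".json":
        ps = parameter_set_from_json(json.loads(path.read_text()))
    elif path.suffix == ".csv":
        with path.open(newline="") as fh:
            rows = list(csv.DictReader(fh))
        missing = [c for c in _CSV_COLUMNS if rows and c not in rows[0]]
        if missing:
            raise ValidationError(f"CSV file missing columns: {missing}")
        ps = _parameter_set_from_csv_rows(rows)
    else:
        raise ValidationError(f"unsupported parameter file extension: {path.suffix}")
    if validate:
        violations = validate_parameter_set(ps)
        if violations:
            raise ValidationError(
                "parameter set failed validation:\n  " + "\n  ".join(violations)
            )
    return ps


def load_settings(path: str | Path) -> EconomicSettings:
    """Load economic settings from a YAML or JSON config file."""
    import yaml

    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    known = {
        "wtp",
        "annual_discount_rate",
        "cycle_weeks",
        "horizon_years",
        "weeks_per_year",
        "currency_conversion",
        "half_cycle_correction",
    }
    unknown = set(doc) - known
    if unknown:
        raise ValidationError(f"unknown settings keys: {sorted(unknown)}")
    return EconomicSettings(**doc)
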