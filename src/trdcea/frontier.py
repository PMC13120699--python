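"""Incremental cost-effectiveness comparisons and the efficiency frontier.

Given per-strategy discounted totals, this module computes pairwise
incremental cost-effectiveness ratios (ICER = ΔCost / ΔQALY), classifies
dominance, constructs the efficiency frontier (the lower-left convex hull
of (QALY, cost) points) with sequential ICERs between adjacent
nondominated strategies, and evaluates net monetary benefit
(NMB = WTP x ΔQALY - ΔCost).
"""

from __future__ import annotations

from dataclasses import dataclass

from .engine import StrategyOutcome
from .parameters import ValidationError

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "EQUIVALENT",
    "ComparisonResult",
    "FrontierResult",
    "icer",
    "efficiency_frontier",
    "net_monetary_benefit",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"

#: Frontier labels.
NONDOMINATED = "nondominated"
STRICTLY_DOMINATED = "strictly dominated"
EXTENDEDLY_DOMINATED = "extendedly dominated"

_TIE_EPS = 0.0  # exact ties only; totals are continuous quantities


@dataclass
class ComparisonResult:
    """Pairwise comparison of a target strategy against a reference.

    ``icer`` carries the ratio ΔCost/ΔQALY when both differences share a
    sign and ΔQALY is nonzero; ``label`` is one of ``"icer"``,
    ``"dominant"`` (target cheaper and at least as effective),
    ``"dominated"`` or ``"equivalent"``.  For the south-west quadrant
    (target cheaper *and* less effective) the ratio is still reported and
    the label notes the reversal: it is the reference's ICER over the
    target.
    """

    target: str
    reference: str
    delta_cost: float
    delta_qaly: float
    icer: float | None
    label: str

    def __str__(self) -> str:
        if self.label == "icer":
            return f"{self.target} vs {self.reference}: ICER {self.icer:,.0f} US$/QALY"
        return f"{self.target} vs {self.reference}: {self.label}"


def icer(target: StrategyOutcome, reference: StrategyOutcome) -> ComparisonResult:
    """Incremental cost-effectiveness of ``target`` versus ``reference``.

    Dominance follows the usual quadrant rules: the target dominates when
    it costs no more and yields no fewer QALYs (not both equal), and is
    dominated in the mirror case.  Internal arithmetic is unrounded;
    round for display only.
    """
    dc = target.cost - reference.cost
    dq = target.qaly - reference.qaly
    if dc == 0 and dq == 0:
        return ComparisonResult(target.strategy, reference.strategy, dc, dq, None,
                                EQUIVALENT)
    if dc <= 0 and dq >= 0:
        return ComparisonResult(target.strategy, reference.strategy, dc, dq, None,
                                DOMINANT)
    if dc >= 0 and dq <= 0:
        return ComparisonResult(target.strategy, reference.strategy, dc, dq, None,
                                DOMINATED)
    ratio = dc / dq
    label = "icer" if dq > 0 else "icer_southwest"
    return ComparisonResult(target.strategy, reference.strategy, dc, dq, ratio, label)


@dataclass
class FrontierResult:
    """Efficiency-frontier classification of a strategy set.

    ``order`` lists strategies sorted by ascending cost (ties broken by
    higher QALY first); ``labels`` maps each strategy to nondominated /
    strictly dominated / extendedly dominated; ``frontier`` lists the
    nondominated strategies in cost order and ``sequential_icers`` the
    ICER of each frontier member versus its predecessor (the cheapest
    member has none).
    """

    order: list[str]
    labels: dict[str, str]
    frontier: list[str]
    sequential_icers: dict[str, float]
    outcomes: dict[str, StrategyOutcome]


def efficiency_frontier(outcomes: list[StrategyOutcome]) -> FrontierResult:
    """Classify strategies and build the efficiency frontier.

    Strictly dominated strategies (another strategy costs no more and
    yields no fewer QALYs, with at least one strict inequality) are
    removed first; extended dominance is then eliminated iteratively
    until sequential ICERs strictly increase along the frontier.
    """
    if not outcomes:
        raise ValidationError("efficiency_frontier requires at least one outcome")
    by_name = {o.strategy: o for o in outcomes}
    if len(by_name) != len(outcomes):
        raise ValidationError("duplicate strategy names in outcomes")

    order = sorted(by_name, key=lambda s: (by_name[s].cost, -by_name[s].qaly))
    labels: dict[str, str] = {}

    for s in order:
        o = by_name[s]
        for t in order:
            if t == s:
                continue
            p = by_name[t]
            if (p.cost <= o.cost and p.qaly >= o.qaly
                    and (p.cost < o.cost or p.qaly > o.qaly)):
                labels[s] = STRICTLY_DOMINATED
                break

    frontier = [s for s in order if s not in labels]

    # Extended dominance: drop interior points until sequential ICERs
    # strictly increase (lower-left convex hull).
    changed = True
    while changed and len(frontier) > 2:
        changed = False
        for i in range(1, len(frontier) - 1):
            lo, mid, hi = (by_name[frontier[i - 1]], by_name[frontier[i]],
                           by_name[frontier[i + 1]])
            icer_in = (mid.cost - lo.cost) / (mid.qaly - lo.qaly)
            icer_out = (hi.cost - mid.cost) / (hi.qaly - mid.qaly)
            if icer_in >= icer_out:
                labels[frontier[i]] = EXTENDEDLY_DOMINATED
                frontier.pop(i)
                changed = True
                break

    for s in frontier:
        labels[s] = NONDOMINATED

    sequential: dict[str, float] = {}
    for prev, cur in zip(frontier, frontier[1:]):
        sequential[cur] = (by_name[cur].cost - by_name[prev].cost) / (
            by_name[cur].qaly - by_name[prev].qaly
        )

    return FrontierResult(
        order=order,
        labels=labels,
        frontier=frontier,
        sequential_icers=sequential,
        outcomes=by_name,
    )


def net_monetary_benefit(
    target: StrategyOutcome, reference: StrategyOutcome, wtp: float
) -> float:
    """NMB = WTP x ΔQALY - ΔCost; positive iff the target is preferred at
    the given willingness-to-pay threshold."""
    if wtp < 0:
        raise ValidationError(f"wtp must be >= 0, got {wtp}")
    return wtp * (target.qaly - reference.qaly) - (target.cost - reference.cost)
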