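"""Deterministic and probabilistic sensitivity analysis.

One-way deterministic analysis (tornado): each parameter is moved to its
declared lower and upper bound in turn, the model re-run, and parameters
ranked by the spread of the resulting ICER.

Probabilistic analysis: all parameters are sampled jointly from their
assigned distributions (independently — no correlation structure is
specified), the model evaluated per draw, and cost-effectiveness
acceptability curves (CEACs) computed as the fraction of draws in which
each strategy attains the maximal net monetary benefit at each
willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .engine import run_strategy
from .parameters import (
    EconomicSettings,
    ParameterSet,
    ValidationError,
    get_param,
    parameter_rng,
    set_param,
)

__all__ = [
    "DsaRow",
    "DsaResult",
    "PsaSampleSet",
    "CeacTable",
    "default_dsa_ranges",
    "one_way_dsa",
    "sample_psa",
    "ceac",
    "frontier_crossover_wtp",
    "default_wtp_grid",
]


# ---------------------------------------------------------------------------
# One-way deterministic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class DsaRow:
    """One tornado bar: the ICER of target vs reference with the parameter
    at its lower and upper bound, and the absolute spread between them."""

    parameter: str
    low: float
    high: float
    icer_low: float
    icer_high: float
    spread: float


@dataclass
class DsaResult:
    """Tornado table: rows sorted by descending spread, plus the base-case
    ICER for plotting the pivot line."""

    target: str
    reference: str
    base_icer: float
    rows: list[DsaRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "parameter": r.parameter,
                    "low": r.low,
                    "high": r.high,
                    "icer_low": r.icer_low,
                    "icer_high": r.icer_high,
                    "spread": r.spread,
                }
                for r in self.rows
            ]
        )


def default_dsa_ranges(ps: ParameterSet) -> dict[str, tuple[float, float]]:
    """Low/high bounds per parameter, taken from the declared PSA
    distribution intervals (95% CI or equivalent)."""
    return {
        key: (d.low, d.high)
        for key, d in ps.psa_distributions.items()
        if d.low is not None and d.high is not None
    }


def _pairwise_icer_value(
    ps: ParameterSet, settings: EconomicSettings, target: str, reference: str
) -> float:
    """Signed ΔCost/ΔQALY of target vs reference (numeric even in
    dominance quadrants; +/-inf when ΔQALY is zero)."""
    t = run_strategy(target, ps, settings, infeasible="rescale")
    r = run_strategy(reference, ps, settings, infeasible="rescale")
    dq = t.qaly - r.qaly
    dc = t.cost - r.cost
    if dq == 0:
        return float("inf") if dc > 0 else float("-inf") if dc < 0 else 0.0
    return dc / dq


def one_way_dsa(
    ps: ParameterSet,
    settings: EconomicSettings,
    target: str,
    reference: str,
    ranges: dict[str, tuple[float, float]] | None = None,
    top_k: int | None = None,
) -> DsaResult:
    """Vary each parameter independently to its bounds and rank by ICER
    spread.  ``ranges`` defaults to the declared distribution intervals."""
    if ranges is None:
        ranges = default_dsa_ranges(ps)
    for key, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValidationError(f"DSA range for {key!r} inverted: {lo} > {hi}")

    base_icer = _pairwise_icer_value(ps, settings, target, reference)
    rows: list[DsaRow] = []
    for key, (lo, hi) in ranges.items():
        base_value = get_param(ps, key)
        try:
            set_param(ps, key, lo)
            icer_lo = _pairwise_icer_value(ps, settings, target, reference)
            set_param(ps, key, hi)
            icer_hi = _pairwise_icer_value(ps, settings, target, reference)
        finally:
            set_param(ps, key, base_value)
        rows.append(
            DsaRow(key, lo, hi, icer_lo, icer_hi, abs(icer_hi - icer_lo))
        )

    rows.sort(key=lambda r: -r.spread)
    if top_k is not None:
        rows = rows[:top_k]
    return DsaResult(target=target, reference=reference, base_icer=base_icer, rows=rows)


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------


@dataclass
class PsaSampleSet:
    """Joint Monte-Carlo sample of the parameter space with per-draw model
    results.

    ``param_draws`` is (n x parameters); ``results`` is long format with
    columns draw, strategy, cost, qaly.  ``n_rescaled`` counts draws in
    which a state's sampled outgoing probabilities exceeded unity and were
    proportionally rescaled.
    """

    n: int
    seed: int
    strategies: list[str]
    param_draws: pd.DataFrame
    results: pd.DataFrame
    n_rescaled: int = 0

    def matrix(self, column: str) -> np.ndarray:
        """(n x strategies) matrix of ``column`` ('cost' or 'qaly')."""
        wide = self.results.pivot(index="draw", columns="strategy", values=column)
        return wide[self.strategies].to_numpy()


def sample_psa(
    ps: ParameterSet,
    settings: EconomicSettings,
    n: int,
    seed: int,
    strategies: list[str] | None = None,
) -> PsaSampleSet:
    """Draw ``n`` joint parameter realisations and evaluate the model for
    each strategy under every draw.

    Each varied parameter draws from its own seeded substream
    (:func:`trdcea.parameters.parameter_rng`), so the draw sequence of one
    parameter is unaffected by adding or removing another.  Identical
    seeds give identical sample sets.
    """
    if n < 1:
        raise ValidationError(f"n must be >= 1, got {n}")
    names = strategies if strategies is not None else ps.strategy_names
    keys = sorted(ps.psa_distributions)
    draws = {
        key: ps.psa_distributions[key].sample(parameter_rng(seed, key), n)
        for key in keys
    }
    param_draws = pd.DataFrame(draws, columns=keys)

    work = ps.copy()
    records = []
    n_rescaled = 0
    for i in range(n):
        for key in keys:
            set_param(work, key, float(param_draws.iloc[i][key]))
        rescued = False
        for name in names:
            try:
                out = run_strategy(name, work, settings, infeasible="error")
            except Exception:
                out = run_strategy(name, work, settings, infeasible="rescale")
                rescued = True
            records.append(
                {"draw": i, "strategy": name, "cost": out.cost, "qaly": out.qaly}
            )
        if rescued:
            n_rescaled += 1

    results = pd.DataFrame.from_records(records)
    return PsaSampleSet(
        n=n,
        seed=seed,
        strategies=names,
        param_draws=param_draws,
        results=results,
        n_rescaled=n_rescaled,
    )


# ---------------------------------------------------------------------------
# Cost-effectiveness acceptability curves
# ---------------------------------------------------------------------------


@dataclass
class CeacTable:
    """Probability of each strategy being cost-effective (maximal NMB)
    over a willingness-to-pay grid.  Rows sum to 1 at every threshold."""

    wtp_grid: np.ndarray
    strategies: list[str]
    probabilities: np.ndarray  # (len(grid) x strategies)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, w in enumerate(self.wtp_grid):
            for j, s in enumerate(self.strategies):
                rows.append(
                    {"wtp": float(w), "strategy": s,
                     "probability": float(self.probabilities[i, j])}
                )
        return pd.DataFrame(rows)

    def probability_at(self, wtp: float, strategy: str) -> float:
        i = int(np.argmin(np.abs(self.wtp_grid - wtp)))
        return float(self.probabilities[i, self.strategies.index(strategy)])


def default_wtp_grid(
    low: float = 0.0, high: float = 400_000.0, step: float = 80.0
) -> np.ndarray:
    """WTP grid covering 0 to 400,000 US$/QALY in steps of 80 (5,001
    points), spanning the decision landmarks of interest."""
    return np.arange(low, high + step / 2, step)


def _win_fractions(cost: np.ndarray, qaly: np.ndarray, wtp: float) -> np.ndarray:
    """Per-strategy fraction of draws attaining maximal NMB at one WTP,
    with exact ties splitting mass equally."""
    nmb = wtp * qaly - cost
    best = nmb.max(axis=1, keepdims=True)
    winners = nmb == best
    return (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)


def ceac(samples: PsaSampleSet, wtp_grid: np.ndarray | None = None) -> CeacTable:
    """Compute acceptability curves over the WTP grid from PSA draws."""
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValidationError("wtp_grid must be nonempty")
    cost = samples.matrix("cost")
    qaly = samples.matrix("qaly")
    probs = np.empty((wtp_grid.size, len(samples.strategies)))
    for i, w in enumerate(wtp_grid):
        probs[i] = _win_fractions(cost, qaly, float(w))
    return CeacTable(wtp_grid=wtp_grid, strategies=list(samples.strategies),
                     probabilities=probs)


def frontier_crossover_wtp(
    samples: PsaSampleSet,
    strategy: str,
    wtp_grid: np.ndarray | None = None,
    tol: float = 1.0,
) -> float | None:
    """Smallest willingness-to-pay at which ``strategy``'s probability of
    being cost-effective is strictly highest.

    The WTP grid brackets the crossover; the boundary is then refined by
    bisection on the NMB draws to within ``tol`` US$/QALY.  Returns None
    if the strategy is never strictly most likely cost-effective on the
    grid.
    """
    if wtp_grid is None:
        wtp_grid = default_wtp_grid()
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    cost = samples.matrix("cost")
    qaly = samples.matrix("qaly")
    j = samples.strategies.index(strategy)

    def leads(w: float) -> bool:
        f = _win_fractions(cost, qaly, w)
        return bool(f[j] > np.max(np.delete(f, j)))

    hit = None
    for i, w in enumerate(wtp_grid):
        if leads(float(w)):
            hit = i
            break
    if hit is None:
        return None
    if hit == 0:
        return float(wtp_grid[0])

    lo, hi = float(wtp_grid[hit - 1]), float(wtp_grid[hit])
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if leads(mid):
            hi = mid
        else:
            lo = mid
    return hi
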