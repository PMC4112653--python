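"""Probabilistic sensitivity analysis and incremental cost-effectiveness.

Runs the Monte Carlo propagation of the parameter priors through the
pathway engine and summarises the resulting cost/QALY clouds: mean-based
incremental analysis with dominance handling, net monetary benefit,
cost-effectiveness plane draws, and acceptability curves/frontier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .params import ParameterDeck, sample_params
from .pathways import StrategyId, strategy_outcome

__all__ = [
    "STRATEGY_ORDER",
    "PsaMatrix",
    "IncrementalResult",
    "CeafCurve",
    "CePlane",
    "run_psa",
    "net_benefit",
    "incremental_analysis",
    "ceaf",
    "ce_plane",
]

#: canonical strategy column order of every PSA matrix
STRATEGY_ORDER: tuple[StrategyId, ...] = (
    StrategyId.VTS, StrategyId.HAS, StrategyId.HAS_THEN_VTS)


def _mean_se(x: np.ndarray) -> float:
    """Monte Carlo standard error of a sample mean."""
    n = x.shape[0]
    return float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")


def _prop_se(p: float, n: int) -> float:
    """Monte Carlo standard error of a sample proportion."""
    return float(np.sqrt(p * (1.0 - p) / n)) if n > 0 else float("nan")


@dataclass
class PsaMatrix:
    """Per-draw strategy costs and QALYs plus replay provenance."""

    costs: np.ndarray  # (n_sims, n_strategies), GBP
    qalys: np.ndarray  # (n_sims, n_strategies)
    strategies: tuple[StrategyId, ...]
    seed: int | None
    deck_fingerprint: str

    @property
    def n_sims(self) -> int:
        return self.costs.shape[0]

    def index_of(self, strategy: StrategyId) -> int:
        return self.strategies.index(StrategyId(strategy))

    def net_benefits(self, lam: float) -> np.ndarray:
        """Per-draw net monetary benefit matrix at willingness-to-pay ``lam``."""
        return net_benefit(lam, self.qalys, self.costs)

    def to_frame(self) -> pd.DataFrame:
        """Long-format per-draw table (draw, strategy, cost, qaly)."""
        rows = []
        for j, s in enumerate(self.strategies):
            rows.append(pd.DataFrame({
                "draw": np.arange(self.n_sims),
                "strategy": s.value,
                "cost": self.costs[:, j],
                "qaly": self.qalys[:, j],
            }))
        return pd.concat(rows, ignore_index=True)


def run_psa(deck: ParameterDeck, n_sims: int | None = None,
            seed: int | None = None) -> PsaMatrix:
    """Monte Carlo PSA: sample the priors and evaluate every strategy.

    Row i of the result holds the pathway-engine outcome for the i-th
    sampled parameter vector; sampling is vectorized, so the whole run is
    a single pass.  ``n_sims`` defaults to the deck's configured simulation
    count (10,000).
    """
    if n_sims is None:
        n_sims = deck.constants.n_sims
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    rng = np.random.default_rng(seed)
    params = sample_params(deck, rng, size=n_sims)
    costs = np.empty((n_sims, len(STRATEGY_ORDER)))
    qalys = np.empty_like(costs)
    for j, strat in enumerate(STRATEGY_ORDER):
        out = strategy_outcome(strat, params)
        costs[:, j] = np.broadcast_to(out.expected_cost, (n_sims,))
        qalys[:, j] = np.broadcast_to(out.expected_qaly, (n_sims,))
    return PsaMatrix(costs=costs, qalys=qalys, strategies=STRATEGY_ORDER,
                     seed=seed, deck_fingerprint=deck.fingerprint())


def net_benefit(lam, qaly, cost):
    """Net monetary benefit: lambda * QALY - cost (elementwise)."""
    lam = np.asarray(lam, dtype=float) if not np.isscalar(lam) else lam
    return lam * np.asarray(qaly, dtype=float) - np.asarray(cost, dtype=float)


@dataclass
class IncrementalResult:
    """Mean-based incremental analysis at one willingness-to-pay threshold."""

    table: pd.DataFrame  # one row per strategy
    icers: dict  # (comparator, reference) -> GBP/QALY between non-dominated strategies
    lam: float

    def dominated(self) -> list[str]:
        return list(self.table.loc[self.table["strongly_dominated"], "strategy"])


def incremental_analysis(psa: PsaMatrix, lam: float = 20_000.0) -> IncrementalResult:
    """Summarise PSA means: dominance, pairwise ICERs, net benefit at ``lam``.

    A strategy is strongly dominated when another has mean cost <= and mean
    QALY >= it, with at least one inequality strict.  ICERs are computed
    only between non-dominated strategies, each against the next-less-
    effective one; an ICER with zero QALY difference is undefined (None).
    """
    if len(psa.strategies) < 2:
        raise ValueError("incremental analysis needs at least two strategies")
    mc = psa.costs.mean(axis=0)
    mq = psa.qalys.mean(axis=0)
    n = psa.n_sims

    k = len(psa.strategies)
    dominated = np.zeros(k, dtype=bool)
    for a in range(k):
        for b in range(k):
            if a == b:
                continue
            if (mc[b] <= mc[a] and mq[b] >= mq[a]
                    and (mc[b] < mc[a] or mq[b] > mq[a])):
                dominated[a] = True

    with np.errstate(divide="ignore", invalid="ignore"):
        cost_per_qaly = np.where(mq != 0, mc / mq, np.nan)

    table = pd.DataFrame({
        "strategy": [s.value for s in psa.strategies],
        "mean_cost": mc,
        "se_cost": [_mean_se(psa.costs[:, j]) for j in range(k)],
        "mean_qaly": mq,
        "se_qaly": [_mean_se(psa.qalys[:, j]) for j in range(k)],
        "cost_per_qaly": cost_per_qaly,
        "net_benefit": net_benefit(lam, mq, mc),
        "strongly_dominated": dominated,
    })

    icers: dict = {}
    alive = [j for j in range(k) if not dominated[j]]
    alive.sort(key=lambda j: mq[j])  # by increasing effectiveness
    for lo, hi in zip(alive, alive[1:]):
        dq = mq[hi] - mq[lo]
        dc = mc[hi] - mc[lo]
        key = (psa.strategies[hi].value, psa.strategies[lo].value)
        icers[key] = float(dc / dq) if dq != 0 else None
    return IncrementalResult(table=table, icers=icers, lam=lam)


@dataclass
class CeafCurve:
    """Acceptability probabilities and expected-NB frontier over a lambda grid."""

    table: pd.DataFrame  # columns: lam, strategy, probability, se, on_frontier

    def probability(self, lam: float, strategy: StrategyId) -> float:
        t = self.table
        row = t[(t["lam"] == lam) & (t["strategy"] == StrategyId(strategy).value)]
        return float(row["probability"].iloc[0])

    def frontier_strategy(self, lam: float) -> str:
        t = self.table
        row = t[(t["lam"] == lam) & t["on_frontier"]]
        return str(row["strategy"].iloc[0])

    def frontier_switch_points(self) -> list[tuple[float, str, str]]:
        """(lambda, from, to) at each change of the frontier strategy along the grid."""
        t = self.table[self.table["on_frontier"]].sort_values("lam")
        switches = []
        prev = None
        for _, row in t.iterrows():
            if prev is not None and row["strategy"] != prev:
                switches.append((float(row["lam"]), prev, str(row["strategy"])))
            prev = str(row["strategy"])
        return switches


def default_lambda_grid() -> np.ndarray:
    """0 to 30,000 GBP/QALY in 500 steps."""
    return np.arange(0.0, 30_000.0 + 1, 500.0)


def ceaf(psa: PsaMatrix, lambda_grid: Sequence[float] | None = None) -> CeafCurve:
    """Acceptability curve per strategy and the expected-NB frontier.

    Per lambda, a strategy's acceptability is the fraction of draws in which
    it attains the maximum net benefit; draws with ties split their weight
    equally among the tied strategies, so probabilities sum to one.  The
    frontier strategy is the argmax of mean net benefit.
    """
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    lambda_grid = np.asarray(list(lambda_grid), dtype=float)
    if lambda_grid.size == 0:
        raise ValueError("lambda grid must be non-empty")

    n, k = psa.costs.shape
    records = []
    for lam in lambda_grid:
        nb = psa.net_benefits(lam)
        best = nb.max(axis=1, keepdims=True)
        is_best = nb == best
        weights = is_best / is_best.sum(axis=1, keepdims=True)
        probs = weights.mean(axis=0)
        frontier = int(np.argmax(nb.mean(axis=0)))
        for j, s in enumerate(psa.strategies):
            records.append({
                "lam": float(lam),
                "strategy": s.value,
                "probability": float(probs[j]),
                "se": _prop_se(float(probs[j]), n),
                "on_frontier": j == frontier,
            })
    return CeafCurve(table=pd.DataFrame.from_records(records))


@dataclass
class CePlane:
    """Per-draw incremental (delta cost, delta QALY) pairs, comparator minus reference."""

    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    reference: StrategyId
    comparator: StrategyId

    def fraction_cost_effective(self, lam: float) -> float:
        """Fraction of draws below the lambda line (incremental NB > 0).

        Equals the comparator's acceptability in the two-strategy
        restriction of the CEAC (up to tie handling on the line).
        """
        inb = net_benefit(lam, self.delta_qaly, self.delta_cost)
        return float(np.mean(inb > 0))

    def fraction_cost_effective_se(self, lam: float) -> float:
        p = self.fraction_cost_effective(lam)
        return _prop_se(p, self.delta_cost.shape[0])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "draw": np.arange(self.delta_cost.shape[0]),
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
        })


def ce_plane(psa: PsaMatrix, reference: StrategyId,
             comparator: StrategyId) -> CePlane:
    """Cost-effectiveness-plane draws of ``comparator`` against ``reference``."""
    i = psa.index_of(reference)
    j = psa.index_of(comparator)
    return CePlane(
        delta_cost=psa.costs[:, j] - psa.costs[:, i],
        delta_qaly=psa.qalys[:, j] - psa.qalys[:, i],
        reference=StrategyId(reference),
        comparator=StrategyId(comparator),
    )
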