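"""Value-of-information analysis: EVPI, population EVPI and partial EVPI.

The expected value of perfect information (EVPI) is the gap between
deciding with perfect knowledge of every parameter and deciding on current
expectations:

    EVPI = E_theta[ max_j NB(j, theta) ] - max_j E_theta[ NB(j, theta) ]

Scaled by the discounted number of future patients the decision applies to,
it bounds the worth of further research.  Partial EVPI (EVPPI) isolates a
parameter subset via a nested two-loop Monte Carlo: the outer loop draws
the parameters of interest, the inner loop averages net benefit over the
remaining uncertainties with the outer draw held fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterDeck, sample_params
from .psa import STRATEGY_ORDER, PsaMatrix, net_benefit
from .pathways import strategy_outcome

__all__ = [
    "PopulationSpec",
    "ParameterPartition",
    "VoiResult",
    "evpi",
    "evpi_se",
    "effective_population",
    "population_evpi",
    "evppi",
    "qaly_parameter_names",
]


@dataclass(frozen=True)
class PopulationSpec:
    """Population to which the adoption decision applies.

    Defaults: 25,000 eligible children per year over a 5-year decision
    horizon, discounted at 3.5% with the first annual cohort undiscounted.
    """

    annual_incidence: float = 25_000.0
    horizon_years: int = 5
    discount_rate: float = 0.035
    first_year_discounted: bool = False

    def validate(self) -> None:
        if self.annual_incidence <= 0:
            raise ValueError("annual incidence must be positive")
        if self.horizon_years < 1:
            raise ValueError("horizon must be at least one year")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount rate must be in [0, 1)")


@dataclass(frozen=True)
class ParameterPartition:
    """Split of the deck entries into parameters of interest and the rest."""

    of_interest: tuple[str, ...]

    def complement(self, deck: ParameterDeck) -> tuple[str, ...]:
        interest = set(self.of_interest)
        unknown = interest - set(deck.entry_names())
        if unknown:
            raise KeyError(f"unknown partition entries: {sorted(unknown)}")
        return tuple(n for n in deck.entry_names() if n not in interest)


@dataclass
class VoiResult:
    evpi_per_person: float
    effective_population: float
    evpi_population: float
    lam: float
    evppi_per_person: float | None = None
    evppi_se: float | None = None
    evpi_se: float | None = None


def evpi(nb: np.ndarray) -> float:
    """EVPI of a draws-by-strategies net-benefit matrix.

    Mean over draws of the per-draw best net benefit, minus the best of the
    per-strategy mean net benefits; clamped at zero against floating-point
    undershoot (the quantity is non-negative by Jensen's inequality).
    """
    nb = np.asarray(nb, dtype=float)
    if nb.ndim != 2 or nb.size == 0:
        raise ValueError("net-benefit matrix must be non-empty and 2-D")
    value = nb.max(axis=1).mean() - nb.mean(axis=0).max()
    return float(max(value, 0.0))


def evpi_se(nb: np.ndarray) -> float:
    """Monte Carlo standard error of the EVPI estimate.

    Treats the per-draw loss max_j NB(j) - NB(j*, draw) of the current-
    information choice j* as the averaged quantity.
    """
    nb = np.asarray(nb, dtype=float)
    j_star = int(np.argmax(nb.mean(axis=0)))
    loss = nb.max(axis=1) - nb[:, j_star]
    n = nb.shape[0]
    return float(np.std(loss, ddof=1) / np.sqrt(n)) if n > 1 else float("nan")


def effective_population(spec: PopulationSpec = PopulationSpec()) -> float:
    """Discounted count of future patients covered by the decision.

    Sums the annual cohorts over the horizon with per-year discounting;
    with the default spec (first cohort undiscounted) this is
    25,000 * sum_{t=0..4} 1.035^-t ~= 116,827 children.
    """
    spec.validate()
    start = 1 if spec.first_year_discounted else 0
    t = np.arange(start, start + spec.horizon_years)
    return float(spec.annual_incidence * np.sum((1.0 + spec.discount_rate) ** -t))


def population_evpi(evpi_per_person: float,
                    spec: PopulationSpec = PopulationSpec()) -> float:
    """Scale unrounded per-person EVPI to the effective population."""
    if evpi_per_person < 0:
        raise ValueError("per-person EVPI cannot be negative")
    return evpi_per_person * effective_population(spec)


def qaly_parameter_names(deck: ParameterDeck) -> tuple[str, ...]:
    """The QALY-driving subset: utility per dBHL plus the four dBHL gains."""
    return tuple(deck.gains) + (deck.utility.name,)


def _mean_nb_per_strategy(deck: ParameterDeck, params, lam: float) -> np.ndarray:
    out = np.empty(len(STRATEGY_ORDER))
    for j, strat in enumerate(STRATEGY_ORDER):
        o = strategy_outcome(strat, params)
        out[j] = np.mean(net_benefit(lam, o.expected_qaly, o.expected_cost))
    return out


def evppi(deck: ParameterDeck, partition: ParameterPartition, lam: float,
          n_outer: int = 100, n_inner: int = 1_000,
          seed: int | None = None,
          baseline_nb: np.ndarray | None = None) -> tuple[float, float]:
    """Partial EVPI for a parameter subset by nested two-loop Monte Carlo.

    Outer loop: draw the parameters of interest from their priors.  Inner
    loop: with the outer draw pinned, draw the complement (independently —
    the deck declares no correlations) and average each strategy's net
    benefit; take the best strategy per outer draw.  The estimate is the
    mean of those per-outer best values minus the best overall expected net
    benefit.  Returns ``(estimate, mc_standard_error)``; the standard error
    reflects outer-loop variability of the per-outer maxima.

    ``baseline_nb`` optionally supplies a pre-computed draws-by-strategies
    net-benefit matrix for the current-information term; otherwise a fresh
    n_outer*n_inner-draw run is used.
    """
    if n_outer < 1 or n_inner < 1:
        raise ValueError("loop sizes must be >= 1")
    if not partition.of_interest:
        raise ValueError("parameters of interest must be non-empty")
    partition.complement(deck)  # validates names

    rng = np.random.default_rng(seed)
    interest = list(partition.of_interest)

    per_outer_best = np.empty(n_outer)
    for i in range(n_outer):
        outer_draw = sample_params(deck, rng, size=None)
        pinned = {name: outer_draw[name] for name in interest}
        inner = sample_params(deck, rng, size=n_inner, fixed=pinned)
        per_outer_best[i] = _mean_nb_per_strategy(deck, inner, lam).max()

    if baseline_nb is None:
        baseline = sample_params(deck, rng, size=n_outer * n_inner)
        current_best = _mean_nb_per_strategy(deck, baseline, lam).max()
    else:
        current_best = np.asarray(baseline_nb).mean(axis=0).max()

    estimate = float(max(per_outer_best.mean() - current_best, 0.0))
    se = float(np.std(per_outer_best, ddof=1) / np.sqrt(n_outer)) if n_outer > 1 else float("nan")
    return estimate, se


def voi_summary(psa: PsaMatrix, lam: float,
                spec: PopulationSpec = PopulationSpec()) -> VoiResult:
    """EVPI at one threshold, per person and scaled to the population."""
    nb = psa.net_benefits(lam)
    per_person = evpi(nb)
    pop = effective_population(spec)
    return VoiResult(
        evpi_per_person=per_person,
        effective_population=pop,
        evpi_population=per_person * pop,
        lam=lam,
        evpi_se=evpi_se(nb),
    )
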