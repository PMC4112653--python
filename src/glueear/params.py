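"""Parameter deck: definition, validation, sampling and (de)serialization.

The model is driven entirely by a *parameter deck* — the full set of care
pathway probabilities, dBHL hearing-gain distributions, resource unit costs
and scalar constants for the three management strategies (ventilation tubes,
hearing aids, hearing aids followed by ventilation tubes).  Each uncertain
entry carries a prior distribution used by the probabilistic sensitivity
analysis:

* pathway probabilities       — beta(alpha, beta) with mean alpha/(alpha+beta)
* resource unit costs         — gamma(shape, scale) with mean shape*scale,
                                or a fixed point value
* hearing gains (dBHL)        — normal(mean, sd), untruncated: a draw may be
                                negative, reflecting the chance of a hearing
                                deterioration
* utility per dBHL            — normal, with sd recovered from the published
                                95% confidence interval

This module is the pipeline's only source of stochastic input: the sampler
is deterministic under a seeded :class:`numpy.random.Generator`, and can
draw either scalar parameter vectors or vectorized batches (one array entry
per Monte Carlo iteration).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterator, Mapping

import numpy as np
import yaml

__all__ = [
    "DeckValidationError",
    "ProbabilityParam",
    "CostParam",
    "HearingGainParam",
    "UtilityParam",
    "ScalarConstants",
    "ParameterDeck",
    "SampledParams",
    "default_deck",
    "load_deck",
    "save_deck",
    "sample_params",
    "scenario_deck",
]

#: z-quantile used to recover a normal sd from a symmetric 95% CI.
_Z95 = 1.96


class DeckValidationError(ValueError):
    """A deck entry violates its declared constraints; names the entry."""


@dataclass(frozen=True)
class ProbabilityParam:
    """A pathway probability with a beta(alpha, beta) prior.

    ``mean`` is the published point estimate; it must agree with the
    analytic beta mean alpha/(alpha+beta) to within 0.001.
    """

    name: str
    alpha: float
    beta: float
    mean: float
    source_ref: str

    def validate(self) -> None:
        # alpha or beta of 0 encodes a degenerate prior at 0 or 1
        if self.alpha < 0 or self.beta < 0 or self.alpha + self.beta <= 0:
            raise DeckValidationError(
                f"probability '{self.name}': alpha and beta must be "
                f"non-negative with alpha+beta > 0 "
                f"(got alpha={self.alpha}, beta={self.beta})"
            )
        if not 0.0 <= self.mean <= 1.0:
            raise DeckValidationError(
                f"probability '{self.name}': mean {self.mean} outside [0, 1]"
            )
        if abs(self.analytic_mean - self.mean) > 1e-3:
            raise DeckValidationError(
                f"probability '{self.name}': beta mean "
                f"{self.analytic_mean:.6f} does not reproduce the stated "
                f"point estimate {self.mean}"
            )

    @property
    def analytic_mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class CostParam:
    """A resource unit cost (GBP): gamma(shape, scale) prior or fixed value.

    For the gamma kind, ``mean`` is the published unit cost and must equal
    shape*scale to within one pound.
    """

    name: str
    kind: str  # "gamma" | "fixed"
    source_ref: str
    shape: float | None = None
    scale: float | None = None
    value: float | None = None
    mean: float | None = None

    def validate(self) -> None:
        if self.kind == "gamma":
            if self.shape is None or self.scale is None:
                raise DeckValidationError(
                    f"cost '{self.name}': gamma kind requires shape and scale"
                )
            if self.shape <= 0 or self.scale <= 0:
                raise DeckValidationError(
                    f"cost '{self.name}': shape and scale must be positive "
                    f"(got shape={self.shape}, scale={self.scale})"
                )
            if self.mean is not None and abs(self.shape * self.scale - self.mean) > 1.0:
                raise DeckValidationError(
                    f"cost '{self.name}': gamma mean "
                    f"{self.shape * self.scale:.2f} does not reproduce the "
                    f"stated unit cost {self.mean}"
                )
        elif self.kind == "fixed":
            if self.value is None:
                raise DeckValidationError(
                    f"cost '{self.name}': fixed kind requires a value"
                )
            if self.value < 0:
                raise DeckValidationError(
                    f"cost '{self.name}': negative fixed cost {self.value}"
                )
        else:
            raise DeckValidationError(
                f"cost '{self.name}': unknown kind '{self.kind}'"
            )

    @property
    def analytic_mean(self) -> float:
        if self.kind == "gamma":
            return self.shape * self.scale
        return self.value


@dataclass(frozen=True)
class HearingGainParam:
    """Mean hearing gain in dBHL for one strategy and model year.

    Sampled as an untruncated normal: the dispersion expresses the chance
    of a larger or smaller (possibly negative) gain.
    """

    strategy: str  # "VTs" | "HAs"
    horizon: str  # "year1" | "year2"
    mean_dBHL: float
    sd_dBHL: float
    source_ref: str

    def validate(self) -> None:
        if self.strategy not in ("VTs", "HAs"):
            raise DeckValidationError(
                f"gain '{self.name}': unknown strategy '{self.strategy}'"
            )
        if self.horizon not in ("year1", "year2"):
            raise DeckValidationError(
                f"gain '{self.name}': unknown horizon '{self.horizon}'"
            )
        if self.sd_dBHL < 0:
            raise DeckValidationError(
                f"gain '{self.name}': negative sd {self.sd_dBHL}"
            )

    @property
    def name(self) -> str:
        return f"gain_{self.strategy.lower()}_{self.horizon}"


@dataclass(frozen=True)
class UtilityParam:
    """Utility increment per unit gain in dBHL, with its published 95% CI.

    The PSA samples it as a normal with sd (ci_high-ci_low)/(2*1.96); the
    published interval is symmetric-looking and no family is stated, so a
    normal is the least-informative conventional choice.
    """

    mean_per_dBHL: float
    ci_low: float
    ci_high: float

    name: str = "utility_per_dbhl"

    def validate(self) -> None:
        if not self.ci_low <= self.mean_per_dBHL <= self.ci_high:
            raise DeckValidationError(
                "utility: mean must lie within its confidence interval"
            )

    @property
    def sd(self) -> float:
        return (self.ci_high - self.ci_low) / (2.0 * _Z95)


@dataclass(frozen=True)
class ScalarConstants:
    """Deterministic model constants (no prior; identical in every draw)."""

    discount_rate: float = 0.035
    spontaneous_resolution_12m: float = 0.308
    aom_episodes_per_year: float = 2.8
    ha_breakage_per_year: float = 0.1644
    extrusion_weeks: float = 39.0
    max_insertions: int = 3
    audiology_visits_per_surgery: float = 1.5
    ent_visits_per_year_has: float = 1.5
    cohort_size: int = 10_000
    n_sims: int = 10_000
    # visit/replacement schedules resolved to per-period counts
    ent_visits_per_insertion: float = 2.0  # week 6 + week 32, before 39-week extrusion
    audiology_visits_per_year_has: float = 2.0  # week 13 + one 26-week follow-up
    earmould_sets_per_year: float = 4.0  # two moulds replaced every 13 weeks
    battery_sets_per_year: float = 13.0  # two batteries replaced every 4 weeks
    devices_per_child: int = 2  # bilateral condition

    def validate(self) -> None:
        for prob_field in ("discount_rate", "spontaneous_resolution_12m", "ha_breakage_per_year"):
            v = getattr(self, prob_field)
            if not 0.0 <= v <= 1.0:
                raise DeckValidationError(
                    f"constant '{prob_field}': {v} outside [0, 1]"
                )
        for name in (
            "aom_episodes_per_year", "extrusion_weeks", "max_insertions",
            "audiology_visits_per_surgery", "ent_visits_per_year_has",
            "cohort_size", "n_sims", "ent_visits_per_insertion",
            "audiology_visits_per_year_has", "earmould_sets_per_year",
            "battery_sets_per_year", "devices_per_child",
        ):
            if getattr(self, name) < 0:
                raise DeckValidationError(f"constant '{name}': negative value")


@dataclass(frozen=True)
class ParameterDeck:
    """The complete, validated input set of the decision model."""

    probabilities: Mapping[str, ProbabilityParam]
    costs: Mapping[str, CostParam]
    gains: Mapping[str, HearingGainParam]
    utility: UtilityParam
    constants: ScalarConstants

    def validate(self) -> "ParameterDeck":
        for p in self.probabilities.values():
            p.validate()
        for c in self.costs.values():
            c.validate()
        for g in self.gains.values():
            g.validate()
        self.utility.validate()
        self.constants.validate()
        return self

    # -- entry access -----------------------------------------------------

    def entry_names(self) -> Iterator[str]:
        """Stable iteration order of all sampled entries (defines the draw order)."""
        yield from self.probabilities
        yield from self.costs
        yield from self.gains
        yield self.utility.name

    def stochastic_names(self) -> list[str]:
        """Names of entries that carry a non-degenerate prior."""
        names = list(self.probabilities)
        names += [n for n, c in self.costs.items() if c.kind == "gamma"]
        names += [n for n, g in self.gains.items() if g.sd_dBHL > 0]
        if self.utility.sd > 0:
            names.append(self.utility.name)
        return names

    def analytic_mean(self, name: str) -> float:
        if name in self.probabilities:
            return self.probabilities[name].analytic_mean
        if name in self.costs:
            return self.costs[name].analytic_mean
        if name in self.gains:
            return self.gains[name].mean_dBHL
        if name == self.utility.name:
            return self.utility.mean_per_dBHL
        raise KeyError(name)

    def means(self) -> "SampledParams":
        """The deterministic parameter vector at the analytic prior means."""
        values = {n: self.analytic_mean(n) for n in self.entry_names()}
        return SampledParams(values=values, constants=self.constants, draw_index=-1)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "probabilities": {
                n: {"alpha": p.alpha, "beta": p.beta, "mean": p.mean,
                    "source_ref": p.source_ref}
                for n, p in self.probabilities.items()
            },
            "costs": {
                n: (
                    {"kind": "gamma", "shape": c.shape, "scale": c.scale,
                     "mean": c.mean, "source_ref": c.source_ref}
                    if c.kind == "gamma"
                    else {"kind": "fixed", "value": c.value,
                          "source_ref": c.source_ref}
                )
                for n, c in self.costs.items()
            },
            "gains": {
                g.name: {"strategy": g.strategy, "horizon": g.horizon,
                         "mean_dBHL": g.mean_dBHL, "sd_dBHL": g.sd_dBHL,
                         "source_ref": g.source_ref}
                for g in self.gains.values()
            },
            "utility": {"mean_per_dBHL": self.utility.mean_per_dBHL,
                        "ci_low": self.utility.ci_low,
                        "ci_high": self.utility.ci_high},
            "constants": {
                f.name: getattr(self.constants, f.name)
                for f in self.constants.__dataclass_fields__.values()
            },
        }

    def fingerprint(self) -> str:
        """SHA-256 of the canonical JSON serialization (provenance hash)."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass(frozen=True)
class SampledParams:
    """One realized parameter vector (or a vectorized batch of them).

    ``values`` maps entry name to a float, or to an ndarray of shape
    (n_draws,) when the sampler was asked for a batch.  Fixed-kind entries
    are scalars in either case.
    """

    values: Mapping[str, float | np.ndarray]
    constants: ScalarConstants
    draw_index: int = 0

    def __getitem__(self, name: str) -> float | np.ndarray:
        try:
            return self.values[name]
        except KeyError:
            raise KeyError(
                f"parameter '{name}' missing from sampled vector"
            ) from None


# ---------------------------------------------------------------------------
# Default deck: the published tables, row by row.

_T1 = "Table 1, VTs post-operative complications"
_T2 = "Table 2, VTs care-pathway probabilities"
_T3 = "Table 3, dBHL gain parameters"
_T4 = "Table 4, resource use and unit costs (GBP 2010-11)"
_METHODS = "Methods text"


def default_deck() -> ParameterDeck:
    """The deck populated with every published parameter of the model."""
    probabilities = {
        "otorrhoea": ProbabilityParam(
            "otorrhoea", 1439, 4052, 0.262, f"{_T1}: ear discharge (otorrhoea)"),
        "granulation": ProbabilityParam(
            "granulation", 37, 850, 0.042, f"{_T1}: granulation tissue"),
        "perforation_first": ProbabilityParam(
            "perforation_first", 178, 7929, 0.022,
            f"{_T1}: tympanic membrane perforation, 1st insertion"),
        "perforation_subsequent": ProbabilityParam(
            "perforation_subsequent", 557, 2799, 0.166,
            f"{_T1}: tympanic membrane perforation, >=2 insertions"),
        "removal_first": ProbabilityParam(
            "removal_first", 6, 77, 0.072, f"{_T2}: removal of VTs, 1st insertion"),
        "removal_subsequent": ProbabilityParam(
            "removal_subsequent", 7, 34, 0.171,
            f"{_T2}: removal of VTs, >=2 insertions"),
        "reinsertion_2nd": ProbabilityParam(
            "reinsertion_2nd", 25, 75, 0.25, f"{_T2}: re-insertion of 2nd VTs"),
        "reinsertion_3rd": ProbabilityParam(
            "reinsertion_3rd", 25, 75, 0.25, f"{_T2}: re-insertion of 3rd VTs"),
    }
    costs = {
        "vt_insertion": CostParam(
            "vt_insertion", "gamma", f"{_T4}: insertion of VTs",
            shape=130.45, scale=6.83, mean=891),
        "tympanoplasty": CostParam(
            "tympanoplasty", "gamma", f"{_T4}: tympanoplasty",
            shape=100.11, scale=18.29, mean=1831),
        "vt_removal": CostParam(
            "vt_removal", "gamma", f"{_T4}: removal of VTs",
            shape=130.45, scale=6.83, mean=891),
        "ha_device": CostParam(
            "ha_device", "fixed", f"{_T4}: hearing aid (each)", value=80),
        "ear_mould": CostParam(
            "ear_mould", "fixed", f"{_T4}: ear-mould (each)", value=17),
        "ha_maintenance_kit": CostParam(
            "ha_maintenance_kit", "fixed", f"{_T4}: HA maintenance kit",
            value=20.88),
        "ha_battery": CostParam(
            "ha_battery", "fixed", f"{_T4}: HA battery (each)", value=0.49),
        "ha_fitting": CostParam(
            "ha_fitting", "gamma", f"{_T4}: HA fitting (pair)",
            shape=71.03, scale=1.07, mean=76),
        "medication": CostParam(
            "medication", "fixed", f"{_T4}: medication course", value=11),
        "gp_visit": CostParam(
            "gp_visit", "gamma", f"{_T4}: GP visit",
            shape=341.67, scale=0.12, mean=41),
        "audiology_visit": CostParam(
            "audiology_visit", "gamma", f"{_T4}: audiological assessment",
            shape=64, scale=0.75, mean=48),
        "ent_visit": CostParam(
            "ent_visit", "gamma", f"{_T4}: ENT outpatient visit",
            shape=84.14, scale=1.09, mean=91.72),
    }
    gains_list = [
        HearingGainParam("VTs", "year1", 13.06, 9.49, f"{_T3}: VTs after 1 year"),
        HearingGainParam("VTs", "year2", 12.24, 9.1, f"{_T3}: VTs after 2 years"),
        HearingGainParam("HAs", "year1", 4.88, 11.11, f"{_T3}: HAs after 1 year"),
        HearingGainParam("HAs", "year2", 7.57, 12.76, f"{_T3}: HAs after 2 years"),
    ]
    deck = ParameterDeck(
        probabilities=probabilities,
        costs=costs,
        gains={g.name: g for g in gains_list},
        utility=UtilityParam(0.00874, 0.005, 0.012),
        constants=ScalarConstants(),
    )
    return deck.validate()


# ---------------------------------------------------------------------------
# YAML (de)serialization.

_TOP_KEYS = {"schema_version", "probabilities", "costs", "gains", "utility",
             "constants"}


def _require_keys(mapping: dict, allowed: set[str], required: set[str],
                  context: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise DeckValidationError(
            f"{context}: unknown keys {sorted(unknown)}"
        )
    missing = required - set(mapping)
    if missing:
        raise DeckValidationError(
            f"{context}: missing required keys {sorted(missing)}"
        )


def load_deck(path) -> ParameterDeck:
    """Load and validate a parameter deck from a YAML config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise DeckValidationError("config root must be a mapping")
    _require_keys(raw, _TOP_KEYS, _TOP_KEYS - {"schema_version"}, "config")

    probabilities = {}
    for name, entry in raw["probabilities"].items():
        _require_keys(entry, {"alpha", "beta", "mean", "source_ref"},
                      {"alpha", "beta", "mean", "source_ref"},
                      f"probability '{name}'")
        probabilities[name] = ProbabilityParam(name=name, **entry)

    costs = {}
    for name, entry in raw["costs"].items():
        kind = entry.get("kind")
        if kind == "gamma":
            _require_keys(entry, {"kind", "shape", "scale", "mean", "source_ref"},
                          {"kind", "shape", "scale", "source_ref"},
                          f"cost '{name}'")
        else:
            _require_keys(entry, {"kind", "value", "source_ref"},
                          {"kind", "value", "source_ref"}, f"cost '{name}'")
        costs[name] = CostParam(name=name, **entry)

    gains = {}
    for name, entry in raw["gains"].items():
        _require_keys(entry,
                      {"strategy", "horizon", "mean_dBHL", "sd_dBHL", "source_ref"},
                      {"strategy", "horizon", "mean_dBHL", "sd_dBHL", "source_ref"},
                      f"gain '{name}'")
        g = HearingGainParam(**entry)
        if g.name != name:
            raise DeckValidationError(
                f"gain '{name}': key does not match strategy/horizon "
                f"(expected '{g.name}')"
            )
        gains[name] = g

    _require_keys(raw["utility"], {"mean_per_dBHL", "ci_low", "ci_high"},
                  {"mean_per_dBHL", "ci_low", "ci_high"}, "utility")
    utility = UtilityParam(**raw["utility"])

    const_fields = set(ScalarConstants.__dataclass_fields__)
    _require_keys(raw["constants"], const_fields, set(), "constants")
    constants = ScalarConstants(**raw["constants"])

    deck = ParameterDeck(probabilities=probabilities, costs=costs,
                         gains=gains, utility=utility, constants=constants)
    return deck.validate()


def save_deck(deck: ParameterDeck, path) -> None:
    """Write a deck to YAML; ``load_deck`` of the result round-trips."""
    with open(path, "w") as fh:
        yaml.safe_dump(deck.to_dict(), fh, sort_keys=False)


def default_deck_path():
    """Path of the shipped default config (equals ``default_deck()``)."""
    return resources.files("glueear").joinpath("data/default_deck.yaml")


# ---------------------------------------------------------------------------
# Sampling.


def sample_params(
    deck: ParameterDeck,
    rng: np.random.Generator,
    size: int | None = None,
    fixed: Mapping[str, float | np.ndarray] | None = None,
    draw_index: int = 0,
) -> SampledParams:
    """Draw one parameter vector (or a batch of ``size``) from the deck priors.

    ``fixed`` pins named entries to given values instead of sampling them —
    the hook used by the partial-perfect-information nested loop.  Entries
    are always drawn in the deck's stable iteration order, so a given seed
    reproduces the same vectors regardless of which entries are pinned.
    """
    fixed = dict(fixed or {})
    unknown = set(fixed) - set(deck.entry_names())
    if unknown:
        raise KeyError(f"unknown fixed parameter(s): {sorted(unknown)}")

    values: dict[str, float | np.ndarray] = {}
    for name, p in deck.probabilities.items():
        if p.alpha == 0 or p.beta == 0:  # degenerate prior
            draw = p.analytic_mean
        else:
            draw = rng.beta(p.alpha, p.beta, size=size)
        values[name] = fixed.get(name, draw)
    for name, c in deck.costs.items():
        if c.kind == "gamma":
            draw = rng.gamma(c.shape, c.scale, size=size)
            values[name] = fixed.get(name, draw)
        else:
            values[name] = fixed.get(name, c.value)
    for name, g in deck.gains.items():
        draw = rng.normal(g.mean_dBHL, g.sd_dBHL, size=size)
        values[name] = fixed.get(name, draw)
    u = deck.utility
    draw = rng.normal(u.mean_per_dBHL, u.sd, size=size)
    values[u.name] = fixed.get(u.name, draw)

    return SampledParams(values=values, constants=deck.constants,
                         draw_index=draw_index)


# ---------------------------------------------------------------------------
# Scenario decks.


def scenario_deck(deck: ParameterDeck, overrides: Mapping[str, float]) -> ParameterDeck:
    """Return a new deck with entry means overridden; the input is untouched.

    Override semantics, per entry type:

    * probability — the beta prior is re-scaled to the new mean, keeping the
      effective sample size alpha+beta (so the prior stays a valid beta);
    * gamma cost — the scale is adjusted to hit the new mean, keeping shape;
    * fixed cost — the value is replaced;
    * hearing gain — the mean is replaced, keeping the sd;
    * utility — mean replaced and the CI shifted by the same amount;
    * constants — the named field is replaced.

    The resulting deck is re-validated; an out-of-range override (for
    example a probability above 1) raises :class:`DeckValidationError`.
    """
    probabilities = dict(deck.probabilities)
    costs = dict(deck.costs)
    gains = dict(deck.gains)
    utility = deck.utility
    constants = deck.constants

    for name, value in overrides.items():
        if name in probabilities:
            p = probabilities[name]
            if not 0.0 <= value <= 1.0:
                raise DeckValidationError(
                    f"probability '{name}': override {value} outside [0, 1]"
                )
            n0 = p.alpha + p.beta
            probabilities[name] = replace(
                p, alpha=value * n0, beta=(1.0 - value) * n0, mean=value)
        elif name in costs:
            c = costs[name]
            if c.kind == "gamma" and value > 0:
                costs[name] = replace(c, scale=value / c.shape, mean=value)
            else:
                # a zero mean collapses a gamma prior to a fixed point value
                costs[name] = replace(c, kind="fixed", value=value,
                                      shape=None, scale=None, mean=None)
        elif name in gains:
            gains[name] = replace(gains[name], mean_dBHL=value)
        elif name == utility.name:
            shift = value - utility.mean_per_dBHL
            utility = replace(utility, mean_per_dBHL=value,
                              ci_low=utility.ci_low + shift,
                              ci_high=utility.ci_high + shift)
        elif name in ScalarConstants.__dataclass_fields__:
            constants = replace(constants, **{name: value})
        else:
            raise KeyError(f"unknown deck entry '{name}'")

    new = ParameterDeck(probabilities=probabilities, costs=costs,
                        gains=gains, utility=utility, constants=constants)
    return new.validate()
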