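"""End-to-end pipeline runner and report formatting.

``run_pipeline`` executes deck loading, the PSA, incremental analysis,
acceptability frontier and value-of-information estimation, and writes
machine-readable CSVs plus a JSON manifest that uniquely determines every
numeric output (re-running with the same manifest reproduces them exactly).
``report_tables`` renders the incremental and EVPI summaries as plain-text
tables at the conventional display precision: whole pounds for money,
three decimals for QALYs, two for probabilities.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass
from datetime import datetime, timezone
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .params import ParameterDeck, default_deck, load_deck, scenario_deck
from .psa import (PsaMatrix, ceaf, ce_plane, default_lambda_grid,
                  incremental_analysis, run_psa)
from .pathways import StrategyId
from .voi import (ParameterPartition, PopulationSpec, effective_population,
                  evpi, evpi_se, evppi, qaly_parameter_names)

__all__ = ["RunManifest", "PipelineResults", "run_pipeline", "report_tables",
           "round_half_up"]

log = logging.getLogger("glueear")


def round_half_up(value: float, decimals: int = 0) -> float:
    """Decimal round-half-up (0.2175 -> 0.218 at 3 decimals), for display."""
    value = float(value)
    if not np.isfinite(value):
        return value
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class RunManifest:
    """Everything needed to replay a pipeline run bit-for-bit."""

    deck_fingerprint: str
    seed: int
    n_sims: int
    lambda_grid: list
    lam: float
    evppi_of_interest: list
    evppi_n_outer: int
    evppi_n_inner: int
    timestamp: str
    artifact_version: str

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class PipelineResults:
    manifest: RunManifest
    psa: PsaMatrix
    incremental: "pd.DataFrame"
    icers: dict
    ceaf_table: pd.DataFrame
    evpi_table: pd.DataFrame
    evppi_report: pd.DataFrame
    output_dir: Path | None


_VOI_LAMBDAS = (5_000.0, 10_000.0, 15_000.0, 20_000.0, 25_000.0, 30_000.0)


def run_pipeline(
    config_path=None,
    output_dir=None,
    overrides: Mapping[str, float] | None = None,
    seed: int = 20_000,
    n_sims: int | None = None,
    lam: float = 20_000.0,
    lambda_grid: Sequence[float] | None = None,
    evppi_of_interest: Sequence[str] | None = None,
    evppi_n_outer: int = 100,
    evppi_n_inner: int = 1_000,
    run_evppi: bool = True,
    population: PopulationSpec = PopulationSpec(),
) -> PipelineResults:
    """Run the full analysis and (optionally) write its output files.

    Output files: psa_draws.csv, ce_plane.csv, ceaf.csv,
    incremental_table.csv, evpi_table.csv, evppi_report.csv, manifest.json.
    """
    deck = load_deck(config_path) if config_path else default_deck()
    if overrides:
        deck = scenario_deck(deck, overrides)
    if n_sims is None:
        n_sims = deck.constants.n_sims
    if lambda_grid is None:
        lambda_grid = default_lambda_grid()
    if evppi_of_interest is None:
        evppi_of_interest = qaly_parameter_names(deck)

    log.info("running PSA: %d simulations, seed %d", n_sims, seed)
    psa = run_psa(deck, n_sims=n_sims, seed=seed)

    inc = incremental_analysis(psa, lam=lam)
    log.info("incremental analysis at lambda=%.0f: %s", lam,
             "; ".join(f"{k[0]} vs {k[1]}: "
                       + (f"{v:.0f}/QALY" if v is not None else "undefined")
                       for k, v in inc.icers.items()) or "no ICERs")

    curve = ceaf(psa, lambda_grid)
    plane = ce_plane(psa, reference=StrategyId.HAS, comparator=StrategyId.VTS)

    pop = effective_population(population)
    voi_rows = []
    for lx in _VOI_LAMBDAS:
        nb = psa.net_benefits(lx)
        per_person = evpi(nb)
        voi_rows.append({
            "lam": lx,
            "evpi_per_person": per_person,
            "evpi_se": evpi_se(nb),
            "effective_population": pop,
            "evpi_population": per_person * pop,
        })
    evpi_table = pd.DataFrame(voi_rows)

    evppi_rows = []
    if run_evppi:
        log.info("EVPPI: %d outer x %d inner loops", evppi_n_outer, evppi_n_inner)
        partition = ParameterPartition(of_interest=tuple(evppi_of_interest))
        est, se = evppi(deck, partition, lam, n_outer=evppi_n_outer,
                        n_inner=evppi_n_inner, seed=seed + 1,
                        baseline_nb=psa.net_benefits(lam))
        evppi_rows.append({
            "lam": lam,
            "parameters": ";".join(evppi_of_interest),
            "evppi_per_person": est,
            "evppi_se": se,
            "evppi_population": est * pop,
        })
    evppi_report = pd.DataFrame(
        evppi_rows, columns=["lam", "parameters", "evppi_per_person",
                             "evppi_se", "evppi_population"])

    manifest = RunManifest(
        deck_fingerprint=deck.fingerprint(),
        seed=seed,
        n_sims=n_sims,
        lambda_grid=[float(x) for x in lambda_grid],
        lam=lam,
        evppi_of_interest=list(evppi_of_interest) if run_evppi else [],
        evppi_n_outer=evppi_n_outer,
        evppi_n_inner=evppi_n_inner,
        timestamp=datetime.now(timezone.utc).isoformat(),
        artifact_version=__version__,
    )

    results = PipelineResults(
        manifest=manifest, psa=psa, incremental=inc.table, icers=inc.icers,
        ceaf_table=curve.table, evpi_table=evpi_table,
        evppi_report=evppi_report,
        output_dir=Path(output_dir) if output_dir else None,
    )
    if output_dir is not None:
        _write_outputs(results, plane)
    return results


def _write_outputs(results: PipelineResults, plane) -> None:
    out = results.output_dir
    out.mkdir(parents=True, exist_ok=True)
    results.psa.to_frame().to_csv(out / "psa_draws.csv", index=False)
    plane.to_frame().to_csv(out / "ce_plane.csv", index=False)
    results.ceaf_table.to_csv(out / "ceaf.csv", index=False)
    results.incremental.to_csv(out / "incremental_table.csv", index=False)
    results.evpi_table.to_csv(out / "evpi_table.csv", index=False)
    results.evppi_report.to_csv(out / "evppi_report.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(results.manifest.to_dict(), fh, indent=2)
    log.info("wrote outputs to %s", out)


def _format_table(df: pd.DataFrame) -> str:
    if df.empty:
        return "  ".join(df.columns)
    return df.to_string(index=False)


def report_tables(results: PipelineResults) -> str:
    """Human-readable incremental and EVPI tables at display precision."""
    inc = results.incremental.copy()
    display = pd.DataFrame({
        "Strategy": inc["strategy"],
        "Cost": [f"£{round_half_up(v):,.0f}" for v in inc["mean_cost"]],
        "QALY gained": [f"{round_half_up(v, 3):.3f}" for v in inc["mean_qaly"]],
        "Cost per QALY": [f"£{round_half_up(v):,.0f}" for v in inc["cost_per_qaly"]],
        "Net benefit": [f"£{round_half_up(v):,.0f}" for v in inc["net_benefit"]],
        "Dominated": ["yes" if d else "" for d in inc["strongly_dominated"]],
    })
    lines = [f"Incremental analysis (lambda = £{results.manifest.lam:,.0f}/QALY)",
             _format_table(display), ""]
    for (hi, lo), v in results.icers.items():
        icer_txt = f"£{round_half_up(v):,.0f}/QALY" if v is not None else "undefined"
        lines.append(f"ICER {hi} vs {lo}: {icer_txt}")

    ev = results.evpi_table
    ev_display = pd.DataFrame({
        "Threshold": [f"£{v:,.0f}" for v in ev.get("lam", [])],
        "EVPI per person": [f"£{round_half_up(v):,.0f}"
                            for v in ev.get("evpi_per_person", [])],
        "EVPI population": [f"£{round_half_up(v):,.0f}"
                            for v in ev.get("evpi_population", [])],
    })
    lines += ["", "Expected value of perfect information",
              _format_table(ev_display)]

    if not results.evppi_report.empty:
        row = results.evppi_report.iloc[0]
        lines += ["", (f"EVPPI ({row['parameters']}) at "
                       f"£{row['lam']:,.0f}/QALY: "
                       f"£{round_half_up(row['evppi_per_person']):,.0f} "
                       f"per person (SE £{row['evppi_se']:,.0f}); "
                       f"£{round_half_up(row['evppi_population']):,.0f} "
                       "at population level")]
    return "\n".join(lines)
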