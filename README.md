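# glueear

A decision-analytic cost-effectiveness and value-of-information model for the
management of persistent bilateral otitis media with effusion ("glue ear") in
children, comparing three strategies over a 24-month horizon from a UK NHS
cost perspective:

* **VTs** — surgical insertion of ventilation tubes (grommets), with up to
  two re-insertions and post-operative complication pathways;
* **HAs** — bilateral hearing aids, relying on natural resolution of the
  effusion (30.8% by 12 months);
* **HAs plus VTs** — hearing aids for the first year, with unresolved
  children switching to the ventilation-tube pathway in the second year.

The package is aimed at health economists and HTA analysts who want a tested,
scriptable re-implementation of this model: every input is a named entry in a
validated *parameter deck* (beta priors for pathway probabilities, gamma
priors for unit costs, normal priors for hearing gains), and the whole
pipeline — decision-tree evaluation, probabilistic sensitivity analysis,
incremental cost-effectiveness, acceptability frontiers and expected value of
(partial) perfect information — is deterministic under a seed.

## Model

Health benefit is measured in QALYs as a linear function of hearing gain:
with a utility increment *u* per dBHL (0.00874, 95% CI 0.005–0.012) and mean
gains *g₁*, *g₂* over the first and second year,

    QALY = u · (g₁ + g₂ / 1.035),

second-year quantities discounted once at 3.5%. Costs accrue along the
care pathways analytically (expectations over branch probabilities; no
microsimulation). Strategies are compared by ICER (Δcost/ΔQALY of the
unrounded PSA means, with strong-dominance handling) and net monetary
benefit NB = λ·QALY − cost at a willingness-to-pay λ. Decision uncertainty
is summarised by the per-draw probability each strategy maximises NB
(CEAC/CEAF) and by value-of-information statistics:

    EVPI  = E_θ[ max_j NB(j,θ) ] − max_j E_θ[ NB(j,θ) ]
    EVPPI = E_ϑ[ max_j E_φ|ϑ NB(j,φ,ϑ) ] − max_j E_θ[ NB(j,θ) ]

with EVPPI estimated by a nested two-loop Monte Carlo (default 100 outer ×
1,000 inner draws) and per-person EVPI scaled to the discounted population
of future patients (25,000/year over 5 years at 3.5% ≈ 116,827 children).

See `docs/methods.md` for assumptions, parameter-by-parameter defaults and
known limitations.

## Worked example

```bash
glueear psa --n-sims 10000 --seed 20000
```

prints (logs go to stderr, results to stdout):

```
Incremental analysis (lambda = £20,000/QALY)
    Strategy   Cost QALY gained Cost per QALY Net benefit Dominated
         VTs £1,766       0.219        £8,078      £2,607
         HAs £1,202       0.106       £11,300        £926
HAs plus VTs £2,487       0.139       £17,899        £292       yes

ICER VTs vs HAs: £5,023/QALY

Expected value of perfect information
Threshold EVPI per person EVPI population
   £5,000            £366     £42,701,920
  £10,000            £481     £56,175,124
  £15,000            £625     £73,000,610
  £20,000            £781     £91,281,552
  £25,000            £944    £110,246,358
  £30,000          £1,109    £129,581,056
```

Reading: inserting ventilation tubes costs £564 more than hearing aids per
child but yields 0.113 extra QALYs, an ICER of about £5,000/QALY — well
under the conventional £20,000 threshold, where tubes offer the highest net
benefit and the combined strategy is strongly dominated (dearer and less
effective than tubes alone). A per-person EVPI of ~£780 at £20,000/QALY,
~£91m over the affected population, bounds the value of further research.

Other subcommands: `glueear ceaf` (acceptability frontier over a λ grid),
`glueear voi`, `glueear evppi --of-interest gain_vts_year1 ...`, and
`glueear all`. Add `--out DIR` to write per-draw CSVs
(`psa_draws.csv`, `ce_plane.csv`, `ceaf.csv`, `incremental_table.csv`,
`evpi_table.csv`, `evppi_report.csv`) plus a `manifest.json` that replays
the run exactly. The same pipeline is available as a library:

```python
from glueear import default_deck, run_psa, incremental_analysis, evpi

psa = run_psa(default_deck(), n_sims=10_000, seed=1)
print(incremental_analysis(psa, lam=20_000).icers)
print(evpi(psa.net_benefits(20_000)))
```

Custom parameter decks are YAML files with the schema of
`src/glueear/data/default_deck.yaml`; load them with `--config` or
`load_deck`, or perturb entries programmatically with `scenario_deck`.

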