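# Methods

## Decision problem and model structure

The model compares three ways of managing persistent bilateral otitis media
with effusion in children under 12: immediate surgical insertion of
ventilation tubes (VTs), bilateral hearing aids (HAs) with the effusion left
to resolve naturally, and hearing aids followed by tubes for children
unresolved at 12 months. It is a two-year decision tree evaluated in
expectation: for a given parameter vector, each strategy's cost is the
probability-weighted sum over its care pathways, and its benefit is a QALY
gain proportional to the hearing improvement. The cohort is a reporting
device only — no individual children are simulated.

Time is split into two annual windows. Year-1 quantities are undiscounted;
every year-2 quantity (costs and gains alike) is discounted once by
1/(1+r) with r = 3.5%/year. Events are not located more finely than the
year that contains them, so there is no sub-year discounting; this matches
the annual convention used for the population scaling.

### Ventilation-tube pathway

The first insertion is certain and occurs in year 1. A second insertion
occurs within year 1 with probability 0.25, and a third within year 2 with
probability 0.25 × 0.25 (insertions are capped at three, and at most one
further insertion happens per year). Each insertion episode accrues, in
expectation:

* the insertion procedure (gamma prior, mean £891);
* otorrhoea (p = 0.262) and granulation tissue (p = 0.042), each managed by
  one GP visit plus one medication course;
* tympanic-membrane perforation triggering a tympanoplasty (p = 0.022 for
  the first insertion, 0.166 for later ones);
* tube removal (p = 0.072 first insertion, 0.171 later), costed as one
  removal procedure and treated as a terminal event within the episode —
  removed children do not re-enter the re-insertion cascade;
* 2 ENT follow-up visits (the week-6 visit plus the single 26-week
  follow-up that fits before the 39-week extrusion time) and 1.5
  audiological assessments.

The ENT count of 2 and the audiology count of 1.5 per episode resolve the
published visit *schedule* into per-episode counts; the schedule fixes them
uniquely given the extrusion time.

### Hearing-aid pathway

Year 1 accrues a one-off start-up (two devices at £80 each, one fitting of
the pair, one maintenance kit) plus a recurring annual block: two ear-moulds
every 13 weeks (4 sets/year), two batteries every 4 weeks (13 sets/year),
accidental breakage/loss re-incurring devices plus fitting with annual
probability 16.44% (at most once per year, no compounding), 2 audiology
visits (week 13 plus one 26-week follow-up per 12-month window), 1.5 ENT
visits, and 2.8 GP visits for acute otitis media, each with a medication
course. Medication attaches to GP visits only, not to ENT visits.

In year 2 the recurring block continues, discounted, for the 69.2% of
children whose effusion has not resolved by 12 months. The published dBHL
trajectory for this strategy is a cohort average that already embeds
natural resolution, so resolution affects year-2 *costs* only — applying it
to the gains as well would double-count it.

### Combined pathway

Year 1 equals the hearing-aid year 1 (costs and gains). In year 2 the
hearing-aid recurring costs continue for the whole cohort while the
unresolved 69.2% additionally receive the ventilation-tube first-year
pathway (first insertion plus possible second insertion), everything
discounted. The year-2 gain basis mixes the tube first-year gain (weight
0.692) with the hearing-aid year-2 trajectory (weight 0.308). The published
sources fix the pathway composition of this arm only loosely; this
composition is a calibration choice — it is the one consistent with the
published per-strategy mean costs — and should be read as such.

## QALYs

QALY = u · (g₁ + g₂/1.035), where u is the utility increment per dBHL and
g₁, g₂ the mean hearing gains after one and two years. The mapping is
linear and identical across strategies, so u cannot favour any strategy in
the effectiveness ranking; it scales every QALY (and hence every
net-benefit difference) multiplicatively.

## Parameter deck and priors

Every input lives in a validated deck with a source reference. Defaults:

| group | prior | validation |
|---|---|---|
| pathway probabilities (8) | beta(α, β) | α/(α+β) reproduces the published point estimate within 0.001 |
| unit costs, uncertain (6) | gamma(shape, scale) | shape·scale reproduces the published unit cost within £1 |
| unit costs, fixed (6) | point value | non-negative |
| hearing gains (4) | normal(mean, sd), untruncated | sd ≥ 0 |
| utility per dBHL | normal(0.00874, sd), sd = (0.012−0.005)/(2·1.96) ≈ 0.00179 | mean within CI |

Choices worth flagging:

* The second parameter of each hearing-gain prior is an SD, not a variance
  (an SD near 9–13 dB is the clinically plausible dispersion; as a variance
  it would imply implausibly tight uncertainty).
* Hearing-gain and utility draws are **untruncated** normals: negative
  sampled gains are meaningful (a hearing deterioration) and produce
  negative QALY contributions.
* No distribution family is published for the utility increment; the
  normal-from-CI choice above is ours. It must be stochastic for the
  partial-information analysis of the QALY parameters to be non-trivial.
* Per-year visit counts (2.8 AOM, 1.5 ENT, 1.5 audiology) are deterministic
  expectations — no dispersion is published for them.
* All entries are sampled independently; the deck declares no correlations.
* The gain parameters are *shared* across strategies within a draw: the
  combined arm's year-2 gain re-uses the same sampled tube-year-1 gain as
  the tube strategy. This matters for decision uncertainty (it correlates
  the arms' net benefits).

Degenerate entries are representable for scenario work: a probability
overridden to 0 or 1 becomes a point mass (α or β = 0), a gamma cost
overridden to 0 collapses to a fixed £0.

## Probabilistic sensitivity analysis

10,000 draws by default, vectorized, seeded through a single
`numpy.random.Generator`; entries are drawn in the deck's stable iteration
order, so a seed fully determines the run (the PSA matrix carries the seed
and a SHA-256 deck fingerprint for replay). Mean costs/QALYs, cost per
QALY, strong dominance, ICERs between non-dominated strategies (from
unrounded means), and net benefit at λ are computed from the matrix.
Acceptability is the fraction of draws in which a strategy attains the
maximum net benefit, ties splitting weight equally (a measure-zero event
under continuous priors); the frontier strategy at each λ is the argmax of
mean net benefit. The default λ grid is £0–£30,000 in £500 steps. Every
stochastic estimate is reported with its Monte Carlo standard error.

## Value of information

EVPI is computed directly on the net-benefit matrix as
mean(per-draw max) − max(per-strategy mean), clamped at zero. The effective
population multiplies 25,000 eligible children/year over a 5-year decision
horizon with per-cohort discounting at 3.5%, first cohort undiscounted:
25,000 · Σ_{t=0..4} 1.035⁻ᵗ ≈ 116,827. (Indexing t = 1..5 instead would
give 112,876 and does not reproduce the published count.) Per-person EVPI
is carried unrounded into the population scaling.

EVPPI uses the plain nested two-loop estimator: the outer loop draws the
parameters of interest (default subset: the utility increment plus the four
hearing gains — the QALY drivers); the inner loop, with the outer draw
pinned, draws the complement independently and averages each strategy's net
benefit; the estimate is the mean of the per-outer best values minus the
best overall expected net benefit. Defaults are 100 outer × 1,000 inner
draws. The reported standard error reflects outer-loop dispersion only;
inner-loop noise additionally gives the estimator a small upward bias at
finite inner size, which is why the Jensen bound 0 ≤ EVPPI ≤ EVPI is only
asserted within two standard errors. Regression-based EVPPI approximations
are deliberately out of scope.

## Numerical conventions

Internal computation is full double precision; rounding is display-only
(round-half-up: whole pounds, 3-decimal QALYs, 2-decimal probabilities).
An ICER between strategies with equal mean QALYs is reported as undefined,
not infinite. Cost breakdowns are category-conserving by construction and
verified as an invariant.

## What passing tests show — and don't

The tests validate the arithmetic of this model against its published
summary tables and against hand-computed closed forms at the prior means,
plus structural invariants (conservation, monotonicity, linearity, Jensen
bracketing, seed determinism). The parameter deck *is* the evidence base:
nothing here re-estimates inputs from patient data, models adenoidectomy,
non-adherence, cholesteatoma or rare surgical harms, or extends beyond the
24-month horizon — so agreement with the published tables demonstrates a
faithful re-implementation, not clinical validity of the inputs.

## Known limitations and discrepancies

* The year-2 cost composition of the hearing-aid and combined arms is
  reverse-engineered to the published mean costs (see above); the sources
  do not itemize which components recur.
* Our PSA reproduces the published per-person EVPI at all six thresholds to
  within ~2%, which pins down the net-benefit distribution. On that same
  distribution the probability that the tube strategy maximises net benefit
  at £20,000/QALY is ≈0.65, and the net-benefit-based share of
  tube-vs-hearing-aid draws below the £20,000 line is ≈0.67. The published
  counterparts (0.58 and "some 90%") are not consistent with the published
  EVPI table under any sampling variant we examined; counting draws with
  per-draw ICER < λ — a known cost-effectiveness-plane miscounting of the
  negative-ΔQALY quadrants — yields ≈0.94 on our draws and is the likely
  origin of the 90% figure. We report the net-benefit-based quantities.
* EVPPI standard errors understate total Monte Carlo uncertainty (outer
  loop only).
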