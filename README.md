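# mhss — regional equity of medical and health services supply

`mhss` is a Python toolkit for measuring how equitably medical and health
services supply (MHSS) is distributed across regions, built around the
analysis design used in Chinese provincial health-equity studies: a
composite provincial index aggregated by **two-stage nested entropy
weighting**, spatial summary by the **weighted standard deviational
ellipse**, inequality measurement by the **Dagum Gini decomposition**
(within-region, between-region, and transvariation components),
**β-convergence** panel regressions with two-way fixed effects, and
distributional dynamics via **kernel densities** and **(spatial) Markov
transition matrices**. It is aimed at health-economics and public-health
researchers who have a province × year × indicator panel and want the
whole pipeline — validated, tested, and reproducible — rather than a
spreadsheet of one-off scripts.

## The model in brief

Indicators x_itjk (province i, year t, indicator k in dimension j, with a
benefit/cost attribute) are min-max normalized over the pooled panel and
entropy-weighted twice — within each dimension, then across dimensions —
giving a composite score M_it ∈ [0,1]. Yearly cross-sections of M are then

- split by the Dagum identity G = G_w + G_nb + G_t over a region scheme,
- regressed as ln(y_{i,t+1}/y_it) = α + β ln y_it (+ controls) + μ_i +
  η_t + ε, with convergence speed v = −ln(1+β)/T,
- classified into per-year quartile classes I–IV whose annual transitions
  form row-stochastic Markov matrices, optionally conditioned on the
  contiguity-lag class of each province's neighbourhood.

A synthetic-data module generates panels with this exact structure
(31 provinces in three regions, 2005–2020, 18 indicators in 6 dimensions)
from a latent convergence process with recorded ground truth, so every
stage is testable as a recovery problem. See `docs/methods.md` for the
full treatment.

## Worked example

Simulate a study-shaped panel, score it, and run the inequality and
dynamics stages (the `mhss` console script is equivalent to
`python -m mhss.cli`):

```sh
mhss simulate --seed 42 --out synth
mhss score   --panel synth/panel.csv --spec synth/indicator_spec.csv --out scores
mhss gini    --scores scores/scores.csv --out gini
mhss converge --scores scores/scores.csv --out conv
mhss markov  --scores scores/scores.csv --contiguity synth/contiguity.csv --out markov
```

which prints

```
wrote synthetic panel (496 records) to synth/
dimension weights (%): human_resources=16.96, facilities=15.68, healing_ability=17.59, primary_care=17.34, service_utilization=15.30, disease_control=17.14
G: 0.3723 -> 0.0758 (decline 79.63%)
beta = -0.3617*** (se 0.0398), N = 465, v = 0.0299
total transitions: 465
```

Reading the numbers: the generated panel has 496 province-year records
(31 provinces × 16 years). The six dimension weights are the stage-2
entropy weights in percent (they always sum to 100). The overall Gini
coefficient of the composite score falls from 0.3723 to 0.0758 across the
sample — a 79.63% decline, as expected for a panel generated with
convergent dynamics (β_true = −0.2 < 0). The fixed-effects regression on
465 annual growth observations finds β̂ = −0.36 (significant at 1%,
province-clustered SE), i.e. convergence, with implied speed v ≈ 0.03 per
year; the estimate is steeper than β_true both because the entropy score
is a nonlinear transform of the latent level and because the within
estimator of a dynamic panel carries a small-T (Nickell) bias — see the
convergence section of `docs/methods.md`. The Markov stage counts
465 = 31 × 15 annual class transitions. Each output directory also holds
CSV tables (per-year decompositions, the full regression table, the
4 lag-conditioned transition matrices) and a JSON run-log.

The same pipeline is available as library functions (`mhss.score`,
`mhss.gini_series`, `mhss.beta_convergence`, `mhss.sde`,
`mhss.spatial_transition_matrices`, ...) operating on pandas objects.

## Layout

```
src/mhss/
  panel.py      data model, CSV I/O, validation, interpolation, regions
  china.py      three-region scheme and queen contiguity for 31 provinces
  synthetic.py  panel generator with recorded ground truth
  entropy.py    two-stage nested entropy index
  ellipse.py    weighted mean center, SDE, trajectory
  inequality.py Dagum Gini decomposition, beta convergence
  dynamics.py   KDE, quartile classes, (spatial) Markov chains
  cli.py        click command group chaining the stages
```
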