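# Methods

`mhss` measures the regional equity of medical and health services supply
(MHSS) from a provincial indicator panel. The pipeline has five analysis
stages fed by a common data model, plus a synthetic-data generator used to
test every stage as a recovery problem with known truth. This note records
the models, the defaults and why, the numerical conventions, and what the
synthetic experiments do and do not establish.

## Composite index: two-stage nested entropy weighting

Each of K indicators x_itjk (province i, year t, dimension j, indicator k)
is min-max normalized over the **pooled** panel — all provinces and years
jointly — with cost indicators reversed:

    p'_itjk = (x - min x)/(max x - min x)        (benefit, attribute +)
    p'_itjk = (max x - x)/(max x - min x)        (cost, attribute -)

Pooling the frame is what makes scores comparable across years; a per-year
frame would re-standardize away exactly the trend the convergence and
transition stages measure. Each indicator's normalized column is rescaled
to a probability vector over the T·N cells, and its Shannon entropy is
normalized by ln(T·N):

    e_jk = -1/ln(TN) * sum_it p ln p,    with 0·ln 0 := 0.

No epsilon is added to the data, so the closed forms (uniform shares → 1,
degenerate → 0) hold exactly. Within dimension j the indicator weights are
information shares, w_jk = (1-e_jk)/Σ_k (1-e_jk), and the stage-1 dimension
score is s_itj = Σ_k w_jk p'_itjk. Stage 2 repeats the device one level up:
the dimension scores are re-shared over cells, their entropy e_j computed
the same way, and the dimension weights are W_j = (1-e_j)/Σ_j (1-e_j). The
composite score is M_it = Σ_j W_j s_itj ∈ [0,1].

Two conventions worth noting. Stage 2 aggregates the min-max values p'
(not the shares p) into s_itj; aggregating shares would scale s with
1/(TN) and break the [0,1] bound of M. A constant indicator carries no
information: it gets entropy 1 (weight 0) and a neutral p' = 0.5 with a
warning, rather than aborting a run; a whole dimension of constant
indicators is an error, since no weights can be formed.

## Spatial summary: weighted standard deviational ellipse

Provinces are points in projected planar coordinates, weighted by their
score M_it (the weighting variable is configurable; score weighting is the
default). The mean center is the weighted centroid. The ellipse axes are
the principal directions of the weighted covariance of deviations about
the center; the azimuth of the **long** axis is reported clockwise from
true north in [0°, 180°), and equals the bearing that maximizes the
weighted directional variance (a grid-search oracle verifies this in the
tests). Degenerate conventions: zero cross-moment → azimuth 0° if the
north-south variance is at least the east-west variance, else 90°; a
circular pattern reports 0°. Semi-axes default to the directional standard
deviations; `arcgis_scale` multiplies them by √2 for comparability with
the common GIS 1-σ ellipse. All computation is planar: units in, units
out; no geodesy.

## Inequality: Dagum decomposition of the Gini coefficient

For one year's cross-section grouped into regions ordered by mean, the
overall Gini G = Σ|y_a - y_b| / (2 n² ȳ) over all ordered pairs splits
into

    G = G_w + G_nb + G_t

with G_w the weighted sum of within-region Ginis, and the cross-region
terms split by the relative affluence D_jh = (d_jh - p_jh)/(d_jh + p_jh),
where d_jh and p_jh are the mean positive gaps in favour of the
higher-mean and lower-mean region respectively, taken over all cross
pairs. The discrete pairwise estimators replace the distribution-function
integrals, so the identity holds to machine precision on finite samples
(enforced at 1e-12, property-tested on randomized groupings). D is set to
0 when both gap moments vanish (the cross-region Gini is then 0 anyway).
Region ordering is recomputed every year; mean ties keep declaration
order. The trend summary reports the endpoint decline rate
100·(G_first - G_last)/G_first.

## Convergence: two-way fixed-effects beta regressions

Annual log-growth is regressed on the lagged log level,

    ln(y_{i,t+1}/y_it) = α + β ln y_it [+ λ'controls] + μ_i + η_t + ε_it,

with province and year fixed effects as explicit indicator regressors
(one level of each dropped). β < 0 is convergence. Standard errors are
clustered by province by default (conventional SEs by flag); significance
stars at the 10/5/1% levels. The conditional variant appends five controls
(log per-capita GDP, urbanization rate, fiscal self-sufficiency,
industrial-structure upgrading, log per-capita FDI). The convergence
speed is reported as

    v = -ln(1 + β) / T

with T the number of annual transitions in the sample (T = 15 for a
2005-2020 panel), i.e. the per-year rate at which the gap to the steady
state closes.

A caveat the test suite documents explicitly: with a lagged dependent
variable among the regressors, the within (fixed-effects) estimator
carries the classic Nickell small-T bias of order (1+β)/T — about −0.05
at β = −0.2, T = 15. On noiseless panels the estimate is exact (the bias
scales with the innovation variance); on stochastic panels the estimator
over-states convergence by roughly that order. The tests assert exact
noiseless identification and a bias bounded by twice the Nickell order;
consumers comparing β̂ across samples of similar T are unaffected, but the
point estimate should not be read as unbiased.

## Distributional dynamics

**Kernel densities.** Gaussian kernel, f(x) = 1/(Nh) Σ K((X_i - x)/h),
evaluated on a 512-point grid spanning the data ±3h. The default
bandwidth is Silverman's rule 0.9·min(sd, IQR/1.34)·N^(-1/5); a fixed
bandwidth can be supplied for cross-year comparability. The kernel sum is
evaluated directly so the single-point closed form f = 1/√(2π) at the
datum holds exactly.

**Quartile classes.** Provinces are classified I-IV each year by the
empirical 25/50/75% quantiles (linear interpolation) of that year's
cross-section; values equal to a cut go to the lower class, and a fully
tied year collapses to class I with a warning. Per-year cuts remove the
common upward trend, so classes measure relative position; a pooled-cuts
mode is available by flag. With 31 provinces the class sizes are 8/8/7/8.

**Markov chains.** Transition counts pool all (province, t→t+1) pairs;
probabilities are row-normalized, with never-visited states reported as
zero rows and flagged. The spatial variant conditions each transition on
the origin year's spatial-lag class — the row-standardized
contiguity-weighted neighbour average, classified on the *same* per-year
score cuts, so "neighbours at level III" reads on the score scale. The
four conditional count matrices partition the unconditional counts by
construction, and this is asserted on every run. Homogeneity of the
conditionals is tested with a Pearson chi-square statistic summed over
origin states; because the tables are sparse (many expected counts
below 5) the asymptotic reference is anti-conservative, so a
permutation-calibrated p-value (destinations shuffled within origin
state) is provided and preferred. The long-run summary is the stationary
distribution (left unit eigenvector), with the uniform returned under a
warning when it is not unique (e.g. an identity matrix).

## Synthetic data: what it emulates

The generator mirrors the study design: 31 provinces split 11/8/12 into
eastern/central/western regions, 16 years (2005-2020, 496 province-year
records), 18 indicators in 6 dimensions with mixed attribute signs. The
latent log-score follows the convergence recursion ln y_{t+1} =
ln y_t + α + β ln y_t + ρ·(W ln y)_t + μ_i + η_t + ε, and each indicator
is a sign-consistent monotone loading of y plus indicator noise, so the
entropy index is a monotone read-out of the latent level when noise is
off (rank-tested), and β-convergence is a direct parameter-recovery
problem.

Defaults, chosen once for realism against the study's published summary
statistics and held fixed: initial region mean log-scores −1.4 (east),
−2.0 (central), −1.8 (west) — east > west > central, the ordering the
study reports — with province jitter 0.25, giving a pooled ln y spread
near the published 0.41; β_true = −0.2; α_true = −0.276 so that mean
annual growth ≈ 0.064 at the mean level; ε s.d. 0.05 (published growth
s.d. 0.06); small province/year effects (0.01/0.005); indicator noise
0.02; missing rate 1% (interior cells only, so every series keeps its
interpolation anchors); spatial spillover ρ = 0 by default — it is the
experimental knob for the spatial Markov stage, and the β-recovery
conditions assume no omitted spatial term. The 31-province configuration
uses the bundled queen-contiguity neighbour list for mainland China
(with the Hainan-Guangdong bridge); other sizes get a connected
ring-plus-chords graph. One seed drives all streams through a splittable
generator.

What passing tests show — and don't. The synthetic indicators are clean
monotone transforms of a single latent factor; real yearbook indicators
mix multiple latent dimensions, reporting artefacts and administrative
breaks. Recovery of β, rank-faithfulness of the index, shrinking Gini
under convergent dynamics, and lag-dependent mobility under ρ > 0 validate
the *machinery*, not any empirical claim about China's health system; the
published data-dependent quantities (fitted weights, coefficient values,
ellipse kilometres) are not reproducible without the undeposited panel
and are not targets.

## Degenerate inputs and numerical conventions (summary)

- Missing cells: linear interpolation in year within each
  (province, indicator) series; boundary gaps flat-filled (a slope
  extrapolation is undefined by the method's description; flat fill is
  conservative). Series with <2 observations are errors.
- Entropy: 0·ln 0 = 0 exactly; single-cell panels are errors
  (ln(TN) = 0).
- Ellipse: <3 points or collinear points are errors.
- Gini: non-positive means are errors; single-region input reduces to
  G = G_w exactly.
- Convergence: non-positive scores are errors (logs); rank-deficient
  designs report the offending column.
- Markov: non-consecutive years are errors; zero rows are flagged, not
  renormalized.

## Problem sizes used in the checked experiments

Default panels (31×16) throughout; 200 replicates for the stochastic
β-recovery distribution; 100 seeds × 499 permutations for the ρ = 0
homogeneity calibration; 1000 randomized groupings for the decomposition
identity; 0.1° grids for the ellipse rotation oracle. The full suite runs
in well under a minute on one core.
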