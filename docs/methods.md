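# Methods

This note documents the models implemented in `paleoterm`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions a user auditing results should know.

## Conventions

Ages are years cal BP (before AD 1950); larger values are older, so a
"terminal" or "last appearance" date is the *smallest* cal BP value in
play. Depths are cm, positive downward. All tabular I/O is CSV (comma,
`.` decimal, UTF-8, `#` comments). Every stochastic routine takes an
explicit integer seed and is bit-reproducible from it.

## Radiocarbon calibration

A determination `y ± σ` (¹⁴C yr BP) is calibrated against a curve
`(μ(t), s(t))` interpolated linearly in both the ¹⁴C age and its 1σ
between grid knots. On a regular calendar grid (default step 1 yr) the
posterior mass is proportional to `N(y; μ(t), √(σ² + s(t)²))` under a
uniform prior in calendar age; cells below 10⁻¹² of the peak are truncated
away and the rest renormalized (sum-to-one enforced at 10⁻⁹). The HPD
region at level `p` is the smallest set of grid cells, filled in
decreasing-mass order, whose mass reaches `p`, reported as maximal
contiguous intervals — it is exact for the discrete representation, and on
curve plateaus it correctly splits into disjoint intervals. The median is
the smallest grid age with cumulative mass ≥ 0.5; mode ties resolve to the
older age. Halving the grid step moves the median by less than one step.
No reservoir or laboratory offsets are modelled. The default reporting
level is 95 %.

## GRIWM terminal dates

For sightings sorted youngest-first, `t₁ ≤ … ≤ tₙ`, each record `i ≥ 2`
defines a sighting rate over the interval back to it,
`λᵢ = (i−1)/(tᵢ−t₁)` (sightings per year), a terminal extension
`Δtᵢ = ln α / ln(1−λᵢ)` (the waiting time after `t₁` at which the
probability of seeing no further sighting at rate `λᵢ` falls to `α`), and
a candidate terminal `Tᵢ = t₁ − Δtᵢ`. Candidates are averaged with
weights `wᵢ ∝ 1/(tᵢ−t₁)`, so records near the youngest sighting dominate.
`λᵢ ≥ 1` (more than one sighting per year) gives a zero extension. Exact
ties are separated by a deterministic 0.5-yr ladder before sorting, which
preserves translation equivariance. Dating error is propagated by
resampling each age from `N(mean, sd)` — or from its full calibrated
density when supplied — re-running the deterministic core (default 10,000
iterations, α = 0.05) and reporting the median with (α/2, 1−α/2) quantile
bounds. With all sds zero the resampled median equals the deterministic
value exactly.

Two properties worth knowing. First, the resampling CI is a Monte-Carlo
interval around the estimator, not a calibrated frequentist interval: in
the package's own simulation (uniform recovery over 5,000 yr, n = 15,
sd = 100 yr) it covers the true extinction time in roughly 55–60 % of
replicates — a stable figure asserted in the tests, not a defect of the
implementation. Second, deleting the oldest record is *not* guaranteed to
leave the terminal unchanged or younger: a distant oldest record carries a
low sighting rate, hence a much younger candidate terminal, and removing
it can make the weighted mean older. The deletion test therefore runs on
equal-gap series, where all candidates coincide and deletion is exactly
neutral.

## Uniform-phase boundary model

Records are modelled as `θⱼ ~ Uniform(end, start)` with observation error
`ageⱼ ~ N(θⱼ, sdⱼ)`. The true ages are integrated out analytically,

    p(ageⱼ | start, end) = [Φ((start−ageⱼ)/sdⱼ) − Φ((end−ageⱼ)/sdⱼ)] / (start−end),

leaving a two-parameter posterior that is sampled with random-walk
Metropolis, 4 chains by default (20,000 draws after 2,000 burn-in),
proposal scale set to a tenth of the data span. Convergence is summarized
with split-R̂ per boundary; R̂ > 1.1 flags the result but never raises.
The prior is flat on a box padded well clear of the data, with an optional
span-penalizing factor `1/(start−end)` (default on) that corrects the
uniform-deposition model's preference for long spans and keeps the
posterior proper for a single record. The end boundary's median and 95 %
quantile interval are the last-appearance estimate. In simulation (n = 20,
3,000-yr window, sd = 50) the 95 % end interval covers the truth in ≈ 94 %
of replicates; a 2-D grid-integration oracle agrees with the sampler on
small series.

## Vole thermometer

July temperature is `Σ optimumₛ × percentₛ / 100`, with percentages over
the non-excluded species present in the optima table. The built-in table
is Clethrionomys 15 °C, Arvicola 17.5 °C, *Microtus arvalis* 21 °C,
*M. agrestis* 19 °C, *Lasiopodomys gregalis* 10 °C, *M. oeconomus*
12.5 °C, Dicrostonyx 7.5 °C; *Microtus nivalis* is excluded as a mountain
species with non-zonal distribution. Names resolve exactly, then through a
synonym map, then at genus level against genus-rank keys. Taxa neither in
the table nor excluded are dropped from the denominator and logged.
Assemblages under 10 usable individuals are flagged low-n (the threshold
is this package's choice; small counts make the weighted mean
noise-dominated). The estimate is always bounded by the optima of the
species present, and is invariant to count rescaling and to excluded
species at any abundance.

## WA-PLS

Percentages are recomputed over the included taxa, optionally square-root
transformed (default on). Component extraction follows the standard
two-way weighted-averaging update: species scores are weighted averages of
the current climate residuals, sample scores are weighted averages of
species scores, each new axis is orthogonalized (abundance-weighted)
against earlier axes and standardized, and the climate is regressed on the
axes with row-sum weights — which makes component 1 identical to classical
WA with inverse deshrinking (asserted to 10⁻⁸ against an independently
coded oracle). Because every step is affine in a sample's taxon
proportions, the fitted model collapses to one coefficient vector and
intercept per component count, which is what prediction uses; a fossil
sample identical to a training sample reproduces its fitted value exactly.
A constant climate vector is fittable with one component (predicting the
constant) and raises for more. Taxa are matched by name; unmatched fossil
taxa are dropped with a warning, and all-zero rows propagate as missing.

Validation: leave-one-out refits give per-component r², RMSEP and maximum
bias (largest |mean residual| over 10 equal-width climate intervals).
Component count is chosen by a paired sign-flip randomization test on the
per-sample squared LOO errors: component c+1 is accepted only if it lowers
RMSEP with p < 0.05 (p = (r+1)/(n+1)), walking up from 1 and stopping at
the first rejection. Sample-specific errors come from bootstrap
resampling of the training set (default 1000 cycles): `SE = √(s1² + s2²)`
with s1 the across-bootstrap spread of the fossil prediction and s2 the
root-mean-square out-of-bag training error.

## Modern analogue technique

Chord distance — Euclidean distance between square-rooted proportion
vectors, with the squared-chord variant as an option — is computed between
each fossil spectrum and every training spectrum on the shared taxon set.
The k = 6 nearest are the analogues; those above the dissimilarity
threshold are rejected afterwards (so fewer than k may remain, and the
retained count is reported); the estimate is the inverse-distance-weighted
mean of their climate values, with a zero-distance analogue returning its
climate exactly. The threshold is the stated quantile of chord distances
among randomly drawn training pairs (Monte-Carlo, seeded; quantile and
pair count are explicit parameters with no claimed canonical default).

## Reconstruction significance

The statistic is the proportion of variance in the (square-root
transformed, column-centered) fossil matrix explained by regressing each
taxon on the reconstructed values; the null distribution comes from
reconstructions by models trained on permutations of the climate vector,
`p = (#null ≥ real + 1)/(n+1)` with 999 randomizations by default. On the
synthetic benchmark this test is conservative: the fossil data generated
from a single gradient are nearly rank-one, so even a null model's
prediction — an arbitrary linear functional of composition — correlates
with the dominant gradient, and a genuinely driven sequence yields p of
order 0.01–0.05 rather than the floor 1/(n+1). Real multi-gradient
training sets discriminate more sharply.

## Biomization

Affinity of a sample for biome b is `A_b = Σ_{PFT ∈ b} Σ_{taxon ∈ PFT}
√(percent)`, counting only taxa strictly above the percentage threshold
(default 0.5 %); a taxon contributes to every PFT it belongs to. The
sample takes the maximal-affinity biome; ties go to the biome defined by
the fewest PFTs (the more specific biome), then input order. If the winner
is temperate forest and the arboreal pollen sum — computed from per-taxon
arboreal flags in the PFT matrix over the same percentage basis — is below
the cutoff (default 70 %), wooded steppe is assigned with an override
flag; the override applies to temperate forest only. The taxon→PFT→biome
matrices are data, not code: the package ships only toy fixtures, and
published matrices are user-supplied CSVs.

## Diversity

Richness is Hurlbert rarefaction, `E(T) = Σ[1 − C(N−Nᵢ, n)/C(N, n)]`,
computed with log-gamma arithmetic; it needs integer counts and a base
count `n ≤ N`. Downcore runs default the base to the minimum sample total,
making values comparable along the core. Evenness defaults to Pielou
`H′/ln S` (undefined for one taxon) with the Hill ratio N2/N1 as an
option; the index used is recorded in the output metadata, since different
choices are common in the literature.

## Synthetic data

Generators draw from streams derived from (master seed, generator name),
so adding a generator never perturbs existing fixtures. They emulate: a
monotone calibration curve with smooth wiggles (plus an optional local
inversion for multimodality tests); sighting series with uniform recovery
over the occupied window and Gaussian dating error (so observed ages can
cross the true extinction time); unimodal Gaussian species-temperature
responses with a common tolerance and multinomial counting noise; and
downcore sequences driven by a known temperature trajectory under the same
response model. They deliberately do *not* emulate taphonomic loss or
age-dependent recovery bias, secondary gradients or taxon-specific
tolerances, curve error correlation, or deposition-rate structure within
the phase — so passing tests demonstrate correctness of the estimators
under their own model assumptions, not robustness to violations of them.

Default problem sizes (benchmark: 40 taxa, 150 modern samples of 300
grains, tolerance 2 °C over a 5–25 °C gradient, 30-sample cores; 200
replicates for coverage runs at reduced MCMC lengths) were chosen so the
full suite runs in about a minute on one CPU while keeping Monte-Carlo
error well inside the asserted tolerances.

## Known limitations

- The GRIWM resampling CI under-covers by construction (see above); treat
  it as a precision summary, not a confidence guarantee.
- The phase sampler is exact only for the marginalised two-boundary model;
  it does not return posteriors of individual true ages.
- Calibrated-density resampling in GRIWM treats records as independent;
  shared curve wiggles induce correlation that is ignored.
- WA-PLS assumes a single dominant gradient; deshrinking is inverse by
  default (classical not implemented) and taxon matching is by exact name
  plus a user synonym table.
- The reconstruction significance test is conservative on near-rank-one
  fossil data (see above).
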