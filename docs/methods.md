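# Methods

## Demographic models

All seven candidate histories share the rooted topology
((pop2, pop3), pop1): the sister pair merges (backward in time) at `T1`
and joins population 1 at `T2`. Every population has the same constant
effective size; times are expressed in units of 4·Ne generations and
per-locus diversity as θ = 4·Ne·μ·L (the ms convention), so nothing in
the inference depends on absolute Ne, μ or generation time — only their
products. Loci are non-recombining internally, unlinked between, and
mutate under an infinite-sites biallelic model.

Admixture is one episode between one ordered pair of populations.
Recent models (A, B, D, E) place it after the sister split; ancient
models (C, F) between the splits, where one participant is the sister
pair's common ancestor. In the continuous variant gene flow runs over
the window [Tgf, Tgf + Tdur] (backward in time) at scaled rate 4Nm; in
the pulse variant a proportion F of the destination's lineages is
replaced instantaneously at Tgf. The forward-in-time direction
conventions are fixed and documented in `triadmix.models`; because the
model pairs (A,B), (D,E), (C,F) are label-symmetric, any fixed
assignment yields the same candidate set.

The msprime adapter simulates haploid lineages in populations of size
1/2, making the pairwise coalescence rate 2 per time unit — exactly the
ms time scale — so plan times, 4Nm and θ transfer without conversion.
Population splits are encoded as 100% mass migrations, keeping three
fixed population indices throughout.

## Priors

Two presets are built in; custom priors load from YAML with per-
parameter distributions and pairwise order constraints.

*Simulation preset* (continuous admixture; per-locus θ for 500 bp):
θ ~ U(0.007, 0.35), whose endpoints are 4·Ne·μ·L at Ne = 2000 and
100 000 with μ = 1.75e-9; T2 ~ U(1, 4); for recent models
Tgf ~ U(0.1, 0.5), T1 ~ U(0.4, 1) truncated to T1 > Tgf, and
Tdur ~ U(0.01, 0.1) truncated so the window ends before T1; for ancient
models T1 ~ U(0.4, 1), Tgf | (T1, T2) ~ U(T1, T2) and the window ends
before T2. The gene-flow magnitude prior "E(0.1)" is implemented as
exponential with rate 0.1 (mean 4Nm = 10): under the mean-0.1 reading
the expected number of migrant lineages over the short admixture window
is of order 10⁻³, every admixture model collapses statistically onto
isolation, and no model choice is possible — so only the rate reading
produces a meaningfully distinguishable candidate set. The
parameterization is an explicit field (`exp_parameterization`) and can
be flipped for sensitivity analyses.

*Empirical preset* (pulse admixture; θ for 1 kb loci):
θ ~ U(0.01, 1.4), F ~ U(0, 1), times on (0.1, 4) with Tgf < T1 < T2
(recent) or T1 < Tgf < T2 (ancient) imposed as sequential conditional
uniforms.

Conditional parameters are drawn by exact truncated-uniform sampling in
declaration order, which preserves the printed marginals of the
unconditioned parameters. The recent-model window constraint
Tgf + Tdur ≤ T1 is enforced by a truncated redraw of Tdur; in the rare
case where the window is narrower than Tdur's lower bound the whole
vector is redrawn.

## Summary statistics

Per locus, for each population pair, sites segregating within the
pair's combined sample are classified into fixed differences, shared
polymorphisms, and private polymorphisms; the two private classes are
pooled so each pair contributes three proportions. Together with the
per-population and total segregating-site counts this gives 13
per-locus statistics. The classification uses only per-population
allele counts, which yields two structural invariances checked by
property tests: permuting haplotypes within a diploid individual
(phase) and relabeling alleles 0↔1 at any site (polarity) never change
any statistic.

Across loci each statistic is compressed to its sample mean, unbiased
variance, skewness (g1) and kurtosis (fourth standardized moment,
m4/m2²) — 52 summaries. Raw central moments are available behind
`standardized_moments=False`. Conventions for degenerate cases: a pair
with no informative sites at a locus contributes zero proportions (not
missing values), and a statistic constant across loci reports zero
skewness and kurtosis, keeping every vector finite and the moment
computation total. When one population is a single haploid sequence its
own segregating-site count and its pairs' shared-polymorphism
proportions are identically zero, so the reduced configuration drops
them (10 per-locus statistics, 40 summaries); a means-only
configuration (13) supports dimension-reduction experiments.
Empirical alignments contribute only biallelic, ungapped, N-free sites;
filtering is per site, not per locus, and filtered counts are logged.

## ABC machinery

Statistics are standardized by their median absolute deviation
(normal-consistent) over the reference table; columns with zero MAD are
dropped from the distance with a warning — in small tables the higher
moments of rare site categories are legitimately degenerate. Rejection
keeps the `round(tolerance·N)` smallest Euclidean distances with
deterministic index tie-breaking, and weights retained rows with the
Epanechnikov kernel 1 − (d/d_max)².

Model choice: simple rejection (share of retained rows) or multinomial
logistic regression of the label on the standardized statistics over
the retained rows, kernel-weighted, with a small ridge penalty
(λ = 1e-6) because the 52 moment statistics are strongly collinear;
probabilities are evaluated at the observed vector, floored at 1e-8 and
renormalized. The minimum pairwise Bayes factor — P(focal)/P(best
competitor) — uses 10 as the conventional strong-support threshold and
is capped at 1e6 when the competitor mass vanishes.

Parameter estimation transforms each parameter to an unbounded scale
(logit over the prior's global support for bounded priors, log for
positive ones), guaranteeing that adjusted draws back-transform into
the support. The conditional mean m(s) and the log squared residuals
are each fit by an ensemble of 10 single-hidden-layer (5 units)
feed-forward networks on kernel-weighted bootstrap resamples of the
retained set; the heteroscedastic adjustment
θ* = m(s_obs) + [θ − m(s)]·σ(s_obs)/σ(s) (ratio clipped to [1e-3, 1e3])
is applied before back-transformation. Two numerical choices matter and
were made deliberately:

- regression targets are z-scored before fitting so the weight-decay
  penalty acts on a fixed scale;
- the decay strength is selected per fit by held-out validation error
  (25% split) over the grid {1e-4, 1e-3, 1e-2, 1, 100} rather than
  drawn at random from a small fixed grid. The extended grid is the
  safeguard against over-adjustment: when the statistics carry no
  information about a parameter, in-sample residuals of a flexible
  regression understate the posterior spread (we measured ~30%
  shrinkage below the prior), while validation selection then prefers
  the near-constant model and leaves the accepted sample — i.e. the
  prior — essentially untouched. The no-information property
  (posterior ≈ prior under pure-noise statistics) and the identity-map
  property (posterior median within 2% when a statistic equals the
  parameter) are both enforced by tests.

Point estimates are weighted posterior medians; intervals are weighted
95% highest-density intervals (shortest contiguous interval holding the
mass; a point mass yields zero width). Everything downstream of a seed
is reproducible bit-for-bit, including per-row simulation seeds derived
from (master seed, model index, row index) so reference tables do not
depend on execution order.

## Validation design (PODS)

Leave-one-out model-selection cross-validation removes one table row,
treats it as observed, and classifies it with the multinomial-logistic
posterior; per true model we report the mean posterior probability, the
full confusion matrix, and the count of replicates whose minimum
pairwise Bayes factor exceeds 10. Parameter-estimation validation draws
fresh pseudo-observed data sets (PODS) from the priors and reports,
per parameter: prediction error ε = Σ(θ̂−θ)²/(n·Var_prior), normalized
so an estimator stuck at the prior mean has expectation 1 (prior
variances come from a seeded 10⁵-draw Monte Carlo, since conditional
priors make closed forms awkward); 95% HPD coverage; and mean interval
width against the prior range.

The default experiment scale is deliberately reduced relative to a
production analysis: reference tables of a few thousand rows, 200 loci
of 500 bp, one diploid individual per population, 100 PODS. At this
scale the regression step retains 1000 data sets — the absolute
retained count, not the retained fraction, is what governs the
regression adjustment's behaviour, so scaled-down experiments hold it
fixed while the table shrinks. The structural findings these
experiments reproduce are directional: models whose migrants leave the
diverged population (D, E) are identified most reliably; the ancient
pair (C, F), differing only in admixture direction, is hardest, and
their misclassified mass flows mostly into each other; information
grows with locus count; HPD coverage stays above 80% for every
parameter while interval widths shrink well below the prior range for
identifiable parameters.

## What the generator does and does not emulate

The synthetic data are exactly the model class: unlinked,
non-recombining, infinite-sites loci from three constant-size
populations with at most one admixture episode and uniform rates across
loci. Passing tests therefore demonstrate the correctness and
calibration of the inference machinery under its own assumptions — not
robustness to intralocus recombination, rate heterogeneity, selection,
population-size change, sequencing error, or model misspecification,
none of which the generator produces. Empirical applications should
treat locus length as a recombination trade-off and check adequacy with
the PCA prior/posterior-predictive utilities before trusting posterior
quantities.

## Known limitations

- Exactly three populations and one admixture episode; no time-varying
  sizes or per-locus rate variation.
- The multinomial-logistic step needs at least two models among the
  retained rows; strongly separated tables at tight tolerances should
  use rejection-based model choice instead.
- The regression adjustment requires a floor of retained rows (default
  50) and remains an approximation; with very few accepted simulations
  prefer wider tolerances.
- MAD standardization drops statistics that are constant in the table;
  with very small tables this can discard weakly informative columns.
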