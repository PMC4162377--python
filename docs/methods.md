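# Methods

`irtalign` estimates group-specific factor means and variances for many
groups of binary-item respondents without assuming exact measurement
invariance, localizes the item parameters that remain non-invariant,
and provides a Monte Carlo harness for judging whether the resulting
group comparison can be trusted.

## Model

Each binary item *p* in group *g* follows a two-parameter response
model.  On the factor metric the response is a dichotomized latent
response variable *y\** = λ_pg·η + ε crossing a threshold τ_pg, with
η ~ N(α_g, ψ_g) and the residual standardized by the link: standard
logistic (variance π²/3) for logit, standard normal for probit.  Both
links give

    P(y = 1 | η) = F(λ_pg·η − τ_pg),

and the IRT metric is the reparameterization a = λ, b = τ/λ.  A zero
loading is representable (optimizers may pass through it) but has no
defined difficulty; the conversion raises.

Estimation is marginal maximum likelihood: the ability is integrated
out by fixed Gauss–Hermite quadrature (21 nodes by default; doubling
the nodes moves fitted log-likelihoods by well under 1e−5 relative on
the standard fixtures, which is why adaptive quadrature is not
implemented even though the quadrature spec carries the flag).
Response patterns are collapsed to unique rows with multiplicities, and
the analytic score is used throughout, so single-group fits take
milliseconds at the problem sizes of interest.  Missing responses
contribute nothing to their item's likelihood term (full-information ML
under missing-at-random; no imputation).  Loadings and thresholds are
box-bounded at ±25 to keep quasi-separated items finite; constant item
columns trigger a warning, not an error.

Three multi-group levels are fitted:

- **configural** — all item parameters free per group, every group's
  factor distribution fixed at N(0, 1); groups are independent and are
  fitted separately;
- **metric** — loadings equal across groups, thresholds free, factor
  variances free in groups 2..G (reference variance 1), means fixed 0;
- **scalar** — loadings and thresholds equal across groups, factor
  means/variances free in groups 2..G (reference fixed at 0/1).

Under these identifications the free-parameter *differences* are
(G−1)(P−1) for metric-vs-configural and 2(G−1)(P−1) for
scalar-vs-configural, which are the degrees of freedom of the
likelihood-ratio tests.  Absolute parameter counts depend on
identification conventions and are not meaningful across software;
only the differences are.

Standard errors for fitted models come from the observed information
(central finite differences of the analytic score, symmetrized and
inverted), with an optional sandwich variant built from per-observation
score outer products.

## Alignment

The configural model absorbs true group differences in the latent mean
and variance into the item parameters.  For any candidate (α_g, ψ_g)
the transformed parameters

    λ_pg,1 = λ_pg,0 / √ψ_g,        τ_pg,1 = τ_pg,0 + α_g·λ_pg,0 / √ψ_g

combined with η ~ N(α_g, ψ_g) reproduce the configural likelihood
*exactly* (with intercepts ν = −τ this is the familiar
ν_1 = ν_0 − α·λ_0/√ψ).  The tests verify this identity to machine
precision; it is the method's foundation.  Alignment chooses the group
distributions minimizing the total non-invariance

    F = Σ_p Σ_{g1<g2} w_{g1,g2} [ f(λ_1 diff) + f(τ_1 diff) ],

with component loss function f(x) = (x² + ε)^(1/4), ε = 1e−4 — a smooth
surrogate of √|x|, concave in |x| so the optimum prefers a few large
non-invariant parameters over many medium ones.  The square-root form
(x² + ε)^(1/2) is selectable but loses that preference.  Pair weights
default to w = √(N_g1·N_g2) (larger groups carry more information);
unit weights are selectable.

**Identification.** The loss is minimized over (α_g, log ψ_g) with the
reference mean pinned at 0 and the variances constrained to
Π_g ψ_g = 1.  Pinning a single reference *variance* instead would leave
a degenerate descent direction: inflating every other group's variance
shrinks all pairwise aligned-loading differences simultaneously, and
the concave loss rewards the collapse (we observed exactly this —
variances running to bounds with a loss below the truthful solution —
before adopting the product constraint).  The conventional
fixed-reference report (α_ref = 0, ψ_ref = 1) is produced afterwards by
an exact affine re-anchoring of the latent scale; on perfectly
invariant inputs this recovers the generating distributions to
optimizer precision.  `identification="product"` skips the
re-anchoring.

**Optimization.** Multistart (30 starts by default) L-BFGS-B with the
analytic gradient; starts perturb the configural anchor by
N(0, 0.5) on means and N(0, 0.3) on log variances, all driven by one
seed, so equal seeds give bit-identical results.  The tiny ε makes the
surface stiff near zero differences, so each start first optimizes at
ε = 0.01 and then re-optimizes at the target ε from the warm point.
Bounds of ±10 on means and ±5 on log variances keep line searches
finite.  Ties between equal-loss starts go to the lowest start index.

Loss decompositions report each item's own terms, loadings and
thresholds separately; each pair term is split half-and-half between
its two groups so that the item column and the group column each sum
to the total loss.

## Post-alignment inference

**Standard errors.**  The default is a parametric bootstrap: the
aligned solution is promoted to a generating population, data sets of
the original group sizes are redrawn (200 by default), each is refitted
and realigned (two starts, warm region), and the empirical covariance
of all aligned outputs is used.  A delta-method variant — central
differences of the configural-to-aligned mapping, warm-started
re-optimization per perturbed coordinate, sandwiched around the
block-diagonal configural covariance — is provided for speed, but it
is *not* calibrated: the argmin of a concave loss behaves like a
weighted median, anchored on whichever cells are currently best
aligned, so its local derivative concentrates on a few inputs and
overstates the sampling variability two- to four-fold on our fixtures
(verified against the true sampling spread over fresh replications).
Use it for rough scale only.  Reference-pinned quantities have SE
exactly 0 under either method.

**Invariance flags.**  For each item and each parameter family
(threshold, loading): all pairwise z-tests of aligned differences; the
largest set of mutually non-significant groups (a maximum clique of
the compatibility graph — a merely *connected* set would let one
imprecise group bridge two incompatible ones, which we observed
flagging the wrong group) starts the invariant set, ties broken by
total sample size then lexicographic labels; then groups are moved out
of (p < α against the set's precision-weighted mean, computed
excluding the tested group, with covariances) or back into the set
until stable.  The set is never shrunk below two groups.  Default
α = 0.01 per test, no multiplicity correction; both configurable.  The
procedure is a documented design choice — the literature reports this
style of output without specifying the algorithm.

**Rates and verdict.**  Non-invariance rates are exact fractions of
flagged (item, group) cells per family; their simple average is
compared with the 25% rule of thumb: at or below it the alignment is
reported "trustworthy", above it the verdict is "run Monte Carlo".

**Ranking.**  Groups are sorted by estimated factor mean (ties by
label); for each group, the groups with significantly smaller means by
a one-sided z-test (default α = 0.05, covariance between means used,
optional Bonferroni over the G(G−1)/2 pairs) are listed.  One-sidedness
makes the lists automatically consistent with the ordering.

## Synthetic data generator

`make_population` builds the study populations: an invariant item bank
(loadings uniform on [0.8, 2.0], difficulties uniform on [−1.5, 1.5],
the realistic range for binary knowledge items) replicated across G
groups, with round(pct/100·G·P) threshold cells and loading cells
perturbed by uniform ±[0.3, 1.0] shifts — detectable but realistic
differential item functioning; every perturbation is recorded in a
ledger.  Group factor means default to an even spread over [0, 2]
(first group at 0, the anchoring convention) with unit variances.
`generate_responses` draws η ~ N(α_g, ψ_g) per respondent and Bernoulli
responses through the threshold model.  A fitted alignment can be
promoted to a generating population, mirroring a real-data analysis.

What the generator does *not* emulate: complex survey structure
(stratification, weights, clustering), planned-missingness booklet
designs, polytomous items, multidimensional abilities, and local item
dependence.  Passing tests therefore demonstrate correctness of the
method under clean conditional-independence sampling, not robustness
to those features of operational survey data.

## Monte Carlo quality harness

`run_monte_carlo` regenerates data from a population, refits the
configural model and realigns per replication, and reports per-group
bias and RMSE for all parameters plus the headline statistic: the
Pearson correlation between generating and estimated factor means,
computed over groups and averaged over replications.  A mean
correlation of at least 0.98 is the bar for a trustworthy group
ordering.  Failed replications are dropped with a count; more than 20%
failures is an error.  95% coverage of the group means is computed only
on request (`compute_ses=True`), because it needs a bootstrap per
replication.  All randomness in a study flows from a single seed
through spawned seed sequences.

Standard study sizes used by the test suite and the acceptance script:
the 28-group, 17-item, n = 500-per-group design with 33% threshold and
11% loading non-invariance at 5 replications (minutes on one CPU);
property checks run at G = 3–10, P = 4–15, n = 250–2000 with
replication counts of 8–500 chosen per check so the whole suite stays
in the minutes range.

## Known limitations

- Factor-variance estimates are markedly noisier than mean estimates;
  at n = 2000 per group roughly four fifths of replications put every
  ψ̂_g within 0.15 of truth, not nearly all of them.  Means are better
  behaved, and the mean *ranking* (the quantity the method is for) is
  robust: the 0.98 correlation bar is cleared even at 22% average
  injected non-invariance.
- The delta-method SEs are a scale heuristic, not calibrated (above).
- Anchoring is not affine-equivariant on noisy data: re-running with a
  different reference group agrees only to sampling scale (~0.1 on the
  small fixtures), exactly on invariant inputs.
- Single factor only; no cross-loadings, no 3PL guessing parameter, no
  polytomous items, no survey weighting, no Bayesian/approximate-
  invariance variants.
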