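# Methods

## Models

All families reduce to binomial sampling of test-positives.

**Apparent prevalence.** `y ~ Binomial(n, π_a)`, `π_a ~ Beta(α, β)`.
The posterior is conjugate, `Beta(α+y, β+n−y)`; the MCMC path exists
for this family only so the sampler can be validated against the
closed form.

**True prevalence, single population.** The success probability is the
Rogan–Gladen map `π_a = π_t·Se + (1−π_t)(1−Sp)`; π<sub>t</sub>, Se and
Sp carry Beta priors, or point masses when the test's accuracy is
treated as known. The model is only weakly identified from one survey:
the data constrain the one-dimensional apparent rate, so posterior
learning about Se and Sp comes almost entirely from their priors, and
informative accuracy priors are essential. When the joint prior puts
more than 1% mass on `Se + Sp ≤ 1` (where the map inverts and the
mirror solution `(1−π_t, 1−Se, 1−Sp)` fits equally well) the model
constructor emits an identifiability warning rather than imposing a
hard constraint.

**Multiple populations.** Counts `y_i | π_ti, Se, Sp` are binomial per
cluster with shared Se/Sp; cluster prevalences are exchangeable,
`π_ti | μ, ψ ~ Beta(μψ, ψ(1−μ))`, so `E[π_ti] = μ` and
`Var[π_ti] = μ(1−μ)/(ψ+1)` — ψ is inverse heterogeneity. Hyper-priors:
`μ ~ Beta(α_μ, β_μ)`, `ψ ~ Gamma(α_ψ, β_ψ)` (shape/rate). The
hierarchical model is trustworthy mainly with many clusters
(practically, more than eight).

**Zero inflation.** A population is infected with probability w and
disease-free (π = 0) otherwise; `w ~ Beta`. A disease-free population
still yields false positives, so its likelihood is
`Binomial(y; n, 1−Sp)` in the true-prevalence families (and a point
mass at y = 0 for the apparent family, which has no false-positive
mechanism). The mixture is marginalized analytically — the sampler
never carries the discrete indicator — which mixes better and leaves
the marginal posterior unchanged. The mixture prevalence
`π* = z·π_t` is reconstructed after sampling by drawing the indicator
from its exact conditional `P(z=1 | draw) = wL₁/(wL₁+(1−w)L₀)` with a
seed-derived generator, so π* draws (and their atom at zero) are
reproducible. With multiple populations the mixture applies
independently per cluster, with one shared w by default or
exchangeable per-cluster `w_i ~ Beta` (`w_mode="cluster"`) when
region-wide freedom is itself in question.

Freedom-from-disease reporting for hierarchical fits returns:
per-cluster posterior summaries; the fitted prevalence-distribution
shape pair `(μψ, ψ(1−μ))` per draw; the μ summary; the posterior
probability that *every sampled* cluster is below a threshold c (and,
when zero-inflated, that all clusters are free); and the
posterior-predictive probability that a *new* cluster falls below c,
computed from one `Beta(μψ, ψ(1−μ))` draw per retained posterior draw
(multiplied by a Bernoulli(w) indicator when zero-inflated).

## Prior elicitation

Beta priors are elicited from a central-tendency statement plus one
tail statement `P(X > v) = p` (or `< v`). With the concentration
`t = α+β`, the family is parameterized so the central constraint holds
identically — `α = m·t` (mean), `α = 1 + m(t−2)` (mode, requiring
t > 2), or `α` from a nested median solve — and the tail probability
is then monotone in t, so a bracketed scalar root-solve on
`log t ∈ [log 1e−6, log 1e8]` (bisection-safe `brentq`, transformed
tolerance 1e−10) finds the unique solution; both constraints are
verified to 1e−6 before returning. Inconsistent statements (no sign
change over the bracket) raise an error, as does the fully symmetric
statement mean = bound = probability = 1/2, which every symmetric Beta
satisfies — it is rejected as under-determined rather than resolved by
a hidden tie-break. Hyperparameters print rounded to two decimals but
are stored at full precision.

Gamma priors (for ψ) are elicited from a stated median and 95th
percentile: the ratio q95/q50 depends only on the shape and is
monotone in it, giving the same solve-then-rescale structure.

## Sampling

Adaptive random-walk Metropolis-within-Gibbs on transformed scales:
logit for every probability, log for ψ (priors include the Jacobians).
Update blocks: the cluster-prevalence vector (componentwise
accept/reject, valid because the conditional posterior factorizes
across clusters given Se, Sp, μ, ψ), then Se, Sp, μ, ψ, w as scalar
blocks. All chains advance in lock-step as vectorized arrays.
Per-parameter proposal scales adapt every 50 iterations toward a 0.44
acceptance rate **during burn-in only** and are frozen afterwards, so
the retained draws satisfy detailed balance. Defaults: 4 chains ×
30 000 iterations, 10 000 burn-in, thinning 5, seed 1 — enough that
repeating the single-population examples under a different seed moves
posterior means by well under 0.005.

Initialization draws hyperparameters and accuracies from their priors
(overdispersed starts), but prevalences from jittered apparent-scale
draws `Beta(y+½, n−y+½)`. Prevalence starts from the prior can land
near a boundary whose only escape route crosses the label-switched
mirror mode — a barrier a random-walk sampler essentially never
crosses, leaving a chain stuck in a region of negligible posterior
mass. Data-informed starts keep all chains in the identified basin
while remaining overdispersed through the accuracy and hyperparameter
draws.

Posterior quantiles use the median-unbiased (type-8) empirical
quantile convention throughout. Because zero-inflated posteriors are
bimodal by construction (an atom at zero beside the infected
component), reports always carry full density tables alongside
moments; densities use a Gaussian kernel with Silverman's rule-of-
thumb bandwidth on a 512-point grid, full-chain and half-chain per
chain, so the plots are exactly reproducible from exported draws.

## Diagnostics

Effective sample size: per chain, the autocorrelation time is
`τ = 2·Σ_m max-pair` under Geyer's initial-positive-sequence rule
(sum of autocorrelation pairs until the first non-positive pair;
FFT-based autocovariances), floored at 1; chain ESS values are summed.
Shrink factor: potential scale reduction with each chain split in
half, `sqrt(((n−1)/n·W + B/n)/W)` over the 2C half-sequences —
splitting also exposes within-chain drift (a full- versus partial-
chain comparison). Autocorrelation series are per-chain estimates
averaged across chains, with lag 0 ≡ 1; a numerically constant chain
is flagged degenerate and reports zeros at positive lags instead of
NaNs. Running means are cumulative per chain. All diagnostics are
pure functions of the retained draws.

## Bundled examples and chosen run lengths

The nine-study dementia table ships with the package. Its row for
Fish et al. is stored as 88/1665: that sample size is the unique value
consistent with the study's published apparent prevalence (0.053), its
Wald interval (0.042, 0.064) and the review's participant total of
18 263, whereas a duplicated 1754 fails all three.

The hierarchical dementia example elicits μ from "mean 0.20, 99%
certain below 0.3" (→ `Beta(20.27, 81.07)`), Se from "mean 0.88,
P(>0.80)=0.90", Sp from "mean 0.95, P(>0.85)=0.97", and uses a weakly
informative `Gamma(1, 0.1)` on ψ. At the elicited μ mean and the
posterior-typical ψ ≈ 0.69 the implied group-prevalence distribution
is `Beta(0.14, 0.55)` — a heavily right-skewed, low-information shape
appropriate for prevalences spanning 4%–36% across studies. This fit
uses 4 × 150 000 iterations (30 000 burn-in, thinning 5): the
specificity and heterogeneity blocks are the slowest-mixing
coordinates of this posterior (ESS a few hundred at the default
length), and the longer run pins the posterior mean of μ to within
±0.0001 across seeds. Single-population examples use the defaults.

## Synthetic data

`simulate_single` and `simulate_multi` draw from exactly the models
above (freedom indicator → cluster prevalence → binomial count), with
the realized truth returned for scoring. Recovery tests use k = 20
clusters of 500 at μ = 0.2, ψ = 10, Se = 0.90, Sp = 0.95 with
informative accuracy priors — comfortably above the more-than-eight-
clusters robustness floor. The generator reproduces the models'
assumptions and only those: clusters are sampled independently with
known-form priors, tests err independently of covariates, and there
is no missing data, no within-cluster correlation beyond the shared
prevalence, and no covariate structure. Passing recovery tests
therefore demonstrates internal consistency of estimator and
generator, not robustness to real-data violations of exchangeability.

## Limitations

One test per subject; no covariate-dependent prevalence; no test
dependence structures; no missing-outcome handling. The sampler is
random-walk based: posteriors with severe funnels (very small ψ with
many clusters) mix slowly and should be given longer runs, guided by
the reported ESS and shrink factors. Wald intervals for apparent
prevalence are the familiar normal approximation and inherit its
poor coverage at very small counts; they are provided for
comparability with standard reporting, with `y = 0` returning the
degenerate (0, 0, 0).
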