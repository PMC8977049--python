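# trueprev

Bayesian estimation of apparent and **true** disease prevalence from
imperfect diagnostic-test surveys, with percentile-based prior
elicitation.

## The problem

A survey observes `y` positive tests out of `n` sampled subjects. The
observed rate `y/n` estimates the *apparent* prevalence π<sub>a</sub> —
the probability of a positive *test* — not the probability of disease.
With test sensitivity Se and specificity Sp the two are linked by the
Rogan–Gladen relation

    π_a = π_t·Se + (1 − π_t)·(1 − Sp)

and ignoring it biases prevalence estimates whenever the test errs.
`trueprev` fits the Bayesian models built on this relation:

* **Apparent prevalence** — `y ~ Binomial(n, π_a)` with a conjugate
  `Beta(α, β)` prior (closed-form posterior `Beta(α+y, β+n−y)`).
* **True prevalence, one population** —
  `y ~ Binomial(n, π_t·Se + (1−π_t)(1−Sp))` with Beta priors (or known
  point values) on π<sub>t</sub>, Se and Sp.
* **True prevalence, multiple populations** — counts `y_i` per cluster
  (herd, study site, region) with exchangeable cluster prevalences
  `π_ti | μ, ψ ~ Beta(μψ, ψ(1−μ))`: μ is the mean group prevalence and
  ψ the concentration (large ψ = little between-cluster
  heterogeneity); Se and Sp are shared across clusters. Hyper-priors:
  `μ ~ Beta`, `ψ ~ Gamma`.
* **Zero-inflated variants** — any of the above where a population is
  disease-free (π = 0) with probability 1 − w, so surveys of possibly
  disease-free regions are not forced to a positive prevalence.
  Reports include freedom-from-disease probabilities at a chosen
  threshold.

Priors are *elicited* rather than hand-specified: a statement such as
"the mean sensitivity is 0.80, and with probability 0.97 it exceeds
0.75" is converted into `Beta(195.76, 48.94)` by a deterministic
root-solve on the Beta concentration (mean, median and mode statements
are supported; Gamma priors are elicited from a median and a 95th
percentile). Models are fitted with an adaptive random-walk
Metropolis-within-Gibbs sampler on transformed scales; runs are
bit-reproducible given a seed, and every fit carries effective sample
size, split-chain shrink factor, autocorrelation, running-mean and
density diagnostics.

Intended users: epidemiologists and veterinary/public-health
statisticians who need defensible true-prevalence estimates (and
"probability the region is free of disease" statements) from one or
many imperfect-test surveys.

## Worked example

A survey finds 120 positives among 500 subjects (24% apparent
prevalence). The test's sensitivity is believed to average 0.80
(97% sure above 0.75) and its specificity 0.90 (97% sure above 0.85):

```python
from trueprev import *

se_prior = elicit_beta(ElicitationStatement("mean", 0.80, 0.75, 0.97))
sp_prior = elicit_beta(ElicitationStatement("mean", 0.90, 0.85, 0.97))
print("se prior:", se_prior)   # se prior: BetaPrior(alpha=195.76, beta=48.94)
print("sp prior:", sp_prior)   # sp prior: BetaPrior(alpha=135.86, beta=15.10)

est = TruePrevalence(se_prior=se_prior, sp_prior=sp_prior, seed=1)
est.fit(load_fixture("toy_24pct"))
print(est.summary_.round(4))
print("P(pi_t > 0.15) =", est.prob_exceeds("pi_t", 0.15))
```

```
             mean  median    q_lo    q_hi
parameter
pi_t       0.1998  0.2016  0.1151  0.2753
se         0.7992  0.8000  0.7467  0.8467
sp         0.8991  0.9009  0.8463  0.9414
P(pi_t > 0.15) = 0.892
```

The posterior mean true prevalence is 20.0% — *below* the apparent
24%, because part of the positives are false positives — with 95%
credible interval (0.115, 0.275). The test's accuracy parameters are
barely updated from their priors: a single survey cannot learn them.

The same models run from the shell:

```
trueprev elicit --quantity se --central 0.8 --bound 0.75 --prob 0.97
trueprev fit --model true --populations multi --fixture dementia_9 \
    --prevalence-prior 20.27,81.07 --se-prior 25.88,3.53 --sp-prior 25.63,1.35 \
    --out runs/dementia
trueprev report --run runs/dementia
```

`fit` exports `input.csv`, `model.json` and `draws.csv`; `report`
regenerates every summary and diagnostic from those files alone.

Bundled data: `dementia_9` (nine European dementia prevalence studies,
18263 participants, 2137 DSM-IV diagnoses) and the toy surveys
`toy_24pct`/`toy_5pct`. Synthetic surveys with known ground truth come
from `simulate_single` / `simulate_multi`.

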