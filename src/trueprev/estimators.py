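"""Scikit-learn style estimators for prevalence models.

Each estimator takes its priors and MCMC settings as constructor
parameters (so ``get_params``/``set_params``, cloning and grid search
work as usual), validates inputs in ``fit``, and exposes the results
as trailing-underscore attributes: ``samples_`` (posterior draws),
``summary_`` (pooled posterior summary table) and ``spec_`` (the fitted
model specification).  ``predict`` returns the posterior mean of the
headline prevalence parameter, which makes the estimators usable as
the final step of an sklearn pipeline.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import ClusterTable, SurveyCounts
from .inference import (
    MCMCConfig,
    freedom_summaries,
    prob_exceeds,
    run_mcmc,
    summarize,
)
from .models import ModelSpec, apparent_posterior
from .priors import BetaPrior, GammaPrior, PointMass

__all__ = ["ApparentPrevalence", "TruePrevalence", "HierarchicalTruePrevalence"]


def _as_counts(X) -> SurveyCounts:
    if isinstance(X, SurveyCounts):
        return X
    if isinstance(X, (tuple, list)) and len(X) == 2:
        return SurveyCounts(y=int(X[0]), n=int(X[1]))
    arr = np.asarray(X)
    if arr.shape in ((2,), (1, 2)):
        y, n = arr.reshape(2)
        return SurveyCounts(y=int(y), n=int(n))
    raise TypeError("expected SurveyCounts or a (y, n) pair")


def _as_table(X) -> ClusterTable:
    if isinstance(X, ClusterTable):
        return X
    try:
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            return ClusterTable.from_frame(X)
    except ImportError:  # pragma: no cover
        pass
    raise TypeError("expected a ClusterTable or a DataFrame with 'positive' and 'n'")


class _MCMCEstimator(BaseEstimator):
    def _config(self) -> MCMCConfig:
        return MCMCConfig(chains=self.chains, iterations=self.iterations,
                          burn_in=self.burn_in, thin=self.thin, seed=self.seed)

    def _fit_spec(self, spec: ModelSpec, data) -> None:
        self.spec_ = spec
        self.data_ = data
        self.samples_ = run_mcmc(spec, data, self._config())
        self.summary_ = summarize(self.samples_, level=self.level)

    def prob_exceeds(self, parameter: str, threshold: float) -> float:
        return prob_exceeds(self.samples_, parameter, threshold)


class ApparentPrevalence(_MCMCEstimator):
    """Apparent (test-positive) prevalence with a conjugate Beta prior.

    The posterior is available in closed form (``posterior_``); set
    ``method="mcmc"`` to sample it instead, e.g. to validate the
    sampler against the conjugate result.
    """

    def __init__(self, prior: BetaPrior | None = None, method: str = "conjugate",
                 zero_inflated: bool = False, w_prior: BetaPrior | None = None,
                 chains: int = 4, iterations: int = 30_000, burn_in: int = 10_000,
                 thin: int = 5, seed: int = 1, level: float = 0.95):
        self.prior = prior
        self.method = method
        self.zero_inflated = zero_inflated
        self.w_prior = w_prior
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.level = level

    def fit(self, X, y=None):
        if self.method not in ("conjugate", "mcmc"):
            raise ValueError(f"unknown method {self.method!r}")
        if self.zero_inflated and self.method == "conjugate":
            raise ValueError("the zero-inflated mixture has no conjugate posterior; "
                             "use method='mcmc'")
        counts = _as_counts(X)
        prior = self.prior if self.prior is not None else BetaPrior(1.0, 1.0)
        self.posterior_ = apparent_posterior(counts, prior)
        if self.method == "mcmc":
            spec = ModelSpec(family="apparent_single", prevalence_prior=prior,
                             zero_inflated=self.zero_inflated, w_prior=self.w_prior)
            self._fit_spec(spec, counts)
        else:
            self.spec_ = ModelSpec(family="apparent_single", prevalence_prior=prior)
            self.data_ = counts
        return self

    def predict(self, X=None):
        return self.posterior_.mean


class TruePrevalence(_MCMCEstimator):
    """Misclassification-adjusted prevalence for one population.

    The binomial success probability is the Rogan-Gladen map of the
    true prevalence through the test's sensitivity and specificity,
    each of which carries a Beta prior (or a point mass when treated as
    known).  With ``zero_inflated=True`` the population is disease-free
    with probability 1-w and ``pi_star`` draws carry the mixture
    prevalence.
    """

    def __init__(self, prevalence_prior: BetaPrior | None = None,
                 se_prior: BetaPrior | PointMass | None = None,
                 sp_prior: BetaPrior | PointMass | None = None,
                 zero_inflated: bool = False, w_prior: BetaPrior | None = None,
                 chains: int = 4, iterations: int = 30_000, burn_in: int = 10_000,
                 thin: int = 5, seed: int = 1, level: float = 0.95):
        self.prevalence_prior = prevalence_prior
        self.se_prior = se_prior
        self.sp_prior = sp_prior
        self.zero_inflated = zero_inflated
        self.w_prior = w_prior
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.level = level

    def fit(self, X, y=None):
        if self.se_prior is None or self.sp_prior is None:
            raise ValueError("se_prior and sp_prior are required")
        prior = (self.prevalence_prior if self.prevalence_prior is not None
                 else BetaPrior(1.0, 1.0))
        spec = ModelSpec(family="true_single", prevalence_prior=prior,
                         se_prior=self.se_prior, sp_prior=self.sp_prior,
                         zero_inflated=self.zero_inflated, w_prior=self.w_prior)
        self._fit_spec(spec, _as_counts(X))
        return self

    def predict(self, X=None):
        key = "pi_star" if self.zero_inflated else "pi_t"
        return float(self.samples_.pooled(key).mean())


class HierarchicalTruePrevalence(_MCMCEstimator):
    """Exchangeable cluster prevalences with shared test accuracy.

    Cluster prevalences follow Beta(mu*psi, psi*(1-mu)); mu is the mean
    group prevalence (Beta prior) and psi the concentration (Gamma
    prior; larger means less between-cluster heterogeneity).
    ``freedom(threshold)`` reports the disease-freedom summaries.
    """

    def __init__(self, mu_prior: BetaPrior | None = None,
                 psi_prior: GammaPrior | None = None,
                 se_prior: BetaPrior | PointMass | None = None,
                 sp_prior: BetaPrior | PointMass | None = None,
                 zero_inflated: bool = False, w_prior: BetaPrior | None = None,
                 w_mode: str = "shared",
                 chains: int = 4, iterations: int = 30_000, burn_in: int = 10_000,
                 thin: int = 5, seed: int = 1, level: float = 0.95):
        self.mu_prior = mu_prior
        self.psi_prior = psi_prior
        self.se_prior = se_prior
        self.sp_prior = sp_prior
        self.zero_inflated = zero_inflated
        self.w_prior = w_prior
        self.w_mode = w_mode
        self.chains = chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.seed = seed
        self.level = level

    def fit(self, X, y=None):
        if self.se_prior is None or self.sp_prior is None:
            raise ValueError("se_prior and sp_prior are required")
        mu_prior = self.mu_prior if self.mu_prior is not None else BetaPrior(1.0, 1.0)
        psi_prior = self.psi_prior if self.psi_prior is not None else GammaPrior(1.0, 0.1)
        spec = ModelSpec(family="true_multi", prevalence_prior=(mu_prior, psi_prior),
                         se_prior=self.se_prior, sp_prior=self.sp_prior,
                         zero_inflated=self.zero_inflated, w_prior=self.w_prior,
                         w_mode=self.w_mode)
        self._fit_spec(spec, _as_table(X))
        return self

    def predict(self, X=None):
        return float(self.samples_.pooled("mu").mean())

    def freedom(self, threshold: float = 0.02) -> dict:
        return freedom_summaries(self.samples_, level=self.level, threshold=threshold)
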