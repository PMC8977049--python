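"""Probabilistic building blocks for prevalence estimation.

Apparent prevalence pi_a is the probability of a positive test; true
prevalence pi_t is the probability of disease.  An imperfect test with
sensitivity Se and specificity Sp links the two through the
Rogan-Gladen relation

    pi_a = pi_t * Se + (1 - pi_t) * (1 - Sp).

This module provides the likelihoods of the supported model families
(conjugate apparent-prevalence, misclassification-adjusted single
population, hierarchical beta-binomial for multiple populations and
their zero-inflated mixtures), plus the classical Wald interval for raw
apparent prevalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Union

import numpy as np
from scipy import stats
from scipy.special import betaln, gammaln

from .data import ClusterTable, SurveyCounts
from .priors import BetaPrior, GammaPrior, PointMass

__all__ = [
    "ModelSpec",
    "apparent_posterior",
    "rogan_gladen",
    "loglik_true_single",
    "loglik_true_multi",
    "log_hier_prior",
    "mixture_loglik",
    "wald_interval",
]

Family = Literal["apparent_single", "true_single", "true_multi"]


def binom_logpmf(y, n, p):
    """Binomial log-pmf; -inf where the outcome is impossible (p in {0,1})."""
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.asarray(p, dtype=float)
    out = np.full(np.broadcast_shapes(y.shape, n.shape, p.shape), -np.inf)
    coef = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = (0.0 < p) & (p < 1.0)
        out = np.where(inner, coef + y * np.log(np.where(inner, p, 0.5))
                       + (n - y) * np.log1p(-np.where(inner, p, 0.5)), out)
        out = np.where((p == 0.0) & (y == 0), 0.0, out)
        out = np.where((p == 1.0) & (y == n), 0.0, out)
    return out if out.ndim else float(out)


def beta_logpdf(x, a, b):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            (0.0 < x) & (x < 1.0),
            (a - 1) * np.log(np.clip(x, 1e-300, None))
            + (b - 1) * np.log1p(-np.clip(x, None, 1 - 1e-16))
            - betaln(a, b),
            -np.inf,
        )
    return out if out.ndim else float(out)


def gamma_logpdf(x, shape, rate):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(
            x > 0,
            shape * np.log(rate) + (shape - 1) * np.log(np.clip(x, 1e-300, None))
            - rate * x - gammaln(shape),
            -np.inf,
        )
    return out if out.ndim else float(out)


def apparent_posterior(data: SurveyCounts, prior: BetaPrior) -> BetaPrior:
    """Conjugate Beta posterior of apparent prevalence: Beta(a+y, b+n-y)."""
    return BetaPrior(prior.alpha + data.y, prior.beta + data.n - data.y)


def rogan_gladen(pi_t, se, sp):
    """Apparent prevalence implied by true prevalence and test accuracy."""
    pi_t = np.asarray(pi_t, dtype=float)
    out = np.clip(pi_t * se + (1.0 - pi_t) * (1.0 - np.asarray(sp, dtype=float)), 0.0, 1.0)
    return out if out.ndim else float(out)


def loglik_true_single(pi_t, se, sp, data: SurveyCounts):
    """Binomial log-likelihood of (y, n) at success probability rogan_gladen(pi_t, se, sp)."""
    return binom_logpmf(data.y, data.n, rogan_gladen(pi_t, se, sp))


def loglik_true_multi(pi_t_vector, se, sp, data: ClusterTable):
    """Sum of per-cluster binomial log-likelihoods with Se/Sp shared across clusters."""
    pi = np.asarray(pi_t_vector, dtype=float)
    if pi.shape[-1] != data.k:
        raise ValueError(f"expected {data.k} cluster prevalences, got {pi.shape[-1]}")
    return binom_logpmf(data.y, data.n, rogan_gladen(pi, se, sp)).sum(axis=-1)


def log_hier_prior(pi_t_vector, mu, psi):
    """Exchangeable-prevalence log-density: sum of Beta(mu*psi, psi*(1-mu)) terms.

    The mean of this Beta is mu and its variance mu*(1-mu)/(psi+1), so
    large psi means low between-cluster heterogeneity.
    """
    if not 0 < mu < 1:
        raise ValueError(f"mu must lie in (0,1), got {mu}")
    if psi <= 0:
        raise ValueError(f"psi must be positive, got {psi}")
    pi = np.asarray(pi_t_vector, dtype=float)
    return beta_logpdf(pi, mu * psi, psi * (1.0 - mu)).sum(axis=-1)


def _free_logprob(y, n, sp, family: Family):
    """Log-likelihood of the disease-free component (pi = 0)."""
    if family == "apparent_single":
        # a free population cannot yield positives
        return binom_logpmf(y, n, 0.0)
    return binom_logpmf(y, n, 1.0 - np.asarray(sp, dtype=float))


def mixture_loglik(theta: dict, w, data: SurveyCounts | ClusterTable, family: Family):
    """Marginalized zero-inflation mixture log-likelihood.

    ``theta`` holds the infected-component parameters (``pi_t`` or
    ``pi_t_vector``; ``se``/``sp`` for true-prevalence families; or
    ``pi_a``).  Per population the likelihood is
    ``w * L(data | pi) + (1 - w) * L(data | pi = 0)``, with the free
    component at success probability 1-Sp (true prevalence) or 0
    (apparent prevalence); for cluster tables the mixture applies
    independently per cluster.
    """
    if not 0 < w < 1:
        raise ValueError(f"w must lie in (0,1), got {w}")
    if family == "apparent_single":
        l1 = binom_logpmf(data.y, data.n, theta["pi_a"])
        l0 = _free_logprob(data.y, data.n, None, family)
    elif family == "true_single":
        l1 = loglik_true_single(theta["pi_t"], theta["se"], theta["sp"], data)
        l0 = _free_logprob(data.y, data.n, theta["sp"], family)
    elif family == "true_multi":
        pi = np.asarray(theta["pi_t_vector"], dtype=float)
        l1 = binom_logpmf(data.y, data.n, rogan_gladen(pi, theta["se"], theta["sp"]))
        l0 = _free_logprob(data.y, data.n, theta["sp"], family)
    else:
        raise ValueError(f"unknown family {family!r}")
    per = np.logaddexp(np.log(w) + l1, np.log1p(-w) + l0)
    if family == "true_multi":
        return per.sum(axis=-1)
    return per if np.ndim(per) else float(per)


def wald_interval(data: SurveyCounts, level: float = 0.95):
    """Normal-approximation (Wald) point estimate and CI for apparent prevalence."""
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0,1), got {level}")
    p = data.y / data.n
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(p * (1.0 - p) / data.n)
    return p, max(p - half, 0.0), min(p + half, 1.0)


PrevalencePrior = Union[BetaPrior, tuple[BetaPrior, GammaPrior]]


@dataclass(frozen=True)
class ModelSpec:
    """Complete specification of a prevalence model.

    ``prevalence_prior`` is a single ``BetaPrior`` for the single-
    population families, or a ``(BetaPrior, GammaPrior)`` pair for the
    hierarchical (mu, psi) hyper-priors of ``true_multi``.  ``se_prior``
    and ``sp_prior`` must be given (Beta or point mass) exactly when the
    family involves true prevalence; ``w_prior`` exactly when
    ``zero_inflated``.  ``w_mode`` selects one shared infection
    probability (default) or exchangeable per-cluster weights.
    """

    family: Family
    prevalence_prior: PrevalencePrior
    se_prior: BetaPrior | PointMass | None = None
    sp_prior: BetaPrior | PointMass | None = None
    zero_inflated: bool = False
    w_prior: BetaPrior | None = None
    w_mode: Literal["shared", "cluster"] = "shared"

    def __post_init__(self) -> None:
        if self.family not in ("apparent_single", "true_single", "true_multi"):
            raise ValueError(f"unknown family {self.family!r}")
        needs_test = self.family in ("true_single", "true_multi")
        if needs_test and (self.se_prior is None or self.sp_prior is None):
            raise ValueError(f"family {self.family!r} requires se_prior and sp_prior")
        if not needs_test and (self.se_prior is not None or self.sp_prior is not None):
            raise ValueError("se/sp priors are only meaningful for true-prevalence families")
        if self.zero_inflated != (self.w_prior is not None):
            raise ValueError("w_prior must be present exactly when zero_inflated")
        if self.family == "true_multi":
            if not (isinstance(self.prevalence_prior, tuple)
                    and len(self.prevalence_prior) == 2
                    and isinstance(self.prevalence_prior[0], BetaPrior)
                    and isinstance(self.prevalence_prior[1], GammaPrior)):
                raise ValueError("true_multi requires a (BetaPrior, GammaPrior) pair for (mu, psi)")
        elif not isinstance(self.prevalence_prior, BetaPrior):
            raise ValueError(f"family {self.family!r} requires a BetaPrior on prevalence")
        if self.w_mode not in ("shared", "cluster"):
            raise ValueError(f"unknown w_mode {self.w_mode!r}")
        if self.w_mode == "cluster" and self.family != "true_multi":
            raise ValueError("per-cluster zero-inflation weights require family 'true_multi'")
        if needs_test:
            self._check_identifiability()

    def _check_identifiability(self) -> None:
        # Se + Sp <= 1 makes apparent prevalence non-increasing in true
        # prevalence; flag priors that put visible mass there.
        rng = np.random.default_rng(0)
        draw = lambda pr: (np.full(4096, pr.value) if isinstance(pr, PointMass)
                           else pr.rvs(rng, 4096))
        frac = np.mean(draw(self.se_prior) + draw(self.sp_prior) <= 1.0)
        if frac > 0.01:
            warnings.warn(
                f"prior P(Se + Sp <= 1) ~= {frac:.2f}: true prevalence is only weakly "
                "identified (label-switching hazard); consider more informative "
                "accuracy priors",
                UserWarning,
                stacklevel=3,
            )
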