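"""Prior distribution containers.

The models in this package use Beta priors for every probability-scale
parameter (prevalence, sensitivity, specificity, zero-inflation weight,
mean group prevalence) and a Gamma prior for the heterogeneity
(concentration) parameter of the hierarchical model.  Fixed parameter
values are represented as point masses so that "known sensitivity"
models fit in the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class PriorError(ValueError):
    """Raised for invalid prior hyperparameters."""


@dataclass(frozen=True)
class BetaPrior:
    """Beta(alpha, beta) prior on a probability-scale quantity."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise PriorError("Beta hyperparameters must be finite")
        if self.alpha <= 0 or self.beta <= 0:
            raise PriorError(
                f"Beta hyperparameters must be positive, got ({self.alpha}, {self.beta})"
            )

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def dist(self):
        return stats.beta(self.alpha, self.beta)

    def quantile(self, q):
        return stats.beta.ppf(q, self.alpha, self.beta)

    def rvs(self, rng: np.random.Generator, size=None):
        return rng.beta(self.alpha, self.beta, size=size)

    def summary(self) -> "PriorSummary":
        return summarize_prior(self)

    def __repr__(self) -> str:  # printed at 2 dp, stored at full precision
        return f"BetaPrior(alpha={self.alpha:.2f}, beta={self.beta:.2f})"


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape, rate) prior on a positive quantity.

    Parameterized by shape and *rate* (mean = shape/rate), matching the
    usual convention for the heterogeneity parameter of a hierarchical
    beta-binomial model.
    """

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.shape) and np.isfinite(self.rate)):
            raise PriorError("Gamma hyperparameters must be finite")
        if self.shape <= 0 or self.rate <= 0:
            raise PriorError(
                f"Gamma hyperparameters must be positive, got ({self.shape}, {self.rate})"
            )

    @property
    def mean(self) -> float:
        return self.shape / self.rate

    @property
    def dist(self):
        return stats.gamma(self.shape, scale=1.0 / self.rate)

    def quantile(self, q):
        return stats.gamma.ppf(q, self.shape, scale=1.0 / self.rate)

    def rvs(self, rng: np.random.Generator, size=None):
        return rng.gamma(self.shape, 1.0 / self.rate, size=size)

    def summary(self) -> "PriorSummary":
        return summarize_prior(self)

    def __repr__(self) -> str:
        return f"GammaPrior(shape={self.shape:.2f}, rate={self.rate:.2f})"


@dataclass(frozen=True)
class PointMass:
    """Degenerate prior fixing a parameter at a known value.

    Used for analyses that treat test sensitivity/specificity as known
    constants rather than uncertain quantities.
    """

    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise PriorError(f"point mass must lie in [0, 1], got {self.value}")

    @property
    def mean(self) -> float:
        return self.value


@dataclass(frozen=True)
class PriorSummary:
    """Location and spread of a prior: mean, median, IQR and central 95% interval."""

    mean: float
    median: float
    q25: float
    q75: float
    q2_5: float
    q97_5: float

    def __post_init__(self) -> None:
        q = (self.q2_5, self.q25, self.median, self.q75, self.q97_5)
        if not all(a <= b + 1e-12 for a, b in zip(q, q[1:])):
            raise PriorError(f"quantiles out of order: {q}")


def summarize_prior(prior: BetaPrior | GammaPrior) -> PriorSummary:
    """Summarize a prior by its mean and standard quantiles.

    Quantiles are computed from the exact distribution function
    (scipy's incomplete beta / gamma inverses), not by simulation.
    """
    if isinstance(prior, PointMass):
        v = prior.value
        return PriorSummary(v, v, v, v, v, v)
    d = prior.dist
    q2_5, q25, med, q75, q97_5 = d.ppf([0.025, 0.25, 0.5, 0.75, 0.975])
    return PriorSummary(float(d.mean()), float(med), float(q25), float(q75), float(q2_5), float(q97_5))
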