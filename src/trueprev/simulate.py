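"""Synthetic survey generators.

Data are drawn from the same generative models the estimators fit:
a single population tests positive at the Rogan-Gladen rate
``pi_t*Se + (1-pi_t)*(1-Sp)``; in the multi-population case each
cluster first draws a freedom indicator (infected with probability
``w``), then a cluster prevalence from ``Beta(mu*psi, psi*(1-mu))``,
then its binomial count.  Every simulator is deterministic given its
seed, and returns the realized ground truth alongside the data so
recovery experiments can score themselves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ClusterTable, SurveyCounts
from .models import rogan_gladen

__all__ = ["SimulationTruth", "simulate_single", "simulate_multi"]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth that fully determines the sampling distribution."""

    family: str
    seed: int
    pi_t: float | np.ndarray
    se: float
    sp: float
    mu: float | None = None
    psi: float | None = None
    w: float | None = None
    infected: np.ndarray | None = None


def simulate_single(pi_t: float, se: float, sp: float, n: int,
                    seed: int = 0) -> tuple[SurveyCounts, SimulationTruth]:
    """One population: y ~ Binomial(n, pi_t*Se + (1-pi_t)*(1-Sp))."""
    for name, v in (("pi_t", pi_t), ("se", se), ("sp", sp)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0,1], got {v}")
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    y = int(rng.binomial(n, rogan_gladen(pi_t, se, sp)))
    truth = SimulationTruth(family="true_single", seed=seed, pi_t=pi_t, se=se, sp=sp)
    return SurveyCounts(y=y, n=n), truth


def simulate_multi(mu: float, psi: float, se: float, sp: float, n_vector,
                   w: float = 1.0, seed: int = 0) -> tuple[ClusterTable, SimulationTruth]:
    """k clusters of an exchangeable-prevalence region, optionally zero-inflated.

    ``w`` is the probability a cluster is infected at all; ``w=1``
    disables zero-inflation.  Infected clusters draw their prevalence
    from Beta(mu*psi, psi*(1-mu)); free clusters have prevalence 0 and
    still produce false positives at rate 1-Sp.
    """
    if not 0.0 < mu < 1.0:
        raise ValueError(f"mu must lie in (0,1), got {mu}")
    if psi <= 0:
        raise ValueError(f"psi must be positive, got {psi}")
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w must lie in [0,1], got {w}")
    n_vector = np.asarray(n_vector, dtype=int)
    if n_vector.ndim != 1 or n_vector.size < 1 or np.any(n_vector <= 0):
        raise ValueError("n_vector must be a 1-d array of positive sample sizes")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    k = n_vector.size
    infected = rng.random(k) < w
    pi = np.where(infected, rng.beta(mu * psi, psi * (1.0 - mu), size=k), 0.0)
    y = rng.binomial(n_vector, rogan_gladen(pi, se, sp))
    table = ClusterTable(
        labels=tuple(f"cluster_{i + 1}" for i in range(k)), y=y, n=n_vector
    )
    truth = SimulationTruth(family="true_multi", seed=seed, pi_t=pi, se=se, sp=sp,
                            mu=mu, psi=psi, w=w, infected=infected)
    return table, truth
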