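"""Shared fixtures.

The expensive default-configuration MCMC fits used by several test
modules are session-scoped so each is run once per session.
"""

from __future__ import annotations

import pytest

from trueprev import (
    BetaPrior,
    ElicitationStatement,
    GammaPrior,
    MCMCConfig,
    ModelSpec,
    PointMass,
    SurveyCounts,
    elicit_beta,
    load_fixture,
    run_mcmc,
)

# Table-2 prior statements: Se mean 0.8 (97% above 0.75), Sp mean 0.9
# (97% above 0.85); zero-inflation weight mean 0.2 (95% above 0.1).
SE_STMT = ElicitationStatement("mean", 0.80, 0.75, 0.97)
SP_STMT = ElicitationStatement("mean", 0.90, 0.85, 0.97)
W_STMT = ElicitationStatement("mean", 0.20, 0.10, 0.95)

# Dementia example: mean group prevalence 0.2 with 99% certainty below
# 0.3; test accuracy from DSM-IV historical performance statements.
MU_STMT = ElicitationStatement("mean", 0.20, 0.30, 0.99, "less")
SE_DEMENTIA_STMT = ElicitationStatement("mean", 0.88, 0.80, 0.90)
SP_DEMENTIA_STMT = ElicitationStatement("mean", 0.95, 0.85, 0.97)


@pytest.fixture(scope="session")
def toy_priors():
    return {
        "se": elicit_beta(SE_STMT),
        "sp": elicit_beta(SP_STMT),
        "w": elicit_beta(W_STMT),
    }


@pytest.fixture(scope="session")
def quick_cfg():
    return MCMCConfig(chains=2, iterations=4000, burn_in=1500, thin=2, seed=7)


def _true_single_fit(y, prevalence_prior, priors, zero_inflated=False):
    spec = ModelSpec(
        family="true_single",
        prevalence_prior=prevalence_prior,
        se_prior=priors["se"],
        sp_prior=priors["sp"],
        zero_inflated=zero_inflated,
        w_prior=priors["w"] if zero_inflated else None,
    )
    return run_mcmc(spec, SurveyCounts(y=y, n=500), MCMCConfig())


@pytest.fixture(scope="session")
def setup_a_fits(toy_priors):
    """Uniform prevalence prior, elicited Se/Sp priors, both toy datasets."""
    return {y: _true_single_fit(y, BetaPrior(1, 1), toy_priors) for y in (120, 25)}


@pytest.fixture(scope="session")
def setup_b_fits(toy_priors):
    """Weakly informative Beta(1.31, 1.31) prevalence prior (central value 0.5)."""
    prior = elicit_beta(ElicitationStatement("mean", 0.50, 0.08, 0.95))
    return {y: _true_single_fit(y, prior, toy_priors) for y in (120, 25)}


@pytest.fixture(scope="session")
def fixed_accuracy_fits(toy_priors):
    """Known Se=0.80, Sp=0.90 (point masses), uniform prevalence prior."""
    out = {}
    for y in (120, 25):
        spec = ModelSpec(
            family="true_single",
            prevalence_prior=BetaPrior(1, 1),
            se_prior=PointMass(0.80),
            sp_prior=PointMass(0.90),
        )
        out[y] = run_mcmc(spec, SurveyCounts(y=y, n=500), MCMCConfig())
    return out


@pytest.fixture(scope="session")
def zero_inflated_fits(toy_priors):
    return {
        y: _true_single_fit(y, BetaPrior(1, 1), toy_priors, zero_inflated=True)
        for y in (120, 25)
    }


@pytest.fixture(scope="session")
def dementia_fit():
    """Hierarchical fit of the 9-study dementia table with elicited priors."""
    spec = ModelSpec(
        family="true_multi",
        prevalence_prior=(elicit_beta(MU_STMT), GammaPrior(1.0, 0.1)),
        se_prior=elicit_beta(SE_DEMENTIA_STMT),
        sp_prior=elicit_beta(SP_DEMENTIA_STMT),
    )
    # longer run than the single-population default: the sticky
    # specificity/heterogeneity blocks of the 9-study posterior need it
    cfg = MCMCConfig(iterations=150_000, burn_in=30_000, thin=5)
    return run_mcmc(spec, load_fixture("dementia_9"), cfg)
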