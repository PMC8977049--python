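"""Sampler correctness: determinism, conjugate agreement, summaries, freedom."""

import numpy as np
import pytest

from trueprev import (
    BetaPrior,
    GammaPrior,
    MCMCConfig,
    ModelSpec,
    PointMass,
    PosteriorSamples,
    SurveyCounts,
    freedom_summaries,
    prob_exceeds,
    run_mcmc,
    simulate_multi,
    summarize,
)


def test_config_validation():
    with pytest.raises(ValueError):
        MCMCConfig(chains=1)
    with pytest.raises(ValueError):
        MCMCConfig(burn_in=5000, iterations=5000)
    with pytest.raises(ValueError):
        MCMCConfig(thin=0)


def test_seed_determinism_and_sensitivity(quick_cfg):
    spec = ModelSpec(family="apparent_single", prevalence_prior=BetaPrior(1, 1))
    data = SurveyCounts(12, 60)
    a = run_mcmc(spec, data, quick_cfg)
    b = run_mcmc(spec, data, quick_cfg)
    np.testing.assert_array_equal(a.get("pi_a"), b.get("pi_a"))
    other = run_mcmc(spec, data, MCMCConfig(chains=2, iterations=4000,
                                            burn_in=1500, thin=2, seed=8))
    assert not np.array_equal(a.get("pi_a"), other.get("pi_a"))


def test_apparent_mcmc_matches_conjugate_quantiles():
    spec = ModelSpec(family="apparent_single", prevalence_prior=BetaPrior(1, 1))
    samples = run_mcmc(spec, SurveyCounts(120, 500), MCMCConfig())
    analytic = BetaPrior(121, 381)
    draws = samples.pooled("pi_a")
    for q in (0.025, 0.25, 0.5, 0.75, 0.975):
        assert np.quantile(draws, q, method="median_unbiased") == pytest.approx(
            analytic.quantile(q), abs=0.002
        )
    assert draws.mean() == pytest.approx(analytic.mean, abs=0.002)


def test_wrong_data_shape_raises(quick_cfg):
    spec = ModelSpec(family="true_multi",
                     prevalence_prior=(BetaPrior(1, 1), GammaPrior(1, 0.1)),
                     se_prior=PointMass(0.9), sp_prior=PointMass(0.95))
    with pytest.raises(TypeError):
        run_mcmc(spec, SurveyCounts(5, 50), quick_cfg)
    single = ModelSpec(family="apparent_single", prevalence_prior=BetaPrior(1, 1))
    table, _ = simulate_multi(0.2, 10, 0.9, 0.95, [50, 50], seed=0)
    with pytest.raises(TypeError):
        run_mcmc(single, table, quick_cfg)


def test_summarize_constant_chain_and_level():
    samples = PosteriorSamples(params={"x": np.full((2, 200), 0.37)})
    s = summarize(samples)
    assert s.loc["x", "mean"] == s.loc["x", "median"] == 0.37
    assert s.loc["x", "q_lo"] == s.loc["x", "q_hi"] == 0.37
    with pytest.raises(ValueError):
        summarize(samples, level=1.2)


def test_summarize_matches_sort_based_quantile_oracle():
    rng = np.random.default_rng(5)
    draws = rng.standard_normal((3, 501))
    samples = PosteriorSamples(params={"x": draws})
    s = summarize(samples)
    x = np.sort(draws.reshape(-1))
    n = x.size

    def type8(p):  # median-unbiased empirical quantile, computed by hand
        h = (n + 1 / 3) * p + 1 / 3 - 1
        lo = int(np.floor(h))
        return x[lo] + (h - lo) * (x[lo + 1] - x[lo])

    assert s.loc["x", "median"] == pytest.approx(type8(0.5), abs=1e-12)
    assert s.loc["x", "q_lo"] == pytest.approx(type8(0.025), abs=1e-12)
    assert s.loc["x", "q_hi"] == pytest.approx(type8(0.975), abs=1e-12)


def test_prob_exceeds():
    samples = PosteriorSamples(params={"x": np.full((2, 100), 0.9)})
    assert prob_exceeds(samples, "x", 0.5) == 1.0
    rng = np.random.default_rng(2)
    uni = PosteriorSamples(params={"u": rng.random((2, 20_000))})
    assert prob_exceeds(uni, "u", 0.25) == pytest.approx(0.75, abs=0.01)
    with pytest.raises(KeyError):
        prob_exceeds(samples, "nope", 0.5)


def test_probability_draws_stay_in_range(dementia_fit):
    for name in dementia_fit.names:
        x = dementia_fit.pooled(name)
        if name == "psi":
            assert np.all(x > 0)
        else:
            assert np.all((x >= 0) & (x <= 1))


@pytest.fixture(scope="module")
def hier_fit(quick_cfg):
    table, truth = simulate_multi(0.35, 15, 0.9, 0.95, [400] * 12, seed=21)
    spec = ModelSpec(
        family="true_multi",
        prevalence_prior=(BetaPrior(1, 1), GammaPrior(1, 0.1)),
        se_prior=PointMass(0.9),
        sp_prior=PointMass(0.95),
    )
    return run_mcmc(spec, table, quick_cfg), truth


def test_freedom_summaries_boundary_and_separation(hier_fit):
    samples, truth = hier_fit
    at_one = freedom_summaries(samples, threshold=1.0)
    assert at_one["p_all_below"] == 1.0
    assert at_one["p_predictive_below"] == 1.0
    # data generated with prevalences far above 1%: freedom at 1% is implausible
    low = freedom_summaries(samples, threshold=0.01)
    assert low["p_all_below"] == pytest.approx(0.0, abs=1e-6)
    assert low["clusters"].shape[0] == 12
    a, b = low["distribution_params"]
    assert a.shape == b.shape == (samples.chains * samples.draws_per_chain,)


def test_freedom_predictive_agrees_with_larger_monte_carlo(hier_fit):
    samples, _ = hier_fit
    res = freedom_summaries(samples, threshold=0.2)
    mu = samples.pooled("mu")
    psi = samples.pooled("psi")
    rng = np.random.default_rng(17)
    reps = [rng.beta(mu * psi, psi * (1 - mu)) for _ in range(10)]
    oracle = np.mean([np.mean(r < 0.2) for r in reps])
    assert res["p_predictive_below"] == pytest.approx(oracle, abs=0.02)


def test_freedom_requires_hierarchical_fit(quick_cfg):
    spec = ModelSpec(family="apparent_single", prevalence_prior=BetaPrior(1, 1))
    samples = run_mcmc(spec, SurveyCounts(3, 30), quick_cfg)
    with pytest.raises(ValueError):
        freedom_summaries(samples)


def test_posterior_means_stable_across_seeds(toy_priors, setup_a_fits):
    spec = ModelSpec(family="true_single", prevalence_prior=BetaPrior(1, 1),
                     se_prior=toy_priors["se"], sp_prior=toy_priors["sp"])
    other = run_mcmc(spec, SurveyCounts(120, 500),
                     MCMCConfig(seed=2))
    a = setup_a_fits[120].pooled("pi_t").mean()
    b = other.pooled("pi_t").mean()
    assert abs(a - b) < 0.005
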