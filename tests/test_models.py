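"""Likelihoods, the conjugate update, the prevalence map and Wald intervals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from trueprev import (
    BetaPrior,
    ClusterTable,
    GammaPrior,
    ModelSpec,
    PointMass,
    SurveyCounts,
    apparent_posterior,
    load_fixture,
    log_hier_prior,
    loglik_true_multi,
    loglik_true_single,
    mixture_loglik,
    rogan_gladen,
    wald_interval,
)

probs = st.floats(0.01, 0.99)


def test_conjugate_update():
    assert apparent_posterior(SurveyCounts(0, 1), BetaPrior(1, 1)) == BetaPrior(1, 2)
    assert apparent_posterior(SurveyCounts(120, 500), BetaPrior(1, 1)) == BetaPrior(121, 381)


def test_conjugate_posterior_mean_by_quadrature():
    post = apparent_posterior(SurveyCounts(120, 500), BetaPrior(1, 1))
    mean, _ = integrate.quad(lambda x: x * post.dist.pdf(x), 0, 1)
    assert mean == pytest.approx(121 / 502, abs=1e-9)


def test_rogan_gladen_boundaries_and_inverse():
    assert rogan_gladen(0.0, 0.8, 0.9) == pytest.approx(0.1)  # 1 - sp
    assert rogan_gladen(1.0, 0.8, 0.9) == pytest.approx(0.8)  # se
    pa = rogan_gladen(0.2015, 0.80, 0.90)
    assert pa == pytest.approx(0.24105)
    assert (pa - 0.1) / 0.7 == pytest.approx(0.2015)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(se=probs, sp=probs, p1=probs, p2=probs)
def test_rogan_gladen_monotone_iff_test_is_informative(se, sp, p1, p2):
    lo, hi = sorted((p1, p2))
    diff = rogan_gladen(hi, se, sp) - rogan_gladen(lo, se, sp)
    if se + sp > 1:
        assert diff >= 0
    else:
        assert diff <= 0
    assert 0.0 <= rogan_gladen(p1, se, sp) <= 1.0


def test_true_single_perfect_test_reduces_to_direct_binomial():
    # with se = sp = 1 the success probability is pi_t itself
    ll = loglik_true_single(0.3, 1.0, 1.0, SurveyCounts(0, 1))
    assert ll == pytest.approx(np.log(0.7))


def test_true_single_closed_form():
    ll = loglik_true_single(0.5, 0.5, 0.5, SurveyCounts(3, 10))
    from math import comb, log

    assert ll == pytest.approx(log(comb(10, 3)) - 10 * log(2))


def test_true_single_agrees_with_latent_table_enumeration():
    # enumerate diseased count d, true positives and false positives
    pi_t, se, sp, y, n = 0.23, 0.81, 0.93, 3, 7
    total = 0.0
    for d in range(n + 1):
        p_d = stats.binom.pmf(d, n, pi_t)
        for tp in range(d + 1):
            fp = y - tp
            if not 0 <= fp <= n - d:
                continue
            total += (p_d * stats.binom.pmf(tp, d, se)
                      * stats.binom.pmf(fp, n - d, 1 - sp))
    assert loglik_true_single(pi_t, se, sp, SurveyCounts(y, n)) == pytest.approx(
        np.log(total), abs=1e-10
    )


def test_impossible_outcomes_have_zero_likelihood():
    assert loglik_true_single(0.0, 1.0, 1.0, SurveyCounts(2, 5)) == -np.inf
    assert loglik_true_single(1.0, 1.0, 1.0, SurveyCounts(3, 5)) == -np.inf


@pytest.fixture()
def small_table():
    return ClusterTable(labels=("a", "b", "c"), y=np.array([2, 0, 5]),
                        n=np.array([10, 12, 20]))


def test_multi_loglik_is_sum_of_single_terms(small_table):
    pi = np.array([0.1, 0.05, 0.4])
    total = loglik_true_multi(pi, 0.9, 0.95, small_table)
    parts = sum(
        loglik_true_single(p, 0.9, 0.95, SurveyCounts(y, n))
        for p, y, n in zip(pi, small_table.y, small_table.n)
    )
    assert total == pytest.approx(parts, abs=1e-10)


def test_multi_loglik_single_cluster_reduction():
    table = ClusterTable(labels=("only",), y=np.array([4]), n=np.array([9]))
    assert loglik_true_multi(np.array([0.3]), 0.8, 0.9, table) == pytest.approx(
        loglik_true_single(0.3, 0.8, 0.9, SurveyCounts(4, 9))
    )


def test_multi_loglik_all_negative_perfect_test_closed_form():
    table = ClusterTable(labels=("a", "b"), y=np.array([0, 0]), n=np.array([5, 8]))
    pi = np.array([0.1, 0.2])
    expected = 5 * np.log(0.9) + 8 * np.log(0.8)
    assert loglik_true_multi(pi, 1.0, 1.0, table) == pytest.approx(expected)


def test_multi_loglik_rejects_wrong_length(small_table):
    with pytest.raises(ValueError):
        loglik_true_multi(np.array([0.1, 0.2]), 0.9, 0.95, small_table)


def test_hier_prior_uniform_case_and_mean():
    # mu=0.5, psi=2 gives Beta(1,1): zero log-density anywhere inside (0,1)
    assert log_hier_prior(np.array([0.3, 0.9]), 0.5, 2.0) == pytest.approx(0.0)
    rng = np.random.default_rng(11)
    draws = rng.beta(0.2 * 10, 10 * 0.8, size=200_000)
    assert draws.mean() == pytest.approx(0.2, abs=0.005)
    assert draws.var() == pytest.approx(0.2 * 0.8 / 11, rel=0.05)


def test_hier_prior_matches_scipy_and_handles_boundaries():
    pi = np.array([0.1, 0.35, 0.8])
    mine = log_hier_prior(pi, 0.3, 7.0)
    ref = stats.beta.logpdf(pi, 0.3 * 7, 7 * 0.7).sum()
    assert mine == pytest.approx(ref, abs=1e-10)
    assert log_hier_prior(np.array([0.0]), 0.3, 7.0) == -np.inf


def test_mixture_recovers_plain_likelihood_as_w_tends_to_one():
    data = SurveyCounts(8, 40)
    theta = {"pi_t": 0.3, "se": 0.85, "sp": 0.92}
    plain = loglik_true_single(0.3, 0.85, 0.92, data)
    mixed = mixture_loglik(theta, 1 - 1e-12, data, "true_single")
    assert mixed == pytest.approx(plain, abs=1e-9)


def test_mixture_with_perfect_specificity_and_positives():
    # sp = 1 makes false positives impossible: the free component vanishes
    data = SurveyCounts(3, 10)
    theta = {"pi_t": 0.4, "se": 0.9, "sp": 1.0}
    got = mixture_loglik(theta, 0.3, data, "true_single")
    assert got == pytest.approx(np.log(0.3) + loglik_true_single(0.4, 0.9, 1.0, data))


def test_mixture_agrees_with_direct_indicator_enumeration(small_table):
    theta = {"pi_t_vector": np.array([0.2, 0.1, 0.5]), "se": 0.9, "sp": 0.88}
    w = 0.35
    got = mixture_loglik(theta, w, small_table, "true_multi")
    expected = 0.0
    for pi, y, n in zip(theta["pi_t_vector"], small_table.y, small_table.n):
        p_inf = stats.binom.pmf(y, n, rogan_gladen(pi, 0.9, 0.88))
        p_free = stats.binom.pmf(y, n, 1 - 0.88)
        expected += np.log(w * p_inf + (1 - w) * p_free)
    assert got == pytest.approx(expected, abs=1e-10)


def test_mixture_apparent_family_free_component_forbids_positives():
    theta = {"pi_a": 0.2}
    data = SurveyCounts(2, 10)
    got = mixture_loglik(theta, 0.4, data, "apparent_single")
    assert got == pytest.approx(np.log(0.4) + stats.binom.logpmf(2, 10, 0.2))


WALD_ROWS = [
    ("Ravaglia et al.", 60, 961, 0.062, 0.047, 0.078),
    ("Tognoni et al.", 100, 1662, 0.060, 0.049, 0.072),
    ("Gascon-Bayarri et al.", 165, 1754, 0.094, 0.080, 0.108),
    ("Fish et al.", 88, 1665, 0.053, 0.042, 0.064),
    ("Bermejo-Pareja et al.", 306, 5278, 0.058, 0.052, 0.064),
    ("Mathillas et al.", 287, 895, 0.321, 0.290, 0.351),
    ("Tola-Arribas et al.", 184, 2170, 0.085, 0.073, 0.097),
    ("Lucca et al.", 894, 2501, 0.357, 0.339, 0.376),
    ("Perquin et al.", 53, 1377, 0.038, 0.028, 0.049),
]


@pytest.mark.parametrize("label, y, n, point, lo, hi", WALD_ROWS)
def test_wald_interval_reproduces_review_table(label, y, n, point, lo, hi):
    p, lower, upper = wald_interval(SurveyCounts(y, n))
    assert round(p, 3) == point
    assert round(lower, 3) == lo
    assert round(upper, 3) == hi


def test_wald_degenerate_all_negative():
    assert wald_interval(SurveyCounts(0, 50)) == (0.0, 0.0, 0.0)


def test_model_spec_validation():
    with pytest.raises(ValueError):
        ModelSpec(family="true_single", prevalence_prior=BetaPrior(1, 1))
    with pytest.raises(ValueError):
        ModelSpec(family="apparent_single", prevalence_prior=BetaPrior(1, 1),
                  se_prior=BetaPrior(2, 2))
    with pytest.raises(ValueError):
        ModelSpec(family="apparent_single", prevalence_prior=BetaPrior(1, 1),
                  zero_inflated=True)
    with pytest.raises(ValueError):
        ModelSpec(family="true_multi", prevalence_prior=BetaPrior(1, 1),
                  se_prior=PointMass(0.9), sp_prior=PointMass(0.95))


def test_uninformative_accuracy_priors_trigger_identifiability_warning():
    with pytest.warns(UserWarning, match="weakly identified"):
        ModelSpec(family="true_single", prevalence_prior=BetaPrior(1, 1),
                  se_prior=BetaPrior(2, 2), sp_prior=BetaPrior(2, 2))


def test_dementia_fixture_totals():
    table = load_fixture("dementia_9")
    assert table.k == 9
    assert int(table.n.sum()) == 18263
    assert int(table.y.sum()) == 2137
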