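"""Posterior sampling and posterior summaries.

All model families are fitted with the same engine: an adaptive
random-walk Metropolis-within-Gibbs sampler operating on transformed
scales (logit for probabilities, log for the concentration psi).
Proposal standard deviations adapt per parameter toward a 0.44
acceptance rate during burn-in only and are frozen afterwards, so the
retained draws target the exact posterior.  Chains are updated in
lock-step as vectorized numpy arrays; given identical model, data and
configuration (including the seed) the draws are bit-identical.

Zero-inflation is marginalized analytically: the sampler state never
contains the discrete infected/free indicator, which improves mixing
without changing the marginal posterior.  The mixture prevalence
``pi* = z * pi_t`` is reconstructed afterwards from the retained draws
by sampling the indicator from its exact conditional probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import ClusterTable, SurveyCounts
from .models import (
    ModelSpec,
    beta_logpdf,
    gamma_logpdf,
    rogan_gladen,
)
from .priors import BetaPrior, PointMass

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "run_mcmc",
    "summarize",
    "prob_exceeds",
    "freedom_summaries",
]

_ADAPT_WINDOW = 50
_TARGET_ACCEPT = 0.44
QUANTILE_METHOD = "median_unbiased"  # type-8-style empirical quantiles throughout


@dataclass(frozen=True)
class MCMCConfig:
    """Chain layout: chains x iterations, burn-in discarded, then thinned."""

    chains: int = 4
    iterations: int = 30_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 1

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need at least 2 chains for between-chain diagnostics")
        if not 0 <= self.burn_in < self.iterations:
            raise ValueError("need 0 <= burn_in < iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burn_in + self.thin - 1) // self.thin


@dataclass
class PosteriorSamples:
    """Named posterior draws organized as (chain, iteration) arrays."""

    params: dict[str, np.ndarray]
    spec: ModelSpec | None = None
    data: object = None
    config: MCMCConfig | None = None
    cluster_labels: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        shapes = {v.shape for v in self.params.values()}
        if len(shapes) > 1:
            raise ValueError(f"unequal draw counts across parameters: {shapes}")

    @property
    def names(self) -> list[str]:
        return list(self.params)

    @property
    def chains(self) -> int:
        return next(iter(self.params.values())).shape[0]

    @property
    def draws_per_chain(self) -> int:
        return next(iter(self.params.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        if name not in self.params:
            raise KeyError(
                f"unknown parameter {name!r}; available: {', '.join(self.params)}"
            )
        return self.params[name]

    def pooled(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        """One row per retained draw, with chain and iteration columns."""
        c, d = self.chains, self.draws_per_chain
        out = {"chain": np.repeat(np.arange(1, c + 1), d),
               "iteration": np.tile(np.arange(1, d + 1), c)}
        for k, v in self.params.items():
            out[k] = v.reshape(-1)
        return pd.DataFrame(out)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PosteriorSamples":
        chains = int(df["chain"].max())
        draws = int(df["iteration"].max())
        params = {}
        for col in df.columns:
            if col in ("chain", "iteration"):
                continue
            params[col] = df[col].to_numpy().reshape(chains, draws)
        return cls(params=params)


# ---------------------------------------------------------------------------
# sampler internals


def _beta_lp_logit(z, prior: BetaPrior):
    """Beta log-prior plus logit-transform Jacobian, on the sampling scale."""
    x = expit(z)
    with np.errstate(divide="ignore", invalid="ignore"):
        return beta_logpdf(x, prior.alpha, prior.beta) + np.log(x) + np.log1p(-x)


def _gamma_lp_log(z, shape, rate):
    return gamma_logpdf(np.exp(z), shape, rate) + z


def _init_logit(prior, rng, size):
    if isinstance(prior, PointMass):
        return np.full(size, logit(np.clip(prior.value, 1e-12, 1 - 1e-12)))
    return logit(np.clip(prior.rvs(rng, size), 1e-6, 1 - 1e-6))


def _init_prevalence_logit(y, n, rng, size):
    """Data-informed overdispersed prevalence starts.

    Jittered draws on the apparent scale (Jeffreys-smoothed) keep every
    chain inside the identified basin of the misclassification model;
    prior draws of the prevalence can start a chain at a near-boundary
    value whose only escape route crosses the label-switched mirror
    mode, which a random-walk sampler cannot do.
    """
    return logit(np.clip(rng.beta(y + 0.5, n - y + 0.5, size=size), 1e-5, 1 - 1e-5))


class _Adapter:
    """Per-parameter proposal scales, adapted during burn-in only."""

    def __init__(self, shapes: dict):
        self.step = {k: np.ones(s) for k, s in shapes.items()}
        self.acc = {k: np.zeros(s) for k, s in shapes.items()}

    def update(self, it: int, burn_in: int) -> None:
        if it < burn_in and (it + 1) % _ADAPT_WINDOW == 0:
            for k in self.step:
                rate = self.acc[k] / _ADAPT_WINDOW
                self.step[k] *= np.exp(np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5))
                self.acc[k][:] = 0.0


def _binom_coef(y, n):
    from scipy.special import gammaln

    return gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)


def _mix(l1, l0, log_w, log_1mw):
    return np.logaddexp(log_w + l1, log_1mw + l0)


def run_mcmc(spec: ModelSpec, data, cfg: MCMCConfig = MCMCConfig()) -> PosteriorSamples:
    """Draw posterior samples for any model specification.

    ``data`` must be :class:`SurveyCounts` for the single-population
    families and :class:`ClusterTable` for ``true_multi``.  Convergence
    problems are not raised here; use the diagnostics module.
    """
    if spec.family == "true_multi":
        if not isinstance(data, ClusterTable):
            raise TypeError("family 'true_multi' requires a ClusterTable")
        params, labels = _sample_multi(spec, data, cfg)
    else:
        if not isinstance(data, SurveyCounts):
            raise TypeError(f"family {spec.family!r} requires SurveyCounts")
        params = _sample_single(spec, data, cfg)
        labels = ()
    return PosteriorSamples(params=params, spec=spec, data=data, config=cfg,
                            cluster_labels=labels)


def _sample_single(spec: ModelSpec, data: SurveyCounts, cfg: MCMCConfig) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    C = cfg.chains
    y, n = float(data.y), float(data.n)
    coef = _binom_coef(y, n)
    apparent = spec.family == "apparent_single"
    mix = spec.zero_inflated

    se_fixed = apparent or isinstance(spec.se_prior, PointMass)
    sp_fixed = apparent or isinstance(spec.sp_prior, PointMass)

    z = {"pi": _init_prevalence_logit(data.y, data.n, rng, C)}
    z["se"] = (np.full(C, logit(np.clip(spec.se_prior.value, 1e-12, 1 - 1e-12)))
               if (not apparent and se_fixed)
               else (_init_logit(spec.se_prior, rng, C) if not apparent else None))
    z["sp"] = (np.full(C, logit(np.clip(spec.sp_prior.value, 1e-12, 1 - 1e-12)))
               if (not apparent and sp_fixed)
               else (_init_logit(spec.sp_prior, rng, C) if not apparent else None))
    if mix:
        z["w"] = _init_logit(spec.w_prior, rng, C)

    def loglik(zz):
        pi = expit(zz["pi"])
        if apparent:
            p1 = pi
            l0 = 0.0 if y == 0 else -np.inf
        else:
            se, sp = expit(zz["se"]), expit(zz["sp"])
            p1 = pi * se + (1.0 - pi) * (1.0 - sp)
            l0 = coef + y * np.log1p(-sp) + (n - y) * np.log(sp) if mix else None
        l1 = coef + y * np.log(p1) + (n - y) * np.log1p(-p1)
        if not mix:
            return l1
        w = expit(zz["w"])
        return _mix(l1, np.broadcast_to(l0, l1.shape), np.log(w), np.log1p(-w))

    blocks = [("pi", spec.prevalence_prior)]
    if not apparent and not se_fixed:
        blocks.append(("se", spec.se_prior))
    if not apparent and not sp_fixed:
        blocks.append(("sp", spec.sp_prior))
    if mix:
        blocks.append(("w", spec.w_prior))

    adapter = _Adapter({k: (C,) for k, _ in blocks})
    cur_ll = loglik(z)
    cur_lp = {k: _beta_lp_logit(z[k], pr) for k, pr in blocks}

    n_keep = cfg.draws_per_chain
    out = {k: np.empty((C, n_keep)) for k, _ in blocks}
    j = 0
    for it in range(cfg.iterations):
        for k, pr in blocks:
            prop = z[k] + adapter.step[k] * rng.standard_normal(C)
            trial = dict(z)
            trial[k] = prop
            new_ll = loglik(trial)
            new_lp = _beta_lp_logit(prop, pr)
            accept = np.log(rng.random(C)) < new_ll + new_lp - cur_ll - cur_lp[k]
            z[k] = np.where(accept, prop, z[k])
            cur_ll = np.where(accept, new_ll, cur_ll)
            cur_lp[k] = np.where(accept, new_lp, cur_lp[k])
            adapter.acc[k] += accept
        adapter.update(it, cfg.burn_in)
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            for k, _ in blocks:
                out[k][:, j] = expit(z[k])
            j += 1

    name_map = {"pi": "pi_a" if apparent else "pi_t", "se": "se", "sp": "sp", "w": "w"}
    params = {name_map[k]: v for k, v in out.items()}
    if not apparent and se_fixed:
        params["se"] = np.full((C, n_keep), spec.se_prior.value)
    if not apparent and sp_fixed:
        params["sp"] = np.full((C, n_keep), spec.sp_prior.value)
    if mix:
        params["pi_star"] = _pi_star_single(spec, data, params, cfg)
    return params


def _pi_star_single(spec, data, params, cfg) -> np.ndarray:
    """Mixture prevalence draws: indicator sampled from its exact conditional."""
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x5A)))
    y, n = float(data.y), float(data.n)
    coef = _binom_coef(y, n)
    pi = params["pi_a" if spec.family == "apparent_single" else "pi_t"]
    w = params["w"]
    if spec.family == "apparent_single":
        p1 = pi
        l0 = 0.0 if y == 0 else -np.inf
    else:
        se, sp = params["se"], params["sp"]
        p1 = rogan_gladen(pi, se, sp)
        l0 = coef + y * np.log1p(-sp) + (n - y) * np.log(sp)
    l1 = coef + y * np.log(p1) + (n - y) * np.log1p(-p1)
    log_odds = np.log(w) - np.log1p(-w) + l1 - l0
    p_infected = expit(log_odds)
    zind = rng.random(pi.shape) < p_infected
    return np.where(zind, pi, 0.0)


def _sample_multi(spec: ModelSpec, data: ClusterTable, cfg: MCMCConfig):
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    C, k = cfg.chains, data.k
    y = data.y.astype(float)
    n = data.n.astype(float)
    coef = _binom_coef(y, n)
    mu_prior, psi_prior = spec.prevalence_prior
    se_fixed = isinstance(spec.se_prior, PointMass)
    sp_fixed = isinstance(spec.sp_prior, PointMass)
    mix = spec.zero_inflated
    w_cluster = mix and spec.w_mode == "cluster"

    # overdispersed starts: hyperparameters and accuracies from their
    # priors, cluster prevalences data-informed (see _init_prevalence_logit)
    mu0 = np.clip(mu_prior.rvs(rng, C), 1e-4, 1 - 1e-4)
    psi0 = np.clip(psi_prior.rvs(rng, C), 1e-3, 1e6)
    z = {
        "pi": _init_prevalence_logit(y[None, :], n[None, :], rng, (C, k)),
        "mu": logit(mu0),
        "psi": np.log(psi0),
        "se": _init_logit(spec.se_prior, rng, C),
        "sp": _init_logit(spec.sp_prior, rng, C),
    }
    if mix:
        z["w"] = _init_logit(spec.w_prior, rng, (C, k) if w_cluster else C)

    def per_cluster_ll(zpi, zse, zsp, zw):
        """(C, k) per-cluster marginal log-likelihood terms."""
        pi = expit(zpi)
        se = expit(zse)[:, None]
        sp = expit(zsp)[:, None]
        p1 = pi * se + (1.0 - pi) * (1.0 - sp)
        l1 = coef + y * np.log(p1) + (n - y) * np.log1p(-p1)
        if not mix:
            return l1
        l0 = coef + y * np.log1p(-sp) + (n - y) * np.log(sp)
        w = expit(zw) if w_cluster else expit(zw)[:, None]
        return _mix(l1, l0, np.log(w), np.log1p(-np.asarray(w)))

    def hier_lp(zpi, zmu, zpsi):
        pi = expit(zpi)
        mu = expit(zmu)[:, None]
        psi = np.exp(zpsi)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            return (beta_logpdf(pi, mu * psi, psi * (1.0 - mu))
                    + np.log(pi) + np.log1p(-pi))

    cur_ll = per_cluster_ll(z["pi"], z["se"], z["sp"], z.get("w"))
    cur_hier = hier_lp(z["pi"], z["mu"], z["psi"])

    shapes = {"pi": (C, k), "mu": (C,), "psi": (C,)}
    if not se_fixed:
        shapes["se"] = (C,)
    if not sp_fixed:
        shapes["sp"] = (C,)
    if mix:
        shapes["w"] = (C, k) if w_cluster else (C,)
    adapter = _Adapter(shapes)

    n_keep = cfg.draws_per_chain
    out = {"pi": np.empty((C, k, n_keep)), "mu": np.empty((C, n_keep)),
           "psi": np.empty((C, n_keep)), "se": np.empty((C, n_keep)),
           "sp": np.empty((C, n_keep))}
    if mix:
        out["w"] = np.empty((C, k, n_keep)) if w_cluster else np.empty((C, n_keep))
    j = 0
    for it in range(cfg.iterations):
        # cluster prevalences: independent accept/reject per cluster
        prop = z["pi"] + adapter.step["pi"] * rng.standard_normal((C, k))
        new_ll = per_cluster_ll(prop, z["se"], z["sp"], z.get("w"))
        new_hier = hier_lp(prop, z["mu"], z["psi"])
        accept = np.log(rng.random((C, k))) < new_ll + new_hier - cur_ll - cur_hier
        z["pi"] = np.where(accept, prop, z["pi"])
        cur_ll = np.where(accept, new_ll, cur_ll)
        cur_hier = np.where(accept, new_hier, cur_hier)
        adapter.acc["pi"] += accept

        for name, prior in (("se", spec.se_prior), ("sp", spec.sp_prior)):
            if name not in shapes:
                continue
            prop = z[name] + adapter.step[name] * rng.standard_normal(C)
            trial = dict(z)
            trial[name] = prop
            new_ll = per_cluster_ll(trial["pi"], trial["se"], trial["sp"], trial.get("w"))
            logr = ((new_ll - cur_ll).sum(axis=1)
                    + _beta_lp_logit(prop, prior) - _beta_lp_logit(z[name], prior))
            accept = np.log(rng.random(C)) < logr
            z[name] = np.where(accept, prop, z[name])
            cur_ll = np.where(accept[:, None], new_ll, cur_ll)
            adapter.acc[name] += accept

        prop = z["mu"] + adapter.step["mu"] * rng.standard_normal(C)
        new_hier = hier_lp(z["pi"], prop, z["psi"])
        logr = ((new_hier - cur_hier).sum(axis=1)
                + _beta_lp_logit(prop, mu_prior) - _beta_lp_logit(z["mu"], mu_prior))
        accept = np.log(rng.random(C)) < logr
        z["mu"] = np.where(accept, prop, z["mu"])
        cur_hier = np.where(accept[:, None], new_hier, cur_hier)
        adapter.acc["mu"] += accept

        prop = z["psi"] + adapter.step["psi"] * rng.standard_normal(C)
        new_hier = hier_lp(z["pi"], z["mu"], prop)
        logr = ((new_hier - cur_hier).sum(axis=1)
                + _gamma_lp_log(prop, psi_prior.shape, psi_prior.rate)
                - _gamma_lp_log(z["psi"], psi_prior.shape, psi_prior.rate))
        accept = np.log(rng.random(C)) < logr
        z["psi"] = np.where(accept, prop, z["psi"])
        cur_hier = np.where(accept[:, None], new_hier, cur_hier)
        adapter.acc["psi"] += accept

        if mix:
            prop = z["w"] + adapter.step["w"] * rng.standard_normal(shapes["w"])
            trial = dict(z)
            trial["w"] = prop
            new_ll = per_cluster_ll(z["pi"], z["se"], z["sp"], prop)
            if w_cluster:
                accept = (np.log(rng.random((C, k)))
                          < new_ll - cur_ll + _beta_lp_logit(prop, spec.w_prior)
                          - _beta_lp_logit(z["w"], spec.w_prior))
                z["w"] = np.where(accept, prop, z["w"])
                cur_ll = np.where(accept, new_ll, cur_ll)
            else:
                logr = ((new_ll - cur_ll).sum(axis=1)
                        + _beta_lp_logit(prop, spec.w_prior)
                        - _beta_lp_logit(z["w"], spec.w_prior))
                accept = np.log(rng.random(C)) < logr
                z["w"] = np.where(accept, prop, z["w"])
                cur_ll = np.where(accept[:, None], new_ll, cur_ll)
            adapter.acc["w"] += accept

        adapter.update(it, cfg.burn_in)
        if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0:
            out["pi"][:, :, j] = expit(z["pi"])
            out["mu"][:, j] = expit(z["mu"])
            out["psi"][:, j] = np.exp(z["psi"])
            out["se"][:, j] = expit(z["se"])
            out["sp"][:, j] = expit(z["sp"])
            if mix:
                out["w"][..., j] = expit(z["w"])
            j += 1

    labels = data.labels
    params = {"mu": out["mu"], "psi": out["psi"],
              "se": np.full((C, n_keep), spec.se_prior.value) if se_fixed else out["se"],
              "sp": np.full((C, n_keep), spec.sp_prior.value) if sp_fixed else out["sp"]}
    for i, lab in enumerate(labels):
        params[f"pi_t[{lab}]"] = out["pi"][:, i, :]
    if mix:
        if w_cluster:
            for i, lab in enumerate(labels):
                params[f"w[{lab}]"] = out["w"][:, i, :]
        else:
            params["w"] = out["w"]
        _pi_star_multi(spec, data, params, out, cfg)
    return params, labels


def _pi_star_multi(spec, data, params, out, cfg) -> None:
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0x5A)))
    y = data.y.astype(float)[None, :, None]
    n = data.n.astype(float)[None, :, None]
    coef = _binom_coef(y, n)
    pi = out["pi"]
    se = params["se"][:, None, :]
    sp = params["sp"][:, None, :]
    w = out["w"] if spec.w_mode == "cluster" else params["w"][:, None, :]
    p1 = rogan_gladen(pi, se, sp)
    l1 = coef + y * np.log(p1) + (n - y) * np.log1p(-p1)
    l0 = coef + y * np.log1p(-sp) + (n - y) * np.log(sp)
    p_inf = expit(np.log(w) - np.log1p(-np.asarray(w)) + l1 - l0)
    zind = rng.random(pi.shape) < p_inf
    pi_star = np.where(zind, pi, 0.0)
    for i, lab in enumerate(data.labels):
        params[f"pi_star[{lab}]"] = pi_star[:, i, :]


# ---------------------------------------------------------------------------
# posterior summaries


def summarize(samples: PosteriorSamples, level: float = 0.95) -> pd.DataFrame:
    """Pooled-chain mean, median and central credible interval per parameter.

    Returns a DataFrame indexed by parameter name with columns
    ``mean``, ``median``, ``q_lo``, ``q_hi`` (the (1-level)/2 and
    1-(1-level)/2 empirical quantiles, median-unbiased convention).
    """
    if not 0 < level < 1:
        raise ValueError(f"level must lie in (0,1), got {level}")
    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    rows = {}
    for name in samples.names:
        x = samples.pooled(name)
        q = np.quantile(x, [lo, 0.5, hi], method=QUANTILE_METHOD)
        rows[name] = {"mean": x.mean(), "median": q[1], "q_lo": q[0], "q_hi": q[2]}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "parameter"
    df.attrs["level"] = level
    return df


def prob_exceeds(samples: PosteriorSamples, parameter: str, threshold: float) -> float:
    """Posterior probability that a parameter strictly exceeds a threshold."""
    return float(np.mean(samples.pooled(parameter) > threshold))


def freedom_summaries(samples: PosteriorSamples, level: float = 0.95,
                      threshold: float = 0.02) -> dict:
    """Freedom-from-disease summaries for a hierarchical fit.

    Returns a dict with:

    ``clusters``
        per-cluster posterior summaries of the group prevalences
        (``pi_star`` draws when zero-inflated, else ``pi_t``);
    ``distribution_params``
        pooled draws of the fitted prevalence-distribution shape pair
        ``(mu*psi, psi*(1-mu))``;
    ``mu``
        posterior summary of the mean group prevalence;
    ``p_all_below``
        posterior probability that every sampled cluster's prevalence
        is below ``threshold``;
    ``p_region_free``
        (zero-inflated fits only) posterior probability that every
        sampled cluster is disease-free (all indicators zero);
    ``p_predictive_below``
        probability that a new, unsampled group's prevalence falls
        below ``threshold``, from one posterior-predictive draw of
        Beta(mu*psi, psi*(1-mu)) per retained draw (times the
        infection indicator when zero-inflated).
    """
    if samples.spec is None or samples.spec.family != "true_multi":
        raise ValueError("freedom summaries require a hierarchical (true_multi) fit")
    if not 0 < threshold <= 1:
        raise ValueError(f"threshold must lie in (0,1], got {threshold}")
    spec = samples.spec
    labels = samples.cluster_labels
    mix = spec.zero_inflated
    key = "pi_star" if mix else "pi_t"
    cluster_draws = np.stack([samples.get(f"{key}[{lab}]") for lab in labels])  # (k, C, D)

    lo, hi = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for lab, d in zip(labels, cluster_draws):
        x = d.reshape(-1)
        q = np.quantile(x, [lo, 0.5, hi], method=QUANTILE_METHOD)
        rows.append({"cluster": lab, "mean": x.mean(), "median": q[1],
                     "q_lo": q[0], "q_hi": q[2]})
    clusters = pd.DataFrame(rows).set_index("cluster")

    mu = samples.pooled("mu")
    psi = samples.pooled("psi")
    q = np.quantile(mu, [lo, 0.5, hi], method=QUANTILE_METHOD)
    mu_summary = {"mean": mu.mean(), "median": q[1], "q_lo": q[0], "q_hi": q[2]}

    flat = cluster_draws.reshape(cluster_draws.shape[0], -1)
    p_all_below = float(np.mean(np.all(flat < threshold, axis=0)))

    seed = samples.config.seed if samples.config is not None else 0
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xF0)))
    predictive = rng.beta(mu * psi, psi * (1.0 - mu))
    result = {
        "clusters": clusters,
        "distribution_params": (mu * psi, psi * (1.0 - mu)),
        "mu": mu_summary,
        "p_all_below": p_all_below,
        "threshold": threshold,
    }
    if mix:
        result["p_region_free"] = float(np.mean(np.all(flat == 0.0, axis=0)))
        if spec.w_mode == "shared":
            w = samples.pooled("w")
        else:
            w = np.mean([samples.pooled(f"w[{lab}]") for lab in labels], axis=0)
        predictive = np.where(rng.random(predictive.shape) < w, predictive, 0.0)
    result["p_predictive_below"] = float(np.mean(predictive < threshold))
    return result
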