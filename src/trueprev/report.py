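"""Run reports and plain-text export.

A completed fit is exported as three open artifacts in a directory:

``input.csv``
    echo of the data actually analysed (one row per population);
``model.json``
    the full model specification — family, every prior with its
    hyperparameters and summary, zero-inflation settings — plus the
    MCMC configuration, sufficient to re-run the fit exactly;
``draws.csv``
    the raw retained draws, one row per draw with chain and iteration
    columns.

Every number in a report is recomputable from these files alone:
re-loading ``draws.csv`` and re-summarizing reproduces the summary
table exactly, and re-fitting from ``model.json`` + ``input.csv`` with
the recorded seed reproduces the draws bit for bit.  Rendered figures
are deliberately out of scope; the plot-backing tables (densities,
autocorrelations, running means, box-plot statistics) are all exported
so any plotting layer can draw them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data import ClusterTable, SurveyCounts, read_cluster_table  # noqa: F401 (re-export)
from .diagnostics import DiagnosticsBundle, compute_diagnostics
from .inference import MCMCConfig, PosteriorSamples, run_mcmc, summarize
from .models import ModelSpec
from .priors import BetaPrior, GammaPrior, PointMass, summarize_prior

__all__ = [
    "ReportBundle",
    "build_report",
    "cluster_boxplot_stats",
    "export_run",
    "load_run",
]


def cluster_boxplot_stats(samples: PosteriorSamples, cluster: str) -> dict:
    """Five-number box-plot summary of one cluster's prevalence draws.

    Whiskers follow the Tukey convention: the most extreme draws within
    1.5 IQR of the quartiles.
    """
    key = f"pi_t[{cluster}]"
    if key not in samples.params:
        raise KeyError(f"unknown cluster {cluster!r}")
    x = samples.pooled(key)
    q25, med, q75 = np.quantile(x, [0.25, 0.5, 0.75], method="median_unbiased")
    iqr = q75 - q25
    lo_candidates = x[x >= q25 - 1.5 * iqr]
    hi_candidates = x[x <= q75 + 1.5 * iqr]
    return {
        "whisker_low": float(lo_candidates.min()),
        "q25": float(q25),
        "median": float(med),
        "q75": float(q75),
        "whisker_high": float(hi_candidates.max()),
    }


@dataclass
class ReportBundle:
    """Everything the report page shows, plus the raw draws behind it."""

    spec: ModelSpec
    config: MCMCConfig
    data: SurveyCounts | ClusterTable
    prior_summaries: dict
    samples: PosteriorSamples
    posterior_summary: pd.DataFrame
    cluster_stats: dict | None
    threshold_probabilities: dict
    diagnostics: DiagnosticsBundle


def _prior_summaries(spec: ModelSpec) -> dict:
    out = {}

    def add(name, prior):
        if prior is None:
            return
        if isinstance(prior, PointMass):
            out[name] = {"prior": prior, "summary": None}
        else:
            out[name] = {"prior": prior, "summary": summarize_prior(prior)}

    if spec.family == "true_multi":
        add("mu", spec.prevalence_prior[0])
        add("psi", spec.prevalence_prior[1])
    else:
        add("pi_a" if spec.family == "apparent_single" else "pi_t", spec.prevalence_prior)
    add("se", spec.se_prior)
    add("sp", spec.sp_prior)
    add("w", spec.w_prior)
    return out


def build_report(spec: ModelSpec, data, config: MCMCConfig = MCMCConfig(),
                 thresholds: dict | None = None, max_lag: int = 50) -> ReportBundle:
    """Fit the model and assemble the full report bundle."""
    samples = run_mcmc(spec, data, config)
    summary = summarize(samples)
    cluster_stats = None
    if spec.family == "true_multi":
        cluster_stats = {lab: cluster_boxplot_stats(samples, lab)
                         for lab in samples.cluster_labels}
    thr = {}
    for param, cut in (thresholds or {}).items():
        thr[param] = float(np.mean(samples.pooled(param) > cut))
    return ReportBundle(
        spec=spec, config=config, data=data,
        prior_summaries=_prior_summaries(spec),
        samples=samples, posterior_summary=summary,
        cluster_stats=cluster_stats, threshold_probabilities=thr,
        diagnostics=compute_diagnostics(samples, max_lag=max_lag),
    )


# ---------------------------------------------------------------------------
# serialization

def _prior_to_json(prior):
    if prior is None:
        return None
    if isinstance(prior, BetaPrior):
        return {"type": "beta", "alpha": prior.alpha, "beta": prior.beta}
    if isinstance(prior, GammaPrior):
        return {"type": "gamma", "shape": prior.shape, "rate": prior.rate}
    if isinstance(prior, PointMass):
        return {"type": "point", "value": prior.value}
    raise TypeError(f"cannot serialize prior {prior!r}")


def _prior_from_json(obj):
    if obj is None:
        return None
    kind = obj["type"]
    if kind == "beta":
        return BetaPrior(obj["alpha"], obj["beta"])
    if kind == "gamma":
        return GammaPrior(obj["shape"], obj["rate"])
    if kind == "point":
        return PointMass(obj["value"])
    raise ValueError(f"unknown prior type {kind!r}")


def _spec_to_json(spec: ModelSpec, config: MCMCConfig) -> dict:
    if spec.family == "true_multi":
        prev = {"mu": _prior_to_json(spec.prevalence_prior[0]),
                "psi": _prior_to_json(spec.prevalence_prior[1])}
    else:
        prev = _prior_to_json(spec.prevalence_prior)
    return {
        "family": spec.family,
        "prevalence_prior": prev,
        "se_prior": _prior_to_json(spec.se_prior),
        "sp_prior": _prior_to_json(spec.sp_prior),
        "zero_inflated": spec.zero_inflated,
        "w_prior": _prior_to_json(spec.w_prior),
        "w_mode": spec.w_mode,
        "mcmc": {"chains": config.chains, "iterations": config.iterations,
                 "burn_in": config.burn_in, "thin": config.thin,
                 "seed": config.seed},
    }


def _spec_from_json(obj) -> tuple[ModelSpec, MCMCConfig]:
    prev = obj["prevalence_prior"]
    if obj["family"] == "true_multi":
        prevalence = (_prior_from_json(prev["mu"]), _prior_from_json(prev["psi"]))
    else:
        prevalence = _prior_from_json(prev)
    spec = ModelSpec(
        family=obj["family"], prevalence_prior=prevalence,
        se_prior=_prior_from_json(obj["se_prior"]),
        sp_prior=_prior_from_json(obj["sp_prior"]),
        zero_inflated=obj["zero_inflated"],
        w_prior=_prior_from_json(obj["w_prior"]),
        w_mode=obj.get("w_mode", "shared"),
    )
    cfg = MCMCConfig(**obj["mcmc"])
    return spec, cfg


def export_run(bundle: ReportBundle, directory: str | Path) -> dict[str, Path]:
    """Write the input/model/output artifacts; returns the paths written."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}

    if isinstance(bundle.data, ClusterTable):
        input_df = bundle.data.to_frame()
    else:
        input_df = pd.DataFrame({"positive": [bundle.data.y], "n": [bundle.data.n]})
    paths["input"] = directory / "input.csv"
    input_df.to_csv(paths["input"], index=False)

    paths["model"] = directory / "model.json"
    paths["model"].write_text(
        json.dumps(_spec_to_json(bundle.spec, bundle.config), indent=2) + "\n"
    )

    paths["draws"] = directory / "draws.csv"
    bundle.samples.to_frame().to_csv(paths["draws"], index=False, float_format="%.17g")

    paths["summary"] = directory / "summary.csv"
    bundle.posterior_summary.to_csv(paths["summary"])

    diag = bundle.diagnostics.table()
    paths["diagnostics"] = directory / "diagnostics.csv"
    diag.to_csv(paths["diagnostics"])

    if bundle.cluster_stats is not None:
        paths["boxplots"] = directory / "cluster_boxplots.csv"
        pd.DataFrame(bundle.cluster_stats).T.rename_axis("cluster").to_csv(paths["boxplots"])
    return paths


def load_run(directory: str | Path):
    """Re-load an exported run: (spec, config, data, samples).

    The returned samples are reconstructed from ``draws.csv``;
    summarizing them reproduces the exported summary table exactly.
    """
    directory = Path(directory)
    spec, cfg = _spec_from_json(json.loads((directory / "model.json").read_text()))
    input_df = pd.read_csv(directory / "input.csv")
    if spec.family == "true_multi":
        data = ClusterTable.from_frame(
            input_df[["label", "positive", "n"]].rename(columns={"label": "study"})
            if "label" in input_df.columns else input_df
        )
    else:
        data = SurveyCounts(y=int(input_df["positive"][0]), n=int(input_df["n"][0]))
    samples = PosteriorSamples.from_frame(
        pd.read_csv(directory / "draws.csv", float_precision="round_trip")
    )
    samples.spec = spec
    samples.config = cfg
    samples.data = data
    if spec.family == "true_multi":
        samples.cluster_labels = data.labels
    return spec, cfg, data, samples
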