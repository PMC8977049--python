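"""MCMC convergence diagnostics.

These are the quantities behind the usual convergence report for a
multi-chain run: effective sample size (initial-positive-sequence
autocovariance estimator), a between/within-chain shrink factor
(potential scale reduction on split chains), autocorrelation series,
running (ergodic) means, and kernel-density tables for full versus
partial chains.  All of them are pure functions of the retained draws,
so a report can be regenerated exactly from exported samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .inference import PosteriorSamples

__all__ = [
    "effective_sample_size",
    "shrink_factor",
    "autocorrelation_series",
    "running_mean_series",
    "density_table",
    "DiagnosticsBundle",
    "compute_diagnostics",
]

_DENSITY_GRID = 512


def _chain_matrix(samples: PosteriorSamples | np.ndarray, parameter: str | None) -> np.ndarray:
    if isinstance(samples, PosteriorSamples):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorSamples input")
        x = samples.get(parameter)
    else:
        x = np.asarray(samples, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected draws shaped (chains, iterations)")
    return np.asarray(x, dtype=float)


def _acf_1d(x: np.ndarray, max_lag: int) -> np.ndarray:
    """Sample autocorrelations for lags 0..max_lag (FFT autocovariance)."""
    n = x.size
    xc = x - x.mean()
    var = xc @ xc / n
    if var <= 0:
        return np.concatenate([[1.0], np.zeros(max_lag)])
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[: max_lag + 1] / n
    return acov / acov[0]


def effective_sample_size(samples, parameter: str | None = None) -> float:
    """Effective sample size, summed across chains.

    Per chain the autocorrelation time is estimated with the
    initial-positive-sequence rule: successive pairs of autocorrelations
    are summed and accumulation stops at the first negative pair.  A
    (near-)constant chain contributes the estimator floor of 1.
    """
    x = _chain_matrix(samples, parameter)
    n = x.shape[1]
    if x.shape[0] < 2 or n < 100:
        raise ValueError("ESS needs >= 2 chains and >= 100 draws per chain")
    max_lag = n - 2
    total = 0.0
    for chain in x:
        if np.var(chain) <= 1e-300:
            total += 1.0
            continue
        acf = _acf_1d(chain, min(max_lag, n - 1))
        s = 0.0
        for m in range(0, (len(acf) - 1) // 2):
            pair = acf[2 * m] + acf[2 * m + 1]
            if pair <= 0:
                break
            s += pair
        tau = max(2.0 * s - 1.0, 1.0)
        total += n / tau
    return float(min(total, x.size))


def shrink_factor(samples, parameter: str | None = None) -> float:
    """Potential scale reduction on split chains.

    Each chain is halved, giving 2C sequences; the statistic compares
    between-sequence to within-sequence variance and approaches 1 at
    convergence.  Splitting also exposes within-chain drift (a complete
    versus partial chain comparison).
    """
    x = _chain_matrix(samples, parameter)
    if x.shape[0] < 2:
        raise ValueError("shrink factor needs >= 2 chains")
    n = x.shape[1]
    if n < 4:
        raise ValueError("shrink factor needs >= 4 draws per chain")
    half = n // 2
    seqs = np.concatenate([x[:, :half], x[:, half: 2 * half]], axis=0)
    m, n2 = seqs.shape
    means = seqs.mean(axis=1)
    variances = seqs.var(axis=1, ddof=1)
    w = variances.mean()
    b = n2 * means.var(ddof=1)
    if w <= 1e-300:
        return 1.0 if b <= 1e-300 else np.inf
    var_plus = (n2 - 1) / n2 * w + b / n2
    return float(np.sqrt(var_plus / w))


def autocorrelation_series(samples, parameter: str | None = None,
                           max_lag: int = 50) -> pd.DataFrame:
    """Per-lag sample autocorrelations, averaged across chains.

    Lag 0 is 1 by definition.  Chains with (numerically) zero variance
    are flagged degenerate and contribute zeros at positive lags rather
    than NaNs, keeping report generation total.
    """
    x = _chain_matrix(samples, parameter)
    n = x.shape[1]
    if max_lag >= n:
        raise ValueError(f"max_lag must be < draws per chain ({n})")
    rows = []
    degenerate = False
    for chain in x:
        if np.var(chain) <= 1e-300:
            degenerate = True
            rows.append(np.concatenate([[1.0], np.zeros(max_lag)]))
        else:
            rows.append(_acf_1d(chain, max_lag))
    df = pd.DataFrame({"lag": np.arange(max_lag + 1),
                       "autocorrelation": np.mean(rows, axis=0)})
    df.attrs["degenerate"] = degenerate
    return df


def running_mean_series(samples, parameter: str | None = None) -> np.ndarray:
    """Cumulative (ergodic) mean per chain at each retained iteration."""
    x = _chain_matrix(samples, parameter)
    return np.cumsum(x, axis=1) / np.arange(1, x.shape[1] + 1)


def density_table(draws: np.ndarray, grid_size: int = _DENSITY_GRID) -> pd.DataFrame:
    """Gaussian-kernel density on a fixed grid (rule-of-thumb bandwidth).

    The bandwidth is Silverman's rule on the pooled draws; a degenerate
    (zero-spread) sample gets a single point mass column instead.
    Returned columns: ``x`` and ``density``.
    """
    x = np.asarray(draws, dtype=float).reshape(-1)
    n = x.size
    sd = x.std()
    iqr = np.subtract(*np.quantile(x, [0.75, 0.25]))
    scale = min(sd, iqr / 1.349) if iqr > 0 else sd
    if scale <= 1e-12 * max(1.0, abs(x.mean())):  # numerically constant sample
        return pd.DataFrame({"x": [x[0]], "density": [np.inf]})
    bw = 0.9 * scale * n ** (-0.2)
    lo, hi = x.min() - 3 * bw, x.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_size)
    # chunked kernel sum keeps memory bounded for long chains
    dens = np.zeros(grid_size)
    for start in range(0, n, 65536):
        block = x[start: start + 65536]
        u = (grid[:, None] - block[None, :]) / bw
        dens += np.exp(-0.5 * u * u).sum(axis=1)
    dens /= n * bw * np.sqrt(2 * np.pi)
    return pd.DataFrame({"x": grid, "density": dens})


@dataclass
class ParameterDiagnostics:
    ess: float
    shrink: float
    autocorrelation: pd.DataFrame
    running_mean: np.ndarray
    density_full: list[pd.DataFrame]
    density_half: list[pd.DataFrame]


@dataclass
class DiagnosticsBundle:
    """Per-parameter convergence diagnostics for one fit."""

    parameters: dict[str, ParameterDiagnostics]

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {name: {"ess": d.ess, "shrink_factor": d.shrink}
             for name, d in self.parameters.items()}
        ).T
        df.index.name = "parameter"
        return df


def compute_diagnostics(samples: PosteriorSamples, max_lag: int = 50) -> DiagnosticsBundle:
    """Diagnostics for every parameter of a fit.

    Density tables are produced per chain for the full chain and for
    its second half, so coinciding full/partial densities can be checked
    numerically or replotted by any graphics layer.
    """
    out = {}
    for name in samples.names:
        x = samples.get(name)
        n = x.shape[1]
        out[name] = ParameterDiagnostics(
            ess=effective_sample_size(x) if n >= 100 else float("nan"),
            shrink=shrink_factor(x),
            autocorrelation=autocorrelation_series(x, max_lag=min(max_lag, n - 1)),
            running_mean=running_mean_series(x),
            density_full=[density_table(chain) for chain in x],
            density_half=[density_table(chain[n // 2:]) for chain in x],
        )
    return DiagnosticsBundle(parameters=out)
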