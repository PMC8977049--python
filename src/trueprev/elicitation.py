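"""Percentile-based prior elicitation.

Experts rarely think in terms of Beta or Gamma hyperparameters.  They
can, however, state a central tendency ("the mean sensitivity is 0.8")
together with a tail-probability bound ("with probability 0.97 it
exceeds 0.75").  The routines here convert such statements into
hyperparameters by deterministic root-solving on the concentration of
the distribution.

For a mean statement the Beta family is parameterized as
``Beta(m*t, (1-m)*t)`` with ``t`` the concentration (``alpha + beta``);
the tail probability is monotone in ``t``, so a scalar bracketed solve
recovers the unique solution when one exists.  Median and mode
statements are handled analogously (the mode via the closed form
``alpha = 1 + m*(t-2)``, the median via a nested scalar solve).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import optimize, stats

from .priors import BetaPrior, GammaPrior

__all__ = [
    "ElicitationStatement",
    "ElicitationError",
    "elicit_beta",
    "elicit_gamma",
    "elicit_hierarchical",
]

_LOG_T_LO, _LOG_T_HI = np.log(1e-6), np.log(1e8)


class ElicitationError(ValueError):
    """No prior satisfies the stated constraints (or they are degenerate)."""


@dataclass(frozen=True)
class ElicitationStatement:
    """An expert belief about a probability-scale quantity.

    ``central_measure``/``central_value`` pin the location (mean, median
    or mode equal to ``central_value``) and the triple
    (``bound_value``, ``bound_prob``, ``direction``) states that with
    probability ``bound_prob`` the quantity is above (``greater``) or
    below (``less``) ``bound_value``.
    """

    central_measure: Literal["mean", "median", "mode"]
    central_value: float
    bound_value: float
    bound_prob: float
    direction: Literal["greater", "less"] = "greater"

    def __post_init__(self) -> None:
        if self.central_measure not in ("mean", "median", "mode"):
            raise ElicitationError(f"unknown central measure {self.central_measure!r}")
        if self.direction not in ("greater", "less"):
            raise ElicitationError(f"unknown direction {self.direction!r}")
        for name in ("central_value", "bound_value", "bound_prob"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ElicitationError(f"{name} must lie strictly in (0, 1), got {v}")


def _tail(a: float, b: float, stmt: ElicitationStatement) -> float:
    if stmt.direction == "greater":
        return stats.beta.sf(stmt.bound_value, a, b)
    return stats.beta.cdf(stmt.bound_value, a, b)


def _shape_for(t: float, stmt: ElicitationStatement) -> tuple[float, float]:
    """Shape pair with concentration t whose central measure equals the statement's."""
    m = stmt.central_value
    if stmt.central_measure == "mean":
        return m * t, (1.0 - m) * t
    if stmt.central_measure == "mode":
        # mode = (a-1)/(t-2) requires a,b > 1, i.e. t > 2
        return 1.0 + m * (t - 2.0), 1.0 + (1.0 - m) * (t - 2.0)

    # median: alpha solving median(a, t-a) = m; median is increasing in a
    def g(a: float) -> float:
        return stats.beta.ppf(0.5, a, t - a) - m

    lo, hi = t * 1e-9, t * (1.0 - 1e-9)
    a = optimize.brentq(g, lo, hi, xtol=1e-14)
    return a, t - a


def elicit_beta(stmt: ElicitationStatement) -> BetaPrior:
    """Solve for the Beta prior matching a central measure and a tail bound.

    Returns the unique ``BetaPrior`` whose stated central measure equals
    ``stmt.central_value`` and whose tail probability at
    ``stmt.bound_value`` equals ``stmt.bound_prob`` (both to an absolute
    tolerance of 1e-6).

    Raises
    ------
    ElicitationError
        If the constraints admit no Beta solution, or (for the fully
        symmetric statement mean=bound=prob=1/2) infinitely many.
    """
    t_lo = np.log(2.0 + 1e-9) if stmt.central_measure == "mode" else _LOG_T_LO

    def f(log_t: float) -> float:
        a, b = _shape_for(np.exp(log_t), stmt)
        return _tail(a, b, stmt) - stmt.bound_prob

    f_lo, f_hi = f(t_lo), f(_LOG_T_HI)
    if abs(f_lo) < 1e-9 and abs(f_hi) < 1e-9:
        raise ElicitationError(
            "statement is under-determined: every symmetric Beta satisfies it "
            "(central value, bound value and bound probability all 1/2)"
        )
    if np.sign(f_lo) == np.sign(f_hi):
        raise ElicitationError(
            f"no Beta prior has {stmt.central_measure}={stmt.central_value} and "
            f"P(X {'>' if stmt.direction == 'greater' else '<'} {stmt.bound_value})"
            f"={stmt.bound_prob}; the constraints are inconsistent"
        )
    log_t = optimize.brentq(f, t_lo, _LOG_T_HI, xtol=1e-10, rtol=8.9e-16)
    a, b = _shape_for(np.exp(log_t), stmt)
    prior = BetaPrior(float(a), float(b))
    if abs(_tail(a, b, stmt) - stmt.bound_prob) > 1e-6:
        raise ElicitationError("root-solve failed to reach the 1e-6 tolerance")
    return prior


def elicit_gamma(target_median: float, target_p95_upper: float) -> GammaPrior:
    """Solve for the Gamma prior with a stated median and 95th percentile.

    The ratio q95/q50 of a Gamma distribution depends only on the shape
    and decreases monotonically in it, so the shape is found by a
    bracketed solve on that ratio and the rate then rescales the median
    into place.
    """
    if not (0 < target_median < target_p95_upper):
        raise ElicitationError(
            f"need 0 < median < 95th percentile, got ({target_median}, {target_p95_upper})"
        )
    ratio = target_p95_upper / target_median

    def f(log_shape: float) -> float:
        k = np.exp(log_shape)
        return stats.gamma.ppf(0.95, k) / stats.gamma.ppf(0.5, k) - ratio

    lo, hi = np.log(1e-3), np.log(1e6)
    if np.sign(f(lo)) == np.sign(f(hi)):
        raise ElicitationError("no Gamma prior matches the stated median/95th percentile")
    k = float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)))
    rate = float(stats.gamma.ppf(0.5, k) / target_median)
    prior = GammaPrior(k, rate)
    if abs(prior.quantile(0.5) - target_median) > 1e-6 or abs(
        prior.quantile(0.95) - target_p95_upper
    ) > 1e-6 * max(1.0, target_p95_upper):
        raise ElicitationError("root-solve failed to reach the 1e-6 tolerance")
    return prior


def elicit_hierarchical(
    mu_stmt: ElicitationStatement, psi_median: float, psi_p95: float
) -> tuple[BetaPrior, GammaPrior]:
    """Elicit the (mu, psi) hyper-priors of the hierarchical model.

    ``mu`` (the mean group prevalence) gets a Beta prior from a
    percentile statement; ``psi`` (the concentration, inversely related
    to between-group heterogeneity) gets a Gamma prior from a stated
    median and 95th percentile.
    """
    return elicit_beta(mu_stmt), elicit_gamma(psi_median, psi_p95)
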