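"""Gamma-distribution matching for the raft hitting-time curve.

The hitting curve t*C*(1-C)**(t-1), with C = |ln(1 - m/n)|/n, has the shape
of a gamma density.  Matching a scaled gamma density

    A * t**(k-1) * exp(-t/theta) / (theta**k * Gamma(k))

against the hitting curve to first order in t relates gamma parameters
(A, k, theta) fitted to empirical hitting-time data back to the compound
constant C, and hence to the density-threshold fraction m/n:

    C  ~=  t**k / (2*A*Gamma(k)*theta**(k+2) + t**k),
    m   =  n * (1 - exp(-n*C)).

For shape k << 1 the factor t**k is ~ 1 and the recovered threshold m is
approximately constant in t, which is what makes the mapping usable on real
data: a single (k, theta) fit yields a single threshold estimate.

(k-1)! is realized as the gamma function Gamma(k) throughout so non-integer
shapes are admitted.  A is treated purely as a proportionality constant; a
negative fitted A is surfaced with a warning, not rejected.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gamma as gamma_function

from .theory import RealizabilityError, success_probability

__all__ = [
    "GammaLink",
    "C_from_threshold",
    "gamma_pdf_scaled",
    "match_first_order",
    "threshold_from_gamma",
    "threshold_vs_time",
    "solve_A",
    "fit_gamma",
]


class FittingError(ValueError):
    """Degenerate or insufficient data for the gamma fit."""


@dataclass(frozen=True)
class GammaLink:
    """Matching symbols: scale constant A, shape k, scale theta, compound C."""

    A: float
    k: float
    theta: float
    C: float

    def __post_init__(self) -> None:
        if self.k <= 0 or self.theta <= 0:
            raise RealizabilityError(
                f"gamma shape and scale must be positive, got k={self.k}, "
                f"theta={self.theta}"
            )


def C_from_threshold(m: int, n: int) -> float:
    """Compound constant C = |ln(1 - m/n)| / n, identical to the theory q."""
    return success_probability(m, n)


def gamma_pdf_scaled(t, A: float, k: float, theta: float):
    """Scaled gamma density A * t**(k-1) * e**(-t/theta) / (theta**k Gamma(k)).

    With A = 1 this is the standard Gamma(k, theta) density and integrates
    to 1; any other A is a pure proportionality factor.
    """
    if k <= 0 or theta <= 0:
        raise RealizabilityError(
            f"gamma shape and scale must be positive, got k={k}, theta={theta}"
        )
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        base = np.where(
            t > 0,
            np.exp((k - 1.0) * np.log(np.where(t > 0, t, 1.0)) - t / theta),
            0.0 if k > 1 else (1.0 if k == 1 else np.inf),
        )
    out = A * base / (theta**k * gamma_function(k))
    return out if out.ndim else float(out)


def _denominator(A: float, k: float, theta: float) -> float:
    return 2.0 * A * gamma_function(k) * theta ** (k + 2.0)


def match_first_order(A: float, k: float, theta: float, t: float | None = None) -> float:
    """Estimate C from gamma parameters by the first-order series matching.

    Returns C = t**k / (2*A*Gamma(k)*theta**(k+2) + t**k); when *t* is
    omitted the small-shape approximation t**k ~ 1 is applied, giving
    C = 1 / (2*A*Gamma(k)*theta**(k+2) + 1).
    """
    if k <= 0 or theta <= 0:
        raise RealizabilityError(
            f"gamma shape and scale must be positive, got k={k}, theta={theta}"
        )
    tk = 1.0 if t is None else float(t) ** k
    denom = _denominator(A, k, theta) + tk
    if denom == 0.0 or not math.isfinite(denom):
        raise FittingError(
            "degenerate gamma parameters: 2*A*Gamma(k)*theta**(k+2) + t**k "
            f"evaluates to {denom}"
        )
    return tk / denom


def threshold_from_gamma(A: float, k: float, theta: float, n: int) -> float:
    """Recover the raft threshold m from fitted gamma parameters.

    Computes C by first-order matching (with t**k ~ 1) and inverts
    C = |ln(1 - m/n)|/n to m = n * (1 - exp(-n*C)).  Returns m as a real;
    callers may round.  The small-shape approximation degrades for k > 0.1,
    which is flagged with a warning.
    """
    if k > 0.1:
        warnings.warn(
            f"k={k} is outside the k << 1 regime; the t**k ~ 1 approximation "
            "behind this mapping may be poor",
            stacklevel=2,
        )
    if A < 0:
        warnings.warn(
            f"negative scale constant A={A}: treated as a pure "
            "proportionality factor, but the matched C will not lie in (0, 1)",
            stacklevel=2,
        )
    C = match_first_order(A, k, theta)
    if not 0.0 < C < 1.0:
        raise RealizabilityError(
            f"matched C={C} outside (0, 1); the gamma parameters are "
            "inconsistent with a realizable threshold fraction"
        )
    return n * (1.0 - math.exp(-n * C))


def threshold_vs_time(t, A: float, k: float, theta: float, n: int):
    """Threshold curve m(t) = n*(1 - exp(-n*C(t))) with the t-dependence kept.

    Exposes the constancy question: for k << 1 the curve is nearly flat in
    t, so the threshold is effectively time-independent.
    """
    t = np.asarray(t, dtype=float)
    tk = t**k
    C = tk / (_denominator(A, k, theta) + tk)
    out = n * (1.0 - np.exp(-n * C))
    return out if out.ndim else float(out)


def solve_A(m: int, n: int, k: float, theta: float) -> float:
    """Scale constant A that makes the matching recover threshold m exactly.

    Inverts the first-order matching (with t**k ~ 1):
    A = (1/C - 1) / (2*Gamma(k)*theta**(k+2)) with C = C_from_threshold(m, n).
    """
    if k <= 0 or theta <= 0:
        raise RealizabilityError(
            f"gamma shape and scale must be positive, got k={k}, theta={theta}"
        )
    C = C_from_threshold(m, n)
    return (1.0 / C - 1.0) / (2.0 * gamma_function(k) * theta ** (k + 2.0))


def fit_gamma(samples, *, n_bins: int = 50) -> dict:
    """Maximum-likelihood gamma fit to uncensored hitting-time samples.

    Fits shape k and scale theta with the location pinned at 0, then
    estimates the proportionality constant A by a least-squares match of the
    empirical density histogram against :func:`gamma_pdf_scaled`.  Reports a
    Kolmogorov-Smirnov statistic (and p-value) of the fitted law.

    Requires at least 20 positive, non-degenerate samples.
    """
    x = np.asarray(samples, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 20:
        raise FittingError(f"need >= 20 uncensored samples, got {x.size}")
    if np.ptp(x) == 0.0:
        raise FittingError("all samples identical; gamma fit is degenerate")
    if np.any(x <= 0):
        raise FittingError("hitting-time samples must be positive")
    k, _, theta = stats.gamma.fit(x, floc=0.0)
    edges = np.histogram_bin_edges(x, bins=n_bins)
    density, _ = np.histogram(x, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    g = gamma_pdf_scaled(centers, 1.0, k, theta)
    denom = float(np.dot(g, g))
    A = float(np.dot(g, density) / denom) if denom > 0 else float("nan")
    if A < 0:
        warnings.warn(f"fitted scale constant A={A} is negative", stacklevel=2)
    ks = stats.kstest(x, "gamma", args=(k, 0.0, theta))
    return {
        "k": float(k),
        "theta": float(theta),
        "A": A,
        "ks_statistic": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "n_samples": int(x.size),
    }
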