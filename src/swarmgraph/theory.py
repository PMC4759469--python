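"""Closed-form hitting-time theory for the raft threshold.

Inside a dense clump of n cells where any pair can interact, edges appear
with per-pair probability c/n.  A threshold of m rafting cells is reachable
("physically realizable") only when the edge intensity satisfies
c >= |ln(1 - m/n)|; with c set minimal, the per-step success probability is

    q = c_min / n = |ln(1 - m/n)| / n,

and the (unnormalized) probability that the raft first appears at discrete
time t is

    P(t) ∝ t * q * (1 - q)**(t - 1),

a lower-bound hitting curve whose shape resembles a gamma distribution.  Its
continuous-time mode is t_mode = -1 / ln(1 - q), which diverges as the clump
size n grows at fixed threshold fraction m/n.

The logarithm always enters through its absolute value: ln(1 - m/n) is
negative for 0 < m < n and a negative edge intensity is meaningless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "TheoryParams",
    "threshold_ok",
    "c_min",
    "success_probability",
    "hitting_pdf",
    "hitting_pdf_general",
    "hitting_cdf",
    "hitting_pdf_derivative",
    "t_mode",
    "sample_hitting_times",
]


class RealizabilityError(ValueError):
    """The requested (m, n, c) combination is not physically realizable."""


@dataclass(frozen=True)
class TheoryParams:
    """Analytical symbols: threshold m, clump size n, edge intensity c.

    q = c/n is the derived per-step success probability.  The literature
    symbols alpha(c) (exponential path-length bound) and epsilon (vertex/edge
    resilience fraction) both correspond to q here.
    """

    m: int
    n: int
    c: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.m <= self.n:
            raise RealizabilityError(f"need 1 <= m <= n, got m={self.m}, n={self.n}")

    @property
    def c_min(self) -> float:
        return c_min(self.m, self.n)

    @property
    def q(self) -> float:
        c = self.c if self.c is not None else self.c_min
        return c / self.n


def _check_ratio(m: int, n: int) -> float:
    if not 1 <= m < n:
        raise RealizabilityError(
            f"need 1 <= m < n (m = n makes the logarithm diverge); got m={m}, n={n}"
        )
    return m / n


def threshold_ok(m: int, n: int, c: float, *, atol: float = 0.0) -> bool:
    """Whether the threshold relation m >= (1 - e^-c) * n holds.

    Holds exactly for c <= c_min(m, n); *atol* admits boundary intensities
    quoted at limited precision (a c rounded up at the 4th decimal overshoots
    the relation by ~n * rounding error).
    """
    if c < 0:
        raise RealizabilityError(f"edge intensity c must be >= 0, got {c}")
    return m >= (1.0 - math.exp(-c)) * n - atol


def c_min(m: int, n: int) -> float:
    """Minimal physically realizable edge intensity |ln(1 - m/n)|."""
    return abs(math.log1p(-_check_ratio(m, n)))


def success_probability(m: int, n: int) -> float:
    """q = c_min / n, the per-step success probability at minimal intensity."""
    q = c_min(m, n) / n
    if not 0.0 < q < 1.0:
        raise RealizabilityError(
            f"q = |ln(1 - m/n)|/n = {q} outside (0, 1): clump size n={n} too "
            "small for the minimal edge intensity to be realizable"
        )
    return q


def hitting_pdf(t, m: int, n: int):
    """Unnormalized hitting curve t * q * (1 - q)**(t-1) at minimal c.

    Proportional to (a lower bound on) the probability that the threshold
    raft first appears at time t; not a normalized density (its total mass
    over t = 1, 2, ... is 1/q).
    """
    q = success_probability(m, n)
    t = np.asarray(t, dtype=float)
    out = t * q * (1.0 - q) ** (t - 1.0)
    return out if out.ndim else float(out)


def hitting_pdf_general(t, m: int, n: int, c: float):
    """Hitting curve t * (c/n) * (1 - c/n)**(t-1) at a supplied intensity c.

    Requires c >= c_min(m, n) for realizability and c/n < 1; reduces to
    :func:`hitting_pdf` at c = c_min.
    """
    cm = c_min(m, n)
    if c < cm - 1e-12:
        raise RealizabilityError(
            f"c={c} below the minimal realizable intensity c_min={cm:.6g}"
        )
    q = c / n
    if not q < 1.0:
        raise RealizabilityError(f"c/n = {q} must be < 1")
    t = np.asarray(t, dtype=float)
    out = t * q * (1.0 - q) ** (t - 1.0)
    return out if out.ndim else float(out)


def hitting_cdf(t, m: int, n: int, *, normalized: bool = True):
    """Cumulative hitting curve over integer steps 1..t.

    The partial sum has the closed form (1 - (1-q)^T (1 + qT)) / q; divided
    by the total mass 1/q it is a proper distribution function tending to 1.
    With ``normalized=False`` the raw partial sum is returned (for figure
    reproduction of the unnormalized plateau).
    """
    q = success_probability(m, n)
    t = np.asarray(t, dtype=float)
    tf = np.floor(t)
    partial = (1.0 - (1.0 - q) ** tf * (1.0 + q * tf)) / q
    out = partial * q if normalized else partial
    return out if out.ndim else float(out)


def hitting_pdf_derivative(t, m: int, n: int):
    """d/dt of the hitting curve, treating t as continuous.

    Equals q * (1-q)**(t-1) * (1 + t * ln(1-q)); zero exactly at the mode.
    """
    q = success_probability(m, n)
    t = np.asarray(t, dtype=float)
    out = q * (1.0 - q) ** (t - 1.0) * (1.0 + t * np.log1p(-q))
    return out if out.ndim else float(out)


def t_mode(m: int, n: int) -> float:
    """Continuous-time mode -1 / ln(1 - q) of the hitting curve.

    Coherence: at fixed ratio m/n this grows without bound as n increases
    (q -> 0), i.e. very large clumps take arbitrarily long to raft.
    """
    q = success_probability(m, n)
    denom = math.log1p(-q)
    if denom >= 0:  # pragma: no cover - q in (0,1) guarantees denom < 0
        raise RealizabilityError("log argument must lie in (0, 1)")
    return -1.0 / denom


def sample_hitting_times(
    m: int, n: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw from the normalized hitting law p(t) = t * q^2 * (1-q)**(t-1).

    The normalized law is the distribution of G1 + G2 - 1 for independent
    geometric variables G ~ Geom(q) counted in trials, which is how draws
    are generated (exact, no truncation).
    """
    q = success_probability(m, n)
    return rng.geometric(q, size=size) + rng.geometric(q, size=size) - 1
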