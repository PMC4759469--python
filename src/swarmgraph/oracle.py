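"""Exact small-system references for the Model 1 Markov chain.

For a handful of labelled cells (N <= 5) the degree-capped graph state space
is small enough to enumerate completely, the uniform ordered-pair draw of
Model 1 induces an exactly computable row-stochastic transition matrix
(entries are integer counts over N^2, kept in rational arithmetic), and
hitting-time statistics of the raft property follow from the standard
absorbing-chain linear system.  These exact results serve as ground truth
for the stochastic simulator in tests.

Labelled graphs (not isomorphism classes) are enumerated, because the
simulator acts on labelled vertices; isomorphism-class grouping is a display
concern only.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np

from .graph_core import CellGraph, ConfigurationError

MAX_EXACT_N = 5

State = frozenset  # frozenset of (i, j) edge tuples, i < j


class EnumerationLimitError(ConfigurationError):
    """Raised for state spaces too large to enumerate exactly."""


def _max_degree_ok(edges: tuple[tuple[int, int], ...], n: int) -> bool:
    deg = [0] * n
    for i, j in edges:
        deg[i] += 1
        deg[j] += 1
        if deg[i] > 2 or deg[j] > 2:
            return False
    return True


def enumerate_states(n: int) -> list[State]:
    """All labelled graphs on n vertices with max degree <= 2.

    Brute force over the 2**C(n,2) edge subsets; n is capped at 5 because
    the subset count grows as 2**C(n,2).
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n}")
    if n > MAX_EXACT_N:
        raise EnumerationLimitError(
            f"exact enumeration supports n <= {MAX_EXACT_N} (state count grows "
            f"combinatorially); use the stochastic simulator for n = {n}"
        )
    all_edges = list(combinations(range(n), 2))
    states: list[State] = []
    for mask in range(1 << len(all_edges)):
        subset = tuple(e for b, e in enumerate(all_edges) if mask >> b & 1)
        if _max_degree_ok(subset, n):
            states.append(frozenset(subset))
    return states


def state_giant_size(state: State, n: int) -> int:
    """Largest connected component of one enumerated state."""
    g = CellGraph(n_vertices=n, edges=set(state))
    return g.connected_components().giant_size


def exact_transition_matrix(
    states: list[State], n: int
) -> list[list[Fraction]]:
    """Row-stochastic Model 1 kernel in exact rational arithmetic.

    Entry (s, s') counts the ordered draws (i, j) from the n^2 equiprobable
    draws that transform s into s' under the Model 1 rules, over n^2.  All
    no-op draws (diagonal, existing edge, degree cap) accumulate on the
    diagonal.
    """
    index = {s: a for a, s in enumerate(states)}
    n2 = Fraction(1, n * n)
    matrix = [[Fraction(0)] * len(states) for _ in states]
    for s, row_idx in index.items():
        g = CellGraph(n_vertices=n, edges=set(s))
        row = matrix[row_idx]
        for i in range(n):
            for j in range(n):
                if (
                    i != j
                    and ((i, j) if i < j else (j, i)) not in s
                    and g.degree[i] < 2
                    and g.degree[j] < 2
                ):
                    target = frozenset(s | {(i, j) if i < j else (j, i)})
                    row[index[target]] += n2
                else:
                    row[row_idx] += n2
    return matrix


@dataclass
class ExactChain:
    """Enumerated Model 1 chain with its raft-property absorbing set."""

    n: int
    threshold_m: int
    states: list[State]
    transition_matrix: list[list[Fraction]]
    absorbing: np.ndarray  # boolean mask over states
    start_index: int  # index of the empty graph

    @classmethod
    def build(cls, n: int, threshold_m: int) -> "ExactChain":
        if not 1 <= threshold_m <= n:
            raise ConfigurationError(
                f"threshold m={threshold_m} must lie in [1, {n}] (m > n is "
                "unreachable on n vertices)"
            )
        states = enumerate_states(n)
        matrix = exact_transition_matrix(states, n)
        absorbing = np.array(
            [state_giant_size(s, n) >= threshold_m for s in states]
        )
        start = states.index(frozenset())
        return cls(
            n=n,
            threshold_m=threshold_m,
            states=states,
            transition_matrix=matrix,
            absorbing=absorbing,
            start_index=start,
        )

    def dense(self) -> np.ndarray:
        return np.array(
            [[float(x) for x in row] for row in self.transition_matrix]
        )

    def state_distribution(self, t: int) -> np.ndarray:
        """Exact distribution over states after t steps from the empty graph."""
        P = self.dense()
        dist = np.zeros(len(self.states))
        dist[self.start_index] = 1.0
        for _ in range(t):
            dist = dist @ P
        return dist


def exact_hitting_stats(chain: ExactChain, horizon: int = 200) -> dict:
    """Exact hitting-time statistics of the raft property from empty start.

    Expected hitting time comes from the absorbing-chain system
    (I - Q) x = 1 over transient states (solved in floating point with the
    residual checked); the distribution P(tau = t) for t <= horizon comes
    from forward iteration of the chain restricted so absorbed mass stops
    moving (the property is monotone, so absorbing states are closed).
    """
    absorbing = chain.absorbing
    if absorbing[chain.start_index]:
        dist = np.zeros(horizon + 1)
        dist[0] = 1.0
        return {"expected_tau": 0.0, "tau_distribution": dist, "absorbed_mass": 1.0}
    if not absorbing.any():
        raise ConfigurationError(
            f"property 'giant >= {chain.threshold_m}' is unreachable on "
            f"{chain.n} vertices"
        )
    P = chain.dense()
    transient = np.nonzero(~absorbing)[0]
    Q = P[np.ix_(transient, transient)]
    x = np.linalg.solve(np.eye(len(transient)) - Q, np.ones(len(transient)))
    residual = np.max(
        np.abs((np.eye(len(transient)) - Q) @ x - np.ones(len(transient)))
    )
    if residual > 1e-9:  # pragma: no cover - well-conditioned for n <= 5
        raise RuntimeError(f"absorbing-chain solve residual {residual} too large")
    expected = float(x[np.searchsorted(transient, chain.start_index)])

    # forward iteration: track mass over transient states only
    dist = np.zeros(horizon + 1)
    pt = np.zeros(len(transient))
    pt[np.searchsorted(transient, chain.start_index)] = 1.0
    R = P[np.ix_(transient, np.nonzero(absorbing)[0])]
    for t in range(1, horizon + 1):
        dist[t] = float(pt @ R.sum(axis=1))
        pt = pt @ Q
    return {
        "expected_tau": expected,
        "tau_distribution": dist,
        "absorbed_mass": float(dist.sum()),
    }
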