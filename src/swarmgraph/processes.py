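"""The three stochastic update rules and the trajectory runner.

Model 1 draws one ordered vertex pair (i, j) uniformly from {1..N}^2 per
timestep and attempts a single edge addition.  Model 2 sweeps over every
unordered pair once per timestep, creating each eligible edge independently
with probability P.  Model 3 is a Model 2 sweep followed by a death sweep in
which every cell independently loses all of its contacts with probability
p_D (the vertex slot remains and may reconnect later).

Models 1 and 2 are monotone graph processes (the edge set only grows), so
"some component has >= m cells" is a monotone property and its hitting time
is a well-defined stopping time.  Model 3 is not monotone and is treated as
a purely stochastic simulation.

The Model 2/3 sweep is realized by sampling the Binomial number of successes
among pairs eligible at sweep start and resolving those candidates in
uniformly shuffled order with full rule checks — distributionally identical
to visiting the pairs one by one in shuffled order, and necessary to keep
N = 1000, t_max = 10,000 runs fast.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .graph_core import (
    AddOutcome,
    CellGraph,
    ConfigurationError,
    make_empty_graph,
)
from .observables import Trajectory


class Model(enum.Enum):
    MODEL1 = "model1"
    MODEL2 = "model2"
    MODEL3 = "model3"


@dataclass(frozen=True)
class ProcessConfig:
    """Full specification of one simulation run.

    Parameters
    ----------
    model:
        Which update rule to use.
    n_cells:
        Number of cells N (fixed vertex count).
    p_edge:
        Per-pair contact probability P per sweep (Models 2-3 only).
    p_death:
        Per-cell death probability p_D per timestep (Model 3 only).
    t_max:
        Number of timesteps to simulate; the trajectory has t_max + 1 entries.
    threshold_m:
        Raft threshold m: the component size whose hitting time is reported.
    seed:
        Master seed; per-replicate streams are spawned deterministically.
    replicates:
        Number of independent repeats.
    snapshot_times:
        Times at which the full component-size multiset is recorded.
    """

    model: Model
    n_cells: int
    t_max: int
    threshold_m: int = 1
    p_edge: Optional[float] = None
    p_death: Optional[float] = None
    seed: int = 0
    replicates: int = 1
    snapshot_times: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if isinstance(self.model, str):
            object.__setattr__(self, "model", Model(self.model))
        if self.n_cells < 1:
            raise ConfigurationError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.t_max < 0:
            raise ConfigurationError(f"t_max must be >= 0, got {self.t_max}")
        if not 1 <= self.threshold_m <= self.n_cells:
            raise ConfigurationError(
                f"threshold_m must lie in [1, n_cells], got {self.threshold_m}"
            )
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.model in (Model.MODEL2, Model.MODEL3):
            if self.p_edge is None or not 0.0 <= self.p_edge <= 1.0:
                raise ConfigurationError(
                    f"{self.model.value} requires p_edge in [0, 1], got {self.p_edge}"
                )
        if self.model is Model.MODEL3:
            if self.p_death is None or not 0.0 <= self.p_death <= 1.0:
                raise ConfigurationError(
                    f"model3 requires p_death in [0, 1], got {self.p_death}"
                )

    def replicate_rng(self, replicate: int) -> np.random.Generator:
        """Deterministic per-replicate stream spawned from (seed, replicate).

        Equivalent to child *replicate* of ``SeedSequence(seed).spawn(...)``,
        constructed directly so the cost does not grow with the replicate
        count.
        """
        seq = np.random.SeedSequence(self.seed, spawn_key=(replicate,))
        return np.random.default_rng(seq)


# -- single steps -------------------------------------------------------------


def step_model1(g: CellGraph, rng: np.random.Generator) -> AddOutcome:
    """One Model 1 timestep: a single uniform ordered pair draw, in place.

    Both i and j are drawn uniformly and independently from the N vertices,
    so a specific undirected pair {a, b} is proposed with probability 2/N^2
    and the diagonal draws i = j (probability 1/N) are no-ops.
    """
    i, j = rng.integers(0, g.n_vertices, size=2)
    return g.try_add_edge(int(i), int(j))


def _eligible_pair_count(g: CellGraph) -> tuple[int, list[int]]:
    """Number of addable pairs and the list of vertices with spare degree.

    Eligible pairs are absent edges whose endpoints both have degree < 2:
    C(u, 2) minus the isolated-edge components (the only existing edges with
    both endpoints below the cap).
    """
    open_vertices = [v for v in range(g.n_vertices) if g.degree[v] < 2]
    u = len(open_vertices)
    isolated_edges = sum(
        1 for i, j in g.edges if g.degree[i] == 1 and g.degree[j] == 1
    )
    return u * (u - 1) // 2 - isolated_edges, open_vertices


def _sample_candidate_pairs(
    g: CellGraph,
    k: int,
    n_eligible: int,
    open_vertices: list[int],
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    """Draw k distinct eligible pairs uniformly, in uniform random order."""
    if k <= 0:
        return []
    u = len(open_vertices)
    if k * 3 >= n_eligible:
        # dense regime: materialize all eligible pairs once
        pairs = [
            (a, b)
            for ai, a in enumerate(open_vertices)
            for b in open_vertices[ai + 1 :]
            if ((a, b) if a < b else (b, a)) not in g.edges
        ]
        idx = rng.choice(len(pairs), size=k, replace=False)
        chosen = [pairs[int(t)] for t in idx]
        rng.shuffle(chosen)
        return chosen
    # sparse regime: rejection-sample distinct pairs; i.i.d. uniform proposals
    # make the accepted sequence a uniform ordered k-subset
    chosen = []
    seen: set[tuple[int, int]] = set()
    arr = np.asarray(open_vertices)
    while len(chosen) < k:
        m = max(16, 2 * (k - len(chosen)))
        ii = arr[rng.integers(0, u, size=m)]
        jj = arr[rng.integers(0, u, size=m)]
        for a, b in zip(ii.tolist(), jj.tolist()):
            if a == b:
                continue
            key = (a, b) if a < b else (b, a)
            if key in seen or key in g.edges:
                continue
            seen.add(key)
            chosen.append(key)
            if len(chosen) == k:
                break
    return chosen


def step_model2(g: CellGraph, p_edge: float, rng: np.random.Generator) -> int:
    """One Model 2 timestep: a full sweep over all unordered pairs, in place.

    Each pair eligible at sweep start succeeds a Bernoulli(P) trial
    independently; successes are resolved in uniformly shuffled order with
    the degree cap re-checked, so an edge added earlier in the sweep can
    block a later candidate.  Returns the number of edges added.
    """
    if not 0.0 <= p_edge <= 1.0:
        raise ConfigurationError(f"p_edge must be in [0, 1], got {p_edge}")
    n_eligible, open_vertices = _eligible_pair_count(g)
    if n_eligible == 0 or p_edge == 0.0:
        return 0
    k = int(rng.binomial(n_eligible, p_edge))
    added = 0
    for a, b in _sample_candidate_pairs(g, k, n_eligible, open_vertices, rng):
        if g.try_add_edge(a, b) is AddOutcome.ADDED:
            added += 1
    return added


def step_model3(
    g: CellGraph, p_edge: float, p_death: float, rng: np.random.Generator
) -> tuple[int, int]:
    """One Model 3 timestep: Model 2 sweep, then the death sweep, in place.

    Every cell independently dies with probability p_D; death zeroes its row
    and column of the adjacency matrix (all incident edges removed) but the
    cell keeps its vertex slot and may form new contacts later.  Returns
    (edges added, cells died).
    """
    added = step_model2(g, p_edge, rng)
    if not 0.0 <= p_death <= 1.0:
        raise ConfigurationError(f"p_death must be in [0, 1], got {p_death}")
    died = 0
    if p_death > 0.0:
        deaths = np.nonzero(rng.random(g.n_vertices) < p_death)[0]
        for k in deaths.tolist():
            g.kill_vertex(k)
        died = len(deaths)
    return added, died


# -- trajectory runner ---------------------------------------------------------


class _UnionFind:
    """Incremental giant-component tracker for the monotone models."""

    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.size = [1] * n
        self.giant = 1

    def find(self, x: int) -> int:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        if self.size[ra] < self.size[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        self.size[ra] += self.size[rb]
        if self.size[ra] > self.giant:
            self.giant = self.size[ra]


def _giant_size(g: CellGraph) -> int:
    """Largest component size by traversal (used where edges can disappear)."""
    seen = [False] * g.n_vertices
    giant = 1
    for start in range(g.n_vertices):
        if seen[start] or not g.adjacency[start]:
            seen[start] = True
            continue
        stack = [start]
        seen[start] = True
        s = 0
        while stack:
            v = stack.pop()
            s += 1
            for nb in g.adjacency[v]:
                if not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        giant = max(giant, s)
    return giant


def run_single(
    cfg: ProcessConfig,
    replicate: int = 0,
    *,
    stop_when_saturated: bool = False,
    keep_final_graph: bool = False,
) -> Trajectory:
    """Advance one replicate from the empty graph for t_max steps.

    Observables (edge count, average degree, giant-component size) are
    recorded at every timestep including t = 0.  With *stop_when_saturated*
    (Models 1-2 only) the loop exits once no eligible pair remains; the
    frozen terminal values are padded to t_max so all series keep length
    t_max + 1 — the graph provably cannot change again.
    """
    rng = cfg.replicate_rng(replicate)
    g = make_empty_graph(cfg.n_cells)
    t_max = cfg.t_max
    edge_counts = np.zeros(t_max + 1, dtype=np.int64)
    giant_sizes = np.zeros(t_max + 1, dtype=np.int64)
    giant_sizes[0] = 1
    snapshots: dict[int, "np.ndarray"] = {}
    snap_times = set(cfg.snapshot_times)

    def take_snapshot(t: int) -> None:
        if t in snap_times:
            comp = g.connected_components()
            snapshots[t] = np.array(
                sorted(comp.sizes.elements(), reverse=True), dtype=np.int64
            )

    take_snapshot(0)
    monotone = cfg.model in (Model.MODEL1, Model.MODEL2)
    uf = _UnionFind(cfg.n_cells) if monotone else None
    t_stop = t_max

    if cfg.model is Model.MODEL1:
        n = cfg.n_cells
        check_every = 512
        batch = min(max(t_max, 1), 65536)
        draws = iter(())
        for t in range(1, t_max + 1):
            pair = next(draws, None)
            if pair is None:
                block = rng.integers(0, n, size=(batch, 2))
                draws = iter(block.tolist())
                pair = next(draws)
            i, j = pair
            if g.try_add_edge(i, j) is AddOutcome.ADDED:
                uf.union(i, j)
            edge_counts[t] = g.n_edges
            giant_sizes[t] = uf.giant
            take_snapshot(t)
            if stop_when_saturated and t % check_every == 0:
                if _eligible_pair_count(g)[0] == 0:
                    t_stop = t
                    break
    elif cfg.model is Model.MODEL2:
        for t in range(1, t_max + 1):
            n_eligible, open_vertices = _eligible_pair_count(g)
            if n_eligible == 0:  # frozen forever: pad below
                t_stop = t
                break
            k = int(rng.binomial(n_eligible, cfg.p_edge)) if cfg.p_edge else 0
            for a, b in _sample_candidate_pairs(g, k, n_eligible, open_vertices, rng):
                if g.try_add_edge(a, b) is AddOutcome.ADDED:
                    uf.union(a, b)
            edge_counts[t] = g.n_edges
            giant_sizes[t] = uf.giant
            take_snapshot(t)
    else:  # MODEL3: not monotone; giant recomputed by traversal
        giant_sizes[0] = _giant_size(g)
        for t in range(1, t_max + 1):
            step_model3(g, cfg.p_edge, cfg.p_death, rng)
            edge_counts[t] = g.n_edges
            giant_sizes[t] = _giant_size(g)
            take_snapshot(t)

    if t_stop < t_max:  # saturated early: state is frozen from t_stop on
        edge_counts[t_stop:] = edge_counts[t_stop]
        giant_sizes[t_stop:] = giant_sizes[t_stop]
        for t in snap_times:
            if t > t_stop:
                take_snapshot_frozen = np.array(
                    sorted(g.connected_components().sizes.elements(), reverse=True),
                    dtype=np.int64,
                )
                snapshots[t] = take_snapshot_frozen

    return Trajectory(
        times=np.arange(t_max + 1, dtype=np.int64),
        edge_counts=edge_counts,
        avg_degrees=2.0 * edge_counts / cfg.n_cells,
        giant_sizes=giant_sizes,
        snapshots=snapshots,
        n_cells=cfg.n_cells,
        replicate=replicate,
        final_graph=g if keep_final_graph else None,
        saturated_at=t_stop if t_stop < t_max else None,
    )


def run_process(
    cfg: ProcessConfig, *, stop_when_saturated: bool = False
) -> list[Trajectory]:
    """Run all replicates of *cfg*; bit-reproducible given (seed, replicate)."""
    return [
        run_single(cfg, r, stop_when_saturated=stop_when_saturated)
        for r in range(cfg.replicates)
    ]
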