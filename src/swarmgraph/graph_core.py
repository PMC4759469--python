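"""Degree-capped undirected graph state for chain ("raft") formation models.

Cells are vertices; an edge is a side-by-side cell-cell contact.  Because a
rafting cell can touch at most two neighbours, every vertex carries a hard
degree cap of 2, so every connected component is a simple path or a simple
cycle.  The graph is the state of the discrete-time Markov processes defined
in :mod:`swarmgraph.processes`.

Vertex ids are 0-based internally; all user-facing text output (CLI, edge
lists) is 1-based.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator

#: Maximum number of contacts a cell can maintain (side-by-side rafting).
DEGREE_CAP = 2


class AddOutcome(enum.Enum):
    """Result of attempting to add one edge under the rafting rules."""

    ADDED = "added"
    REJECTED_SELF = "rejected_self"
    REJECTED_EXISTS = "rejected_exists"
    REJECTED_DEGREE = "rejected_degree"


class ConfigurationError(ValueError):
    """Invalid simulation or model configuration."""


@dataclass
class CellGraph:
    """Undirected loop-free graph on a fixed vertex set with degree cap 2.

    Parameters
    ----------
    n_vertices:
        Number of cells.  The vertex set is fixed for the lifetime of the
        process; only edges appear (and, under the death process, disappear).

    Attributes
    ----------
    edges:
        Canonical storage of undirected edges as ``(i, j)`` tuples with
        ``i < j``.
    degree:
        Per-vertex degree, each in ``{0, 1, 2}``.
    adjacency:
        Per-vertex neighbour lists (length <= 2), kept in sync with *edges*.
    """

    n_vertices: int
    edges: set[tuple[int, int]] = field(default_factory=set)
    degree: list[int] = field(init=False)
    adjacency: list[list[int]] = field(init=False)

    def __post_init__(self) -> None:
        if self.n_vertices < 1:
            raise ConfigurationError(
                f"n_vertices must be a positive integer, got {self.n_vertices}"
            )
        self.degree = [0] * self.n_vertices
        self.adjacency = [[] for _ in range(self.n_vertices)]
        initial = self.edges
        self.edges = set()
        for i, j in initial:
            outcome = self.try_add_edge(i, j)
            if outcome is not AddOutcome.ADDED:
                raise ConfigurationError(
                    f"initial edge ({i}, {j}) violates graph rules: {outcome.value}"
                )

    # -- basic queries ----------------------------------------------------

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, i: int, j: int) -> bool:
        if i == j:
            return False
        return ((i, j) if i < j else (j, i)) in self.edges

    def _check_vertex(self, i: int) -> None:
        if not 0 <= i < self.n_vertices:
            raise IndexError(
                f"vertex id {i} out of range for graph on {self.n_vertices} vertices"
            )

    # -- mutation ---------------------------------------------------------

    def try_add_edge(self, i: int, j: int) -> AddOutcome:
        """Attempt to add the undirected edge {i, j} under the rafting rules.

        The edge is added iff ``i != j``, the edge is absent, and both
        endpoints currently have degree < 2.  Otherwise the graph is left
        unchanged and the specific rejection reason is returned.
        """
        self._check_vertex(i)
        self._check_vertex(j)
        if i == j:
            return AddOutcome.REJECTED_SELF
        key = (i, j) if i < j else (j, i)
        if key in self.edges:
            return AddOutcome.REJECTED_EXISTS
        if self.degree[i] >= DEGREE_CAP or self.degree[j] >= DEGREE_CAP:
            return AddOutcome.REJECTED_DEGREE
        self.edges.add(key)
        self.degree[i] += 1
        self.degree[j] += 1
        self.adjacency[i].append(j)
        self.adjacency[j].append(i)
        return AddOutcome.ADDED

    def kill_vertex(self, k: int) -> int:
        """Remove every edge incident to vertex *k* (cell death).

        The vertex slot remains and may re-form edges later.  Returns the
        number of edges removed.
        """
        self._check_vertex(k)
        neighbours = list(self.adjacency[k])
        for nb in neighbours:
            key = (k, nb) if k < nb else (nb, k)
            self.edges.discard(key)
            self.adjacency[nb].remove(k)
            self.degree[nb] -= 1
        self.adjacency[k].clear()
        self.degree[k] = 0
        return len(neighbours)

    # -- derived quantities -----------------------------------------------

    def average_degree(self) -> float:
        """Mean vertex degree, ``2 |E| / N``; lies in [0, 2].

        Each undirected edge is counted once (the upper triangle of the
        symmetric adjacency matrix) and contributes degree to two endpoints.
        """
        return 2.0 * len(self.edges) / self.n_vertices

    def connected_components(self) -> "ComponentDecomposition":
        return connected_components(self)

    def copy(self) -> "CellGraph":
        g = CellGraph.__new__(CellGraph)
        g.n_vertices = self.n_vertices
        g.edges = set(self.edges)
        g.degree = list(self.degree)
        g.adjacency = [list(a) for a in self.adjacency]
        return g

    def edge_key(self) -> frozenset:
        """Hashable identity of the edge set (for state-space bookkeeping)."""
        return frozenset(self.edges)


@dataclass(frozen=True)
class ComponentDecomposition:
    """Partition of the vertex set into maximal connected components.

    With the degree cap every component is a simple path or a simple cycle;
    ``kinds`` records which, so that cycle components can be inspected
    separately when deciding whether they should count as rafts.
    """

    components: list[frozenset[int]]
    sizes: Counter
    giant_size: int
    kinds: list[str]  # "path" (includes singletons) or "cycle", per component

    def __iter__(self) -> Iterator[frozenset[int]]:
        return iter(self.components)


def make_empty_graph(n: int) -> CellGraph:
    """Initial state of every graph process: *n* cells, no contacts."""
    return CellGraph(n_vertices=int(n))


def average_degree(g: CellGraph) -> float:
    return g.average_degree()


def try_add_edge(g: CellGraph, i: int, j: int) -> AddOutcome:
    return g.try_add_edge(i, j)


def connected_components(g: CellGraph) -> ComponentDecomposition:
    """Exact component decomposition by traversal of the neighbour lists.

    Verifies the path-or-cycle corollary of the degree cap: a component on
    ``s`` vertices is a cycle iff it carries ``s`` edges (every degree 2),
    otherwise a path with ``s - 1`` edges.
    """
    seen = [False] * g.n_vertices
    components: list[frozenset[int]] = []
    kinds: list[str] = []
    sizes: Counter = Counter()
    giant = 0
    for start in range(g.n_vertices):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        members = []
        n_edge_ends = 0
        while stack:
            v = stack.pop()
            members.append(v)
            n_edge_ends += g.degree[v]
            for nb in g.adjacency[v]:
                if not seen[nb]:
                    seen[nb] = True
                    stack.append(nb)
        s = len(members)
        n_edges = n_edge_ends // 2
        if n_edges not in (s - 1, s):  # pragma: no cover - invariant guard
            raise RuntimeError("degree-capped component is neither path nor cycle")
        components.append(frozenset(members))
        kinds.append("cycle" if n_edges == s else "path")
        sizes[s] += 1
        giant = max(giant, s)
    return ComponentDecomposition(
        components=components, sizes=sizes, giant_size=giant, kinds=kinds
    )


# -- edge-list text format ----------------------------------------------------


def write_edge_list(g: CellGraph, fh: IO[str]) -> None:
    """Write a two-column tab-separated edge list (1-based ids, i < j)."""
    fh.write(f"# n_vertices={g.n_vertices}\n")
    for i, j in sorted(g.edges):
        fh.write(f"{i + 1}\t{j + 1}\n")


def read_edge_list(fh: IO[str] | Iterable[str]) -> CellGraph:
    """Read the edge-list format written by :func:`write_edge_list`."""
    n_vertices = None
    pairs: list[tuple[int, int]] = []
    for line in fh:
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("n_vertices="):
                n_vertices = int(body.split("=", 1)[1])
            continue
        a, b = line.split()
        pairs.append((int(a) - 1, int(b) - 1))
    if n_vertices is None:
        raise ConfigurationError("edge list missing '# n_vertices=' header")
    return CellGraph(n_vertices=n_vertices, edges={(min(p), max(p)) for p in pairs})
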