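"""Graph ingestion, fixtures, generators and network statistics.

Graphs are simple (no self-loops, no multi-edges), undirected and
unweighted.  Node labels are arbitrary strings kept in first-appearance
order; every matrix in the package uses the stable 0-based internal index
of :class:`Graph`, and every user-facing result maps back to the original
labels.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

logger = logging.getLogger(__name__)

__all__ = [
    "Graph",
    "DistanceMatrix",
    "GraphStats",
    "read_edge_list",
    "write_edge_list",
    "load_fixture",
    "FIXTURE_NAMES",
    "generate_random",
    "all_pairs_shortest_path",
    "graph_stats",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list line cannot be parsed."""


@dataclass(frozen=True)
class Graph:
    """A simple undirected graph with stable label ↔ index mapping.

    Parameters
    ----------
    labels
        Node labels in first-appearance order.
    edge_index
        ``(M, 2)`` integer array of internal node ids, one row per edge.
        Self-loops and duplicates must already be removed.
    """

    labels: tuple[str, ...]
    edge_index: np.ndarray
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "_index", {lab: i for i, lab in enumerate(self.labels)}
        )
        if len(self._index) != len(self.labels):
            raise ValueError("duplicate node labels")

    # -- basic counts -------------------------------------------------
    @property
    def N(self) -> int:
        return len(self.labels)

    @property
    def M(self) -> int:
        return int(self.edge_index.shape[0])

    # -- label <-> index ----------------------------------------------
    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node label {label!r}") from None

    def label(self, i: int) -> str:
        return self.labels[i]

    # -- structure ----------------------------------------------------
    def adjacency(self) -> np.ndarray:
        """Dense symmetric 0/1 adjacency matrix with zero diagonal."""
        A = np.zeros((self.N, self.N))
        if self.M:
            u, v = self.edge_index[:, 0], self.edge_index[:, 1]
            A[u, v] = 1.0
            A[v, u] = 1.0
        return A

    def adjacency_sparse(self) -> csr_matrix:
        u = np.concatenate([self.edge_index[:, 0], self.edge_index[:, 1]])
        v = np.concatenate([self.edge_index[:, 1], self.edge_index[:, 0]])
        data = np.ones(len(u))
        return csr_matrix((data, (u, v)), shape=(self.N, self.N))

    @property
    def degrees(self) -> np.ndarray:
        """Integer degree per internal node id."""
        deg = np.zeros(self.N, dtype=np.int64)
        for col in (0, 1):
            np.add.at(deg, self.edge_index[:, col], 1)
        return deg

    def degree(self, label: str) -> int:
        return int(self.degrees[self.index(label)])

    def neighbors(self, label: str) -> set[str]:
        j = self.index(label)
        out: set[str] = set()
        for u, v in self.edge_index:
            if u == j:
                out.add(self.labels[v])
            elif v == j:
                out.add(self.labels[u])
        return out

    def edges_as_labels(self) -> set[frozenset[str]]:
        return {
            frozenset((self.labels[u], self.labels[v]))
            for u, v in self.edge_index
        }

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.labels)
        g.add_edges_from(
            (self.labels[u], self.labels[v]) for u, v in self.edge_index
        )
        return g

    @classmethod
    def from_label_pairs(
        cls,
        pairs: Iterable[tuple[str, str]],
        isolated: Iterable[str] = (),
    ) -> "Graph":
        """Build a graph from labelled edges, dropping self-loops/duplicates."""
        labels: list[str] = []
        index: dict[str, int] = {}

        def intern(lab: str) -> int:
            if lab not in index:
                index[lab] = len(labels)
                labels.append(lab)
            return index[lab]

        seen: set[frozenset[int]] = set()
        edges: list[tuple[int, int]] = []
        for a, b in pairs:
            u, v = intern(a), intern(b)
            if u == v:
                logger.warning("dropping self-loop at node %r", a)
                continue
            key = frozenset((u, v))
            if key in seen:
                logger.warning("dropping duplicate edge (%r, %r)", a, b)
                continue
            seen.add(key)
            edges.append((u, v))
        for lab in isolated:
            intern(lab)
        arr = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
        return cls(tuple(labels), arr)


@dataclass(frozen=True)
class DistanceMatrix:
    """All-pairs shortest-path lengths; unreachable pairs are ``inf``."""

    d: np.ndarray  # float matrix; np.inf marks unreachable pairs

    @property
    def N(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class GraphStats:
    N: int
    M: int
    mean_degree: float        # <k> = 2M/N
    second_moment: float      # <k^2> = sum(k_j^2)/N
    max_degree: int
    diameter: int             # over the largest connected component


# ---------------------------------------------------------------------------
# Parsing and writing
# ---------------------------------------------------------------------------

_DELIMS = (",", "\t", " ")


def read_edge_list(
    source: str | Path | TextIO,
    delimiter: str | None = None,
    comment_prefixes: Sequence[str] = ("#", "%"),
) -> Graph:
    """Parse a two-column edge list into a :class:`Graph`.

    The delimiter is auto-detected among comma, tab and whitespace unless
    given.  Lines starting with a comment prefix and blank lines are
    skipped; duplicate edges and self-loops are dropped with a warning.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = source.read()

    pairs: list[tuple[str, str]] = []
    for lineno, raw in enumerate(io.StringIO(text), start=1):
        line = raw.strip()
        if not line or any(line.startswith(p) for p in comment_prefixes):
            continue
        if delimiter is not None:
            tokens = [t for t in line.split(delimiter) if t.strip()]
            tokens = [t.strip() for t in tokens]
        elif "," in line:
            tokens = [t.strip() for t in line.split(",") if t.strip()]
        else:
            tokens = line.split()
        if len(tokens) != 2:
            raise EdgeListParseError(
                f"line {lineno}: expected 2 tokens, found {len(tokens)}: {line!r}"
            )
        pairs.append((tokens[0], tokens[1]))

    if not pairs:
        raise EdgeListParseError("empty edge list: no edges found")
    return Graph.from_label_pairs(pairs)


def write_edge_list(g: Graph, destination: str | Path | TextIO) -> None:
    """Write ``label1<TAB>label2`` lines, one edge per line, lexicographic."""
    lines = sorted(
        "\t".join(sorted((g.labels[u], g.labels[v]))) for u, v in g.edge_index
    )
    text = "\n".join(lines) + "\n"
    if isinstance(destination, (str, Path)):
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)
    else:
        destination.write(text)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

# Zachary's karate club: the standard 34-node, 78-edge social network of a
# university karate club that split into two factions (leaders: nodes 1
# and 34).  Labels are the conventional 1-based ids.
KARATE_EDGES = """\
1 2
1 3
1 4
1 5
1 6
1 7
1 8
1 9
1 11
1 12
1 13
1 14
1 18
1 20
1 22
1 32
2 3
2 4
2 8
2 14
2 18
2 20
2 22
2 31
3 4
3 8
3 9
3 10
3 14
3 28
3 29
3 33
4 8
4 13
4 14
5 7
5 11
6 7
6 11
6 17
7 17
9 31
9 33
9 34
10 34
14 34
15 33
15 34
16 33
16 34
19 33
19 34
20 34
21 33
21 34
23 33
23 34
24 26
24 28
24 30
24 33
24 34
25 26
25 28
25 32
26 32
27 30
27 34
28 34
29 32
29 34
30 33
30 34
31 33
31 34
32 33
32 34
33 34
"""

FIXTURE_NAMES = ("karate", "triangle", "path3", "star(n)", "cycle(n)")

_PARAM_RE = re.compile(r"^(star|cycle)\((\d+)\)$")


def load_fixture(name: str) -> Graph:
    """Return a named deterministic graph.

    Recognized names: ``karate``, ``triangle``, ``path3``, ``star(n)``,
    ``cycle(n)``.
    """
    if name == "karate":
        return read_edge_list(io.StringIO(KARATE_EDGES))
    if name == "triangle":
        return Graph.from_label_pairs([("1", "2"), ("2", "3"), ("1", "3")])
    if name == "path3":
        return Graph.from_label_pairs([("1", "2"), ("2", "3")])
    m = _PARAM_RE.match(name)
    if m:
        kind, n = m.group(1), int(m.group(2))
        if kind == "star":
            if n < 2:
                raise ValueError("star(n) requires n >= 2")
            return Graph.from_label_pairs(
                [("1", str(i)) for i in range(2, n + 1)]
            )
        if n < 3:
            raise ValueError("cycle(n) requires n >= 3")
        return Graph.from_label_pairs(
            [(str(i), str(i % n + 1)) for i in range(1, n + 1)]
        )
    raise ValueError(
        f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
    )


# ---------------------------------------------------------------------------
# Random generators
# ---------------------------------------------------------------------------

def generate_random(
    model: str,
    n: int,
    seed: int,
    p: float | None = None,
    m: int | None = None,
) -> Graph:
    """Generate a reproducible random graph.

    Parameters
    ----------
    model
        ``"er"`` (Erdős–Rényi G(n, p), requires ``p``) or ``"ba"``
        (Barabási–Albert preferential attachment, requires ``m`` edges
        per new node; the result is connected).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if model == "er":
        if p is None or not (0.0 <= p <= 1.0):
            raise ValueError("er model requires p in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=seed)
    elif model == "ba":
        if m is None or m < 1:
            raise ValueError("ba model requires m >= 1")
        g = nx.barabasi_albert_graph(n, m, seed=seed)
    else:
        raise ValueError(f"unknown model {model!r}; use 'er' or 'ba'")
    labels = [str(v) for v in g.nodes()]
    return Graph.from_label_pairs(
        [(str(u), str(v)) for u, v in g.edges()], isolated=labels
    )


# ---------------------------------------------------------------------------
# Distances and statistics
# ---------------------------------------------------------------------------

def all_pairs_shortest_path(g: Graph) -> DistanceMatrix:
    """BFS shortest-path lengths between all node pairs (``inf`` if none)."""
    if g.M == 0:
        d = np.full((g.N, g.N), np.inf)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(d)
    d = _csgraph_shortest_path(
        g.adjacency_sparse(), method="D", unweighted=True, directed=False
    )
    return DistanceMatrix(d)


def graph_stats(g: Graph) -> GraphStats:
    """Size, degree moments and diameter (of the largest component)."""
    if g.N == 0:
        raise ValueError("empty graph")
    deg = g.degrees.astype(float)
    mean_k = 2.0 * g.M / g.N
    second = float((deg**2).sum() / g.N)
    dist = all_pairs_shortest_path(g).d
    # restrict diameter to the largest connected component
    finite = np.isfinite(dist)
    comp_sizes = finite.sum(axis=1)
    rep = int(np.argmax(comp_sizes))
    members = finite[rep]
    sub = dist[np.ix_(members, members)]
    diameter = int(sub.max()) if sub.size else 0
    return GraphStats(
        N=g.N,
        M=g.M,
        mean_degree=mean_k,
        second_moment=second,
        max_degree=int(deg.max(initial=0)),
        diameter=diameter,
    )
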