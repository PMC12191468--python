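"""Classical centrality baselines: degree, betweenness, PageRank.

All return a :class:`CentralityScores` with the same descending-score,
ascending-label-tie-break ranking convention as the walk scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from .graph_io import Graph

__all__ = [
    "CentralityScores",
    "degree_centrality",
    "betweenness_centrality",
    "pagerank",
    "DEFAULT_DAMPING",
]

#: The standard damping factor; on the karate-club benchmark it also
#: reproduces the canonical top-10 baseline ranking (see docs/methods.md).
DEFAULT_DAMPING = 0.85


@dataclass(frozen=True)
class CentralityScores:
    method: str
    scores: Mapping[str, float]
    ranking: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        order = sorted(self.scores, key=lambda lab: (-self.scores[lab], lab))
        object.__setattr__(self, "ranking", tuple(order))

    def top(self, k: int) -> tuple[str, ...]:
        return self.ranking[:k]


def degree_centrality(g: Graph) -> CentralityScores:
    """Raw degree |N(j)| per node."""
    deg = g.degrees
    return CentralityScores(
        "degree", {lab: float(deg[i]) for i, lab in enumerate(g.labels)}
    )


def betweenness_centrality(g: Graph) -> CentralityScores:
    """Unnormalized shortest-path betweenness (each unordered pair once)."""
    bc = nx.betweenness_centrality(g.to_networkx(), normalized=False)
    return CentralityScores(
        "betweenness", {lab: float(bc[lab]) for lab in g.labels}
    )


def pagerank(
    g: Graph,
    damping: float = DEFAULT_DAMPING,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> CentralityScores:
    """PageRank by power iteration with uniform teleportation.

    Iterates ``x <- damping * P^T x + (1 - damping)/N`` on the
    column-stochastic transition ``P^T`` of the undirected graph
    (dangling nodes redistribute uniformly) until the L1 change drops
    below ``tol``.
    """
    if not 0.0 < damping < 1.0:
        raise ValueError("damping must lie in (0, 1)")
    N = g.N
    A = g.adjacency()
    deg = g.degrees.astype(float)
    out = np.where(deg > 0, deg, 1.0)
    PT = (A / out[:, None]).T  # column-stochastic for non-dangling columns
    dangling = deg == 0
    x = np.full(N, 1.0 / N)
    for _ in range(max_iter):
        x_new = damping * (PT @ x + x[dangling].sum() / N) + (1.0 - damping) / N
        if np.abs(x_new - x).sum() < tol:
            return CentralityScores(
                "pagerank",
                {lab: float(x_new[i]) for i, lab in enumerate(g.labels)},
            )
        x = x_new
    raise RuntimeError(f"PageRank did not converge in {max_iter} iterations")
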