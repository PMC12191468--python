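"""Ranking-agreement statistics: Kendall tau-a, top-k overlap, scatter pairs.

The Kendall coefficient here is the tau-a form: over all unordered item
pairs, a pair is concordant when both score vectors order it the same
strict way and discordant when they order it oppositely; pairs tied in
either vector count in neither.  tau = (Nc − Nd) / (n(n−1)/2).  Note
that ``scipy.stats.kendalltau`` defaults to the tie-corrected tau-b,
which differs on tied data (e.g. degree scores), so the pair counting is
done explicitly here.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KendallResult",
    "kendall_tau",
    "average_tau",
    "top_k_overlap",
    "correlation_pairs",
]


@dataclass(frozen=True)
class KendallResult:
    tau: float
    nc: int
    nd: int
    n: int


def _aligned(x: Mapping[str, float], y: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    if set(x) != set(y):
        raise ValueError("score mappings must cover the same item set")
    items = sorted(x)
    return (
        np.asarray([x[i] for i in items], dtype=float),
        np.asarray([y[i] for i in items], dtype=float),
    )


def kendall_tau(x: Mapping[str, float], y: Mapping[str, float]) -> KendallResult:
    """Tau-a rank correlation between two per-item score mappings."""
    xv, yv = _aligned(x, y)
    n = xv.size
    if n < 2:
        raise ValueError("need at least 2 items")
    sx = np.sign(xv[:, None] - xv[None, :])
    sy = np.sign(yv[:, None] - yv[None, :])
    prod = sx * sy
    upper = np.triu_indices(n, k=1)
    nc = int((prod[upper] > 0).sum())
    nd = int((prod[upper] < 0).sum())
    tau = (nc - nd) / (n * (n - 1) / 2)
    return KendallResult(tau=tau, nc=nc, nd=nd, n=n)


def average_tau(values: Sequence[float]) -> float:
    """Arithmetic mean of tau values, reported to 3 decimals (half-up)."""
    if len(values) == 0:
        raise ValueError("empty list of tau values")
    mean = Decimal(sum(Decimal(str(v)) for v in values)) / len(values)
    return float(mean.quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def top_k_overlap(rank_a: Sequence[str], rank_b: Sequence[str], k: int) -> int:
    """Size of the intersection of the two top-k lists."""
    if k <= 0:
        raise ValueError("k must be positive")
    if k > len(rank_a) or k > len(rank_b):
        raise ValueError("k exceeds ranking length")
    return len(set(rank_a[:k]) & set(rank_b[:k]))


def correlation_pairs(
    scores_a: Mapping[str, float], scores_b: Mapping[str, float]
) -> pd.DataFrame:
    """Per-node paired scores (columns ``node, a, b``) for scatter plots."""
    if set(scores_a) != set(scores_b):
        raise ValueError("score mappings must cover the same node set")
    nodes = list(scores_a)
    return pd.DataFrame(
        {
            "node": nodes,
            "a": [scores_a[n] for n in nodes],
            "b": [scores_b[n] for n in nodes],
        }
    )
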