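"""Coined discrete-time quantum walk on a cycle (reference walk).

This is the genuinely unitary one-dimensional walk used as an oracle for
the coin/shift machinery: a walker on ``n`` ring sites carries a 2-state
coin with basis ``|f> = (1, 0)^T`` (move forward, ``j -> j+1``) and
``|b> = (0, 1)^T`` (move backward, ``j -> j-1``).  States are length-2n
complex vectors in coin-major order, ``index(c, j) = c*n + j`` with
``f = 0`` and ``b = 1`` — the same ordering the network walk uses.

Probability is conserved exactly here; the network-walk generalisation in
:mod:`ioqw.ioqw_core` is deliberately non-unitary.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "hadamard_coin",
    "line_shift",
    "line_evolve",
    "line_observe",
    "localized_state",
]

_NORM_TOL = 1e-8


def hadamard_coin() -> np.ndarray:
    return np.array([[1.0, 1.0], [1.0, -1.0]]) / np.sqrt(2.0)


def localized_state(n: int, position: int, coin: np.ndarray | None = None) -> np.ndarray:
    """Walker localized at one site with a given (default ``|f>``) coin state."""
    if coin is None:
        coin = np.array([1.0, 0.0])
    psi = np.zeros(2 * n, dtype=complex)
    psi[position] = coin[0]
    psi[n + position] = coin[1]
    return psi


def line_shift(n: int) -> np.ndarray:
    """Conditional-shift permutation matrix on the 2n-dimensional ring space.

    The ``|f>`` sector translates ``j -> j+1 (mod n)``, the ``|b>`` sector
    ``j -> j-1 (mod n)``.
    """
    if n < 2:
        raise ValueError("need at least 2 sites")
    S = np.zeros((2 * n, 2 * n))
    for j in range(n):
        S[(j + 1) % n, j] = 1.0            # forward sector
        S[n + (j - 1) % n, n + j] = 1.0    # backward sector
    return S


def _coin_lift(coin: np.ndarray, n: int) -> np.ndarray:
    """Apply the 2x2 coin to the coin index of a coin-major state space."""
    if coin.shape != (2, 2):
        raise ValueError("coin must be 2x2")
    return np.kron(coin, np.eye(n))


def line_evolve(psi0: np.ndarray, coin: np.ndarray, t: int) -> np.ndarray:
    """Evolve ``t`` steps with U = S · (coin ⊗ I): coin toss, then shift."""
    if t < 0:
        raise ValueError("t must be >= 0")
    psi0 = np.asarray(psi0, dtype=complex)
    if psi0.ndim != 1 or psi0.size % 2:
        raise ValueError("state must be a length-2n vector")
    norm = np.linalg.norm(psi0)
    if abs(norm - 1.0) > _NORM_TOL:
        raise ValueError(f"initial state is not normalized (|psi| = {norm:.3g})")
    n = psi0.size // 2
    U = line_shift(n) @ _coin_lift(coin, n)
    psi = psi0
    for _ in range(t):
        psi = U @ psi
    return psi


def line_observe(psi: np.ndarray) -> np.ndarray:
    """Per-site probabilities P(j) = sum over coin sectors of |amplitude|^2."""
    psi = np.asarray(psi, dtype=complex)
    n = psi.size // 2
    return np.abs(psi[:n]) ** 2 + np.abs(psi[n:]) ** 2
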