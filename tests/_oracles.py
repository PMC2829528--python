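"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: the alignment
oracle is a plain recursive enumeration, the rotation oracle samples
random rotations, and the column-cost oracle evaluates candidates
directly from the cost definition.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

GAP = -1


def brute_force_align_cost(A: np.ndarray, B: np.ndarray, gap: float) -> float:
    """Minimum alignment cost by exhaustive recursion (no memoization)."""

    def rec(i: int, j: int) -> float:
        if i == 0 and j == 0:
            return 0.0
        best = np.inf
        if i > 0 and j > 0:
            d = A[i - 1] - B[j - 1]
            best = rec(i - 1, j - 1) + float(d @ d)
        if i > 0:
            best = min(best, rec(i - 1, j) + gap)
        if j > 0:
            best = min(best, rec(i, j - 1) + gap)
        return best

    return rec(A.shape[0], B.shape[0])


def alignment_cost(columns, A, B, gap: float) -> float:
    """Cost of an explicit alignment, straight from the definition."""
    total = 0.0
    for i, j in columns:
        if i == GAP or j == GAP:
            total += gap
        else:
            d = A[i] - B[j]
            total += float(d @ d)
    return total


def best_random_rotation_residual(A: np.ndarray, B: np.ndarray,
                                  n_rot: int, rng) -> float:
    """Min residual over random rotations, each with optimal translation.

    For a fixed rotation the optimal translation matches the centroids,
    so the residual reduces to the centered quantity.
    """
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    Rs = Rotation.random(n_rot, random_state=rng).as_matrix()  # (n_rot,3,3)
    moved = np.einsum("ij,rjk->rik", Bc, Rs)
    diff = moved - Ac[None]
    res = np.einsum("rij,rij->r", diff, diff)
    return float(res.min())


def random_pair_alignment(rng, n_fixed: int, n_moving: int):
    """A random valid global alignment (list of (i, j) columns)."""
    cols = []
    i = j = 0
    while i < n_fixed or j < n_moving:
        moves = []
        if i < n_fixed and j < n_moving:
            moves.append("d")
        if i < n_fixed:
            moves.append("u")
        if j < n_moving:
            moves.append("l")
        mv = moves[rng.integers(len(moves))]
        if mv == "d":
            cols.append((i, j))
            i += 1
            j += 1
        elif mv == "u":
            cols.append((i, GAP))
            i += 1
        else:
            cols.append((GAP, j))
            j += 1
    return cols


def random_rigid(rng):
    """A random proper rotation matrix and translation vector."""
    Q = Rotation.random(random_state=rng).as_matrix()
    t = rng.uniform(-20.0, 20.0, size=3)
    return Q, t
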