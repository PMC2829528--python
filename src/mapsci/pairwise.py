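"""Pairwise structural alignment.

Two operations live here:

* :func:`dp_align` — global (Needleman–Wunsch-style) dynamic
  programming over Cα coordinates already expressed in a common frame.
  A match column costs the squared Euclidean distance between the two
  triples; any column pairing a triple with a gap costs the squared
  gap penalty.  The DP returns the cost-optimal alignment.

* :func:`pairwise_structure_align` — a self-contained bootstrap
  aligner for two structures in arbitrary frames: seed with the best
  gapless terminal/centered window superposition, then iterate
  {superpose on current match columns → re-run the DP in the new
  frame} until the cost stops improving.  Each half-step is optimal
  for the quantity it minimizes, so the cost sequence is
  non-increasing.  Any pairwise structure aligner could be substituted
  here; downstream modules only consume the resulting alignment and
  rigid transform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.spatial.distance import cdist

from .geometry import RigidTransform, superpose
from .params import AlignParams

__all__ = ["GAP", "PairAlignment", "dp_align", "pairwise_structure_align"]

GAP = -1

# traceback pointers
_DIAG, _UP, _LEFT = 0, 1, 2


@dataclass
class PairAlignment:
    """A global alignment of two coordinate sequences.

    ``columns`` is an ordered list of ``(i, j)`` index pairs into the
    first (fixed) and second (moving) sequence, with :data:`GAP` (-1)
    marking a gap; no column is (GAP, GAP).  ``cost`` is the total
    alignment cost in Å².
    """

    columns: list[tuple[int, int]]
    cost: float

    def match_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Index arrays of the match columns (both sides non-gap)."""
        pairs = [(i, j) for i, j in self.columns if i != GAP and j != GAP]
        if not pairs:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        arr = np.array(pairs, dtype=int)
        return arr[:, 0], arr[:, 1]

    @property
    def n_gap_columns(self) -> int:
        return sum(1 for i, j in self.columns if i == GAP or j == GAP)

    def recompute_cost(self, fixed: np.ndarray, moving: np.ndarray,
                       gap_cost_sq: float) -> float:
        total = 0.0
        for i, j in self.columns:
            if i == GAP or j == GAP:
                total += gap_cost_sq
            else:
                d = fixed[i] - moving[j]
                total += float(d @ d)
        return total

    def flipped(self) -> "PairAlignment":
        """Swap the fixed/moving roles."""
        return PairAlignment([(j, i) for i, j in self.columns], self.cost)


@njit(cache=False)
def _nw_fill(costmat, gap):  # pragma: no cover - exercised via dp_align
    n, m = costmat.shape
    D = np.empty((n + 1, m + 1), dtype=np.float64)
    P = np.zeros((n + 1, m + 1), dtype=np.int8)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        D[i, 0] = i * gap
        P[i, 0] = 1
    for j in range(1, m + 1):
        D[0, j] = j * gap
        P[0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # tie preference: match > gap-in-moving > gap-in-fixed
            best = D[i - 1, j - 1] + costmat[i - 1, j - 1]
            ptr = 0
            up = D[i - 1, j] + gap
            if up < best:
                best = up
                ptr = 1
            left = D[i, j - 1] + gap
            if left < best:
                best = left
                ptr = 2
            D[i, j] = best
            P[i, j] = ptr
    return D, P


def _coords_of(obj) -> np.ndarray:
    c = getattr(obj, "coords", obj)
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array or Structure")
    if c.shape[0] == 0:
        raise ValueError("empty structure")
    return c


def dp_align(fixed, moving, params: AlignParams | None = None) -> PairAlignment:
    """Cost-optimal global alignment of two coordinate sequences.

    Both sequences must already be in a common frame; no superposition
    happens here.  Ties are broken deterministically: match over gap in
    the moving sequence over gap in the fixed sequence.
    """
    params = params or AlignParams()
    A = _coords_of(fixed)
    B = _coords_of(moving)
    costmat = cdist(A, B, "sqeuclidean")
    D, P = _nw_fill(costmat, params.gap_cost_sq)
    cols: list[tuple[int, int]] = []
    i, j = A.shape[0], B.shape[0]
    while i > 0 or j > 0:
        ptr = P[i, j]
        if ptr == _DIAG:
            i -= 1
            j -= 1
            cols.append((i, j))
        elif ptr == _UP:
            i -= 1
            cols.append((i, GAP))
        else:
            j -= 1
            cols.append((GAP, j))
    cols.reverse()
    return PairAlignment(cols, float(D[A.shape[0], B.shape[0]]))


def _seed_offsets(mode: str, lp: int, lq: int, w: int) -> tuple[int, int]:
    if mode == "nterm":
        return 0, 0
    if mode == "cterm":
        return lp - w, lq - w
    if mode == "center":
        return (lp - w) // 2, (lq - w) // 2
    raise ValueError(f"unknown seed window {mode!r}")


def pairwise_structure_align(
    P, Q, params: AlignParams | None = None,
) -> tuple[PairAlignment, RigidTransform]:
    """Align structure ``Q`` onto structure ``P`` from arbitrary frames.

    Returns the final alignment and the cumulative rigid transform that
    maps ``Q``'s original coordinates into ``P``'s frame.  The cost is
    non-increasing over the refinement iterations.
    """
    params = params or AlignParams()
    A = _coords_of(P)
    B0 = _coords_of(Q)
    lp, lq = A.shape[0], B0.shape[0]
    if lp < 3 or lq < 3:
        raise ValueError("pairwise structure alignment requires length >= 3")

    w = min(lp, lq, 40)
    best: tuple[float, PairAlignment, RigidTransform] | None = None
    for mode in params.seed_windows:
        oa, ob = _seed_offsets(mode, lp, lq, w)
        tf, _ = superpose(A[oa:oa + w], B0[ob:ob + w])
        aln = dp_align(A, tf.apply(B0), params)
        if best is None or aln.cost < best[0]:
            best = (aln.cost, aln, tf)
    assert best is not None
    cost, aln, tf = best

    B = tf.apply(B0)
    for _ in range(params.max_pair_iters):
        ia, ib = aln.match_pairs()
        if ia.size == 0:
            break
        step, _ = superpose(A[ia], B[ib])
        B = step.apply(B)
        tf = tf.compose(step)
        new_aln = dp_align(A, B, params)
        if cost - new_aln.cost < params.inner_tol:
            if new_aln.cost <= cost:
                aln, cost = new_aln, new_aln.cost
            break
        aln, cost = new_aln, new_aln.cost
    return aln, tf
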