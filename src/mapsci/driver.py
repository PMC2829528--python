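"""The main iterative multiple-alignment loop.

Starting from one of the input proteins as the initial consensus, the
algorithm repeats:

1. align every protein to the current consensus (full bootstrap
   structure alignment on the first pass, plain coordinate-frame
   dynamic programming afterwards);
2. merge the pairwise alignments into one correspondence matrix with
   the center-star scheme;
3. interleave per-protein optimal rigid superposition onto the
   consensus with per-column consensus re-estimation until the
   combined objective stalls;
4. drop all-gap columns and recompute the consensus,

until the relative drop in the sum-of-consensus (SC) distance falls
below the threshold eta.  Every step is cost-optimal for the quantity
it touches while leaving the others fixed, so the SC-distance is
non-increasing and the loop converges to a local minimum.  The
consensus frame never moves; the proteins are transformed into it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .consensus import consensus_from_correspondence
from .coremetrics import strict_core_columns
from .geometry import RigidTransform, superpose
from .multialign import (GAP, Correspondence, merge_center_star, sc_distance,
                         strip_all_gap_columns)
from .pairwise import PairAlignment, dp_align, pairwise_structure_align
from .params import AlignParams
from .structio import Structure

logger = logging.getLogger(__name__)

__all__ = [
    "INIT_STRATEGIES",
    "AlignmentResult",
    "select_initial_consensus",
    "optimal_transforms_and_consensus",
    "align",
]

#: Valid initial-consensus selection strategies: the protein of median
#: length; the protein minimizing the sum (center) or the maximum
#: (minmax) of the pairwise alignment costs; or the protein whose
#: initial merged alignment yields the largest strict core (maxcore).
INIT_STRATEGIES = ("median", "center", "minmax", "maxcore")


@dataclass
class AlignmentResult:
    """Everything produced by one run of :func:`align`.

    ``correspondence`` holds the final gapped matrix with coordinates
    in the consensus frame; ``transforms[j]`` maps protein j's input
    coordinates into that frame.  ``sc_trace`` records the SC-distance
    at the end of every outer iteration and is non-increasing.
    """

    correspondence: Correspondence
    transforms: list[RigidTransform]
    sc_trace: list[float]
    iterations: int
    initial_consensus_index: int
    structures: list[Structure] = field(default_factory=list)
    params: AlignParams = field(default_factory=AlignParams)

    @property
    def n_proteins(self) -> int:
        return self.correspondence.n_proteins

    @property
    def consensus_coords(self) -> np.ndarray:
        return self.correspondence.consensus_coords

    @property
    def sc(self) -> float:
        return self.sc_trace[-1]

    def transformed_coords(self, j: int) -> np.ndarray:
        """Final-frame coordinates of protein ``j`` (0-based)."""
        return self.correspondence.row_coords[j + 1]


def _pairwise_cache(structures, params) -> dict:
    cache = {}
    for i in range(len(structures)):
        for j in range(i + 1, len(structures)):
            cache[(i, j)] = pairwise_structure_align(
                structures[i], structures[j], params)
    return cache


def _alignment_to(cache, c: int, j: int) -> tuple[PairAlignment, RigidTransform]:
    """Pairwise alignment with protein ``c`` as the fixed sequence."""
    if c < j:
        return cache[(c, j)]
    aln, tf = cache[(j, c)]
    return aln.flipped(), tf.inverse()


def _initial_correspondence(structures, c: int, cache, params) -> Correspondence:
    """Center-star merge around candidate ``c`` with all proteins moved
    into ``c``'s frame by their pairwise transforms."""
    K = len(structures)
    alns, coords = [], []
    for j in range(K):
        if j == c:
            n = len(structures[c])
            alns.append(PairAlignment([(p, p) for p in range(n)], 0.0))
            coords.append(structures[c].coords.copy())
        else:
            aln, tf = _alignment_to(cache, c, j)
            alns.append(aln)
            coords.append(tf.apply(structures[j].coords))
    return merge_center_star(len(structures[c]), alns,
                             structures[c].coords.copy(), coords)


def select_initial_consensus(
    structures,
    strategy: str = "maxcore",
    params: AlignParams | None = None,
    cache: dict | None = None,
    core_cutoff: float = 4.0,
) -> int:
    """Pick the index of the initial consensus protein.

    ``median`` uses lengths only (lower median, lowest index on ties);
    the other strategies need all pairwise structure alignments, which
    are computed here unless a precomputed ``cache`` is supplied.
    """
    params = params or AlignParams()
    K = len(structures)
    if K < 2:
        raise ValueError("at least two structures are required")
    if strategy not in INIT_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")

    if strategy == "median":
        lengths = [len(s) for s in structures]
        target = sorted(lengths)[(K - 1) // 2]
        return lengths.index(target)

    if cache is None:
        cache = _pairwise_cache(structures, params)
    costs = np.zeros((K, K))
    for (i, j), (aln, _) in cache.items():
        costs[i, j] = costs[j, i] = aln.cost

    if strategy == "center":
        return int(np.argmin(costs.sum(axis=1)))
    if strategy == "minmax":
        np.fill_diagonal(costs, -np.inf)
        return int(np.argmin(costs.max(axis=1)))

    # maxcore: largest strict core of the candidate's initial merge
    best_idx, best_core = 0, -1
    for c in range(K):
        H = _initial_correspondence(structures, c, cache, params)
        core = len(strict_core_columns(H, cutoff=core_cutoff))
        if core > best_core:
            best_idx, best_core = c, core
    return best_idx


def optimal_transforms_and_consensus(
    H: Correspondence,
    params: AlignParams | None = None,
    rule: str | None = None,
) -> tuple[list[RigidTransform], Correspondence, float]:
    """Interleaved minimization of the combined objective for a fixed
    correspondence: per-protein optimal superposition onto the current
    consensus (mismatch columns removed), alternated with the optimal
    per-column consensus, until the objective's decrease falls below
    ``inner_tol``.  Returns the per-protein incremental transforms, the
    updated correspondence and the final objective (Å²); the objective
    is non-increasing at every half-step.
    """
    params = params or AlignParams()
    H = H.copy()
    K = H.n_proteins
    deltas = [RigidTransform.identity() for _ in range(K)]
    s_prev = sc_distance(H, params)
    for _ in range(params.max_inner_iters):
        for j in range(1, K + 1):
            both = (H.idx[0] != GAP) & (H.idx[j] != GAP)
            if not both.any():
                continue
            A = H.row_coords[0][H.idx[0][both]]
            B = H.row_coords[j][H.idx[j][both]]
            tf, _ = superpose(A, B)
            H.row_coords[j] = tf.apply(H.row_coords[j])
            deltas[j - 1] = deltas[j - 1].compose(tf)
        H = consensus_from_correspondence(H, params, rule)
        s = sc_distance(H, params)
        if s_prev - s < params.inner_tol:
            s_prev = s
            break
        s_prev = s
    return deltas, H, s_prev


def align(
    structures,
    strategy: str = "maxcore",
    params: AlignParams | None = None,
    core_cutoff: float = 4.0,
) -> AlignmentResult:
    """Multiple structure alignment with consensus identification.

    Parameters
    ----------
    structures:
        Two or more :class:`~mapsci.structio.Structure` objects (or
        (n, 3) coordinate arrays), each of length >= 3.
    strategy:
        Initial-consensus choice, one of :data:`INIT_STRATEGIES`
        (default ``"maxcore"``).
    params:
        Alignment parameters; defaults everywhere.
    core_cutoff:
        Distance cutoff (Å) used only by the maxcore strategy.
    """
    params = params or AlignParams()
    structs = [s if isinstance(s, Structure)
               else Structure(f"P{i}", np.asarray(s, dtype=float))
               for i, s in enumerate(structures)]
    K = len(structs)
    if K < 2:
        raise ValueError("at least two structures are required")
    if any(len(s) < 3 for s in structs):
        raise ValueError("every structure must have length >= 3")

    cache = None
    if strategy != "median":
        cache = _pairwise_cache(structs, params)
    c = select_initial_consensus(structs, strategy, params, cache=cache,
                                 core_cutoff=core_cutoff)
    logger.info("initial consensus: structure %d (%s)", c, structs[c].id)

    # iteration 0: full pairwise structure alignments against the center
    alignments: list[PairAlignment] = []
    coords: list[np.ndarray] = []
    transforms: list[RigidTransform] = []
    for j in range(K):
        if j == c:
            alignments.append(
                PairAlignment([(p, p) for p in range(len(structs[c]))], 0.0))
            coords.append(structs[c].coords.copy())
            transforms.append(RigidTransform.identity())
        else:
            if cache is not None:
                aln, tf = _alignment_to(cache, c, j)
            else:
                aln, tf = pairwise_structure_align(structs[c], structs[j],
                                                   params)
            alignments.append(aln)
            coords.append(tf.apply(structs[j].coords))
            transforms.append(tf)

    consensus_coords = structs[c].coords.copy()
    sc_prev = np.inf
    sc_trace: list[float] = []
    H = None
    for it in range(params.max_outer_iters):
        if it > 0:
            alignments = [dp_align(consensus_coords, coords[j], params)
                          for j in range(K)]
        H = merge_center_star(len(consensus_coords), alignments,
                              consensus_coords, coords)
        deltas, H, sc = optimal_transforms_and_consensus(H, params)
        transforms = [transforms[j].compose(deltas[j]) for j in range(K)]
        sc_trace.append(sc)

        H = strip_all_gap_columns(H)
        H = consensus_from_correspondence(H, params)
        H = strip_all_gap_columns(H)
        consensus_coords = H.consensus_coords
        coords = [H.row_coords[j + 1] for j in range(K)]
        if consensus_coords.shape[0] == 0:
            raise RuntimeError(
                "consensus vanished: structures share no alignable core "
                "at this gap penalty")

        if params.convergence == "relative":
            done = (sc_prev - sc) / max(sc_prev, 1e-12) < params.eta
        else:
            done = sc_prev - sc < params.eta
        sc_prev = sc
        if done:
            break

    return AlignmentResult(H, transforms, sc_trace, len(sc_trace), c,
                           structs, params)
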