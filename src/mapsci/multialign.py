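"""The correspondence matrix and its maintenance.

A multiple structure alignment is stored as a gapped matrix with K+1
rows: row 0 is the consensus pseudo-structure, rows 1..K are the input
proteins.  Internally each row keeps its ungapped coordinate array
(already in the current working frame) plus an integer index row of
the correspondence: entry ``idx[i, c]`` is the position within row
``i``'s coordinate array occupying column ``c``, or -1 for a gap.

This module provides the center-star merge of pairwise alignments
against the consensus, the removal of all-gap columns, and the
sum-of-consensus (SC) distance: the total cost, over all proteins, of
each protein's gapped alignment against the consensus row (squared
Euclidean distance for triple/triple columns, the squared gap penalty
for triple/gap columns, zero for gap/gap columns).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pairwise import GAP, PairAlignment
from .params import AlignParams

__all__ = [
    "Correspondence",
    "merge_center_star",
    "strip_all_gap_columns",
    "sc_distance",
    "project_pair",
]


@dataclass
class Correspondence:
    """Gapped correspondence of K proteins plus the consensus (row 0)."""

    idx: np.ndarray                 # (K+1, L) int array, -1 = gap
    row_coords: list[np.ndarray]    # K+1 ungapped (n_i, 3) arrays

    def __post_init__(self) -> None:
        self.idx = np.asarray(self.idx, dtype=np.int64)
        if self.idx.ndim != 2:
            raise ValueError("idx must be 2-D")
        if len(self.row_coords) != self.idx.shape[0]:
            raise ValueError("one coordinate array per row is required")
        self.row_coords = [np.asarray(c, dtype=float).reshape(-1, 3)
                           for c in self.row_coords]

    @property
    def n_proteins(self) -> int:
        return self.idx.shape[0] - 1

    @property
    def width(self) -> int:
        return self.idx.shape[1]

    @property
    def consensus_coords(self) -> np.ndarray:
        return self.row_coords[0]

    def validate(self) -> None:
        """Check the structural invariants of the matrix."""
        for i, coords in enumerate(self.row_coords):
            row = self.idx[i]
            nz = row[row != GAP]
            if not np.array_equal(nz, np.arange(len(coords))):
                raise ValueError(
                    f"row {i}: removing gaps must reproduce the coordinate "
                    f"sequence in order")
        if self.width > 0 and np.any(np.all(self.idx == GAP, axis=0)):
            raise ValueError("all-gap column present")

    def column_coords(self, col: int) -> list[np.ndarray | None]:
        """Coordinates (or None for gaps) of every row at one column."""
        return [self.row_coords[i][v] if (v := int(self.idx[i, col])) != GAP
                else None for i in range(self.idx.shape[0])]

    def copy(self) -> "Correspondence":
        return Correspondence(self.idx.copy(),
                              [c.copy() for c in self.row_coords])


def merge_center_star(
    consensus_len: int,
    pair_alignments: list[PairAlignment],
    consensus_coords: np.ndarray | None = None,
    protein_coords: list[np.ndarray] | None = None,
) -> Correspondence:
    """Merge K pairwise (consensus, protein) alignments into one matrix.

    Every pairwise alignment must carry the consensus as its first
    (fixed) sequence and cover all ``consensus_len`` positions.
    Consensus positions become shared columns; each protein's
    insertions (columns where the consensus has a gap) get private
    columns placed before the consensus position they precede, ordered
    by protein index.  Projecting the merge back onto (consensus,
    protein j) and dropping mutual-gap columns reproduces alignment j
    exactly, so the merge changes no consensus–protein distance.
    """
    K = len(pair_alignments)
    if K < 1:
        raise ValueError("at least one pairwise alignment is required")
    aligned = []      # per protein: array of length consensus_len (idx or GAP)
    insertions = []   # per protein: dict slot -> list of moving indices
    for j, aln in enumerate(pair_alignments):
        a = np.full(consensus_len, GAP, dtype=np.int64)
        ins: dict[int, list[int]] = {}
        cpos = 0
        for ci, cj in aln.columns:
            if ci == GAP:
                ins.setdefault(cpos, []).append(cj)
            else:
                if ci != cpos:
                    raise ValueError(
                        f"alignment {j}: consensus side out of order or "
                        f"wrong length")
                a[cpos] = cj
                cpos += 1
        if cpos != consensus_len:
            raise ValueError(
                f"alignment {j}: consensus-side length {cpos} != "
                f"{consensus_len}")
        aligned.append(a)
        insertions.append(ins)

    cols: list[np.ndarray] = []
    for p in range(consensus_len + 1):
        for j in range(K):
            for q in insertions[j].get(p, ()):
                col = np.full(K + 1, GAP, dtype=np.int64)
                col[j + 1] = q
                cols.append(col)
        if p < consensus_len:
            col = np.full(K + 1, GAP, dtype=np.int64)
            col[0] = p
            for j in range(K):
                col[j + 1] = aligned[j][p]
            cols.append(col)

    idx = (np.stack(cols, axis=1) if cols
           else np.empty((K + 1, 0), dtype=np.int64))
    if consensus_coords is None:
        consensus_coords = np.zeros((consensus_len, 3))
    if protein_coords is None:
        protein_coords = [
            np.zeros((sum(1 for _, cj in aln.columns if cj != GAP), 3))
            for aln in pair_alignments
        ]
    return Correspondence(idx, [np.asarray(consensus_coords, dtype=float)]
                          + [np.asarray(c, dtype=float)
                             for c in protein_coords])


def strip_all_gap_columns(H: Correspondence) -> Correspondence:
    """Drop columns where every row (consensus included) has a gap.

    Idempotent; preserves column order and the SC-distance, since a
    gap aligned to a gap costs nothing.
    """
    keep = ~np.all(H.idx == GAP, axis=0)
    return Correspondence(H.idx[:, keep], H.row_coords)


def sc_distance(H: Correspondence, params: AlignParams | None = None) -> float:
    """Sum-of-consensus distance of the correspondence, in Å².

    Sum over proteins of the column costs against the consensus row:
    squared Euclidean distance when both entries are triples, the
    squared gap penalty when exactly one is a gap, zero for two gaps.
    """
    params = params or AlignParams()
    cons_idx = H.idx[0]
    cons = H.row_coords[0]
    total = 0.0
    for j in range(1, H.idx.shape[0]):
        row = H.idx[j]
        both = (cons_idx != GAP) & (row != GAP)
        one = (cons_idx != GAP) ^ (row != GAP)
        diff = cons[cons_idx[both]] - H.row_coords[j][row[both]]
        total += float(np.einsum("ij,ij->", diff, diff))
        total += float(one.sum()) * params.gap_cost_sq
    return total


def project_pair(H: Correspondence, j: int,
                 params: AlignParams | None = None) -> PairAlignment:
    """Project the merge back to (consensus, protein j).

    Mutual-gap columns are dropped; the remaining columns form the
    pairwise alignment of the consensus with protein ``j`` (1-based
    row index), with its cost recomputed from the current coordinates.
    """
    params = params or AlignParams()
    if not (1 <= j <= H.n_proteins):
        raise IndexError("protein row index out of range")
    cols = [(int(a), int(b)) for a, b in zip(H.idx[0], H.idx[j])
            if not (a == GAP and b == GAP)]
    aln = PairAlignment(cols, 0.0)
    aln.cost = aln.recompute_cost(H.row_coords[0], H.row_coords[j],
                                  params.gap_cost_sq)
    return aln
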