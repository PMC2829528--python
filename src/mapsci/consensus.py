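"""Optimal consensus structure for a fixed correspondence.

For a fixed correspondence and fixed frames, the consensus that
minimizes the SC-distance decomposes column by column: in each column
the optimal entry is either the centroid of the proteins' triples in
that column (the centroid minimizes the sum of squared distances to a
set of points) or a gap.  Writing m for the number of proteins with a
triple in the column, g for the number with a gap, x for the centroid
and spread = Σ‖x − p‖² over the m triples, the two candidate costs are

* consensus triple:  spread + g·ρ²   (each protein gap faces a triple)
* consensus gap:     m·ρ²            (each protein triple faces a gap)

The default rule ("sc") compares exactly these two totals, which makes
the consensus update a non-increasing step of the SC-distance.  An
alternative rule ("literal") compares spread against m·ρ² alone,
ignoring the g·ρ² term on the triple branch; the two coincide whenever
the column has no protein gaps.  Ties prefer the triple, keeping the
consensus maximal and the choice deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .multialign import GAP, Correspondence
from .params import AlignParams

__all__ = ["ConsensusColumn", "consensus_column",
           "consensus_from_correspondence"]


@dataclass(frozen=True)
class ConsensusColumn:
    """Outcome of the per-column consensus choice.

    ``value`` is the chosen coordinate triple (the centroid of the
    column's non-gap entries) or ``None`` for a gap; ``support`` is the
    number of proteins with a triple in the column and ``spread`` their
    total squared deviation from the centroid, in Å².
    """

    value: np.ndarray | None
    support: int
    spread: float

    @property
    def is_gap(self) -> bool:
        return self.value is None


def consensus_column(points, n_gaps: int,
                     params: AlignParams | None = None,
                     rule: str | None = None) -> ConsensusColumn:
    """Choose the optimal consensus entry for one column.

    ``points`` are the coordinate triples of the proteins that have a
    residue in the column (m = len(points)); ``n_gaps`` counts the
    proteins with a gap there.
    """
    params = params or AlignParams()
    rule = rule or params.consensus_rule
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    m = pts.shape[0]
    if m == 0:
        if n_gaps == 0:
            raise ValueError("empty column")
        return ConsensusColumn(None, 0, 0.0)
    x = pts.mean(axis=0)
    d = pts - x
    spread = float(np.einsum("ij,ij->", d, d))
    rho2 = params.gap_cost_sq
    if rule == "sc":
        keep = spread + n_gaps * rho2 <= m * rho2
    elif rule == "literal":
        keep = spread <= m * rho2
    else:
        raise ValueError(f"unknown consensus rule {rule!r}")
    return ConsensusColumn(x if keep else None, m, spread)


def consensus_from_correspondence(
    H: Correspondence,
    params: AlignParams | None = None,
    rule: str | None = None,
) -> Correspondence:
    """Replace the consensus row with the per-column optimal choices.

    Under the default "sc" rule the resulting SC-distance never exceeds
    the SC-distance with the previous consensus row.  Columns in which
    every protein has a gap become consensus gaps regardless of rule.
    """
    params = params or AlignParams()
    K1, L = H.idx.shape
    new_row = np.full(L, GAP, dtype=np.int64)
    coords: list[np.ndarray] = []
    for c in range(L):
        col = H.idx[1:, c]
        nz = col != GAP
        m = int(nz.sum())
        if m == 0:
            continue
        pts = np.stack([H.row_coords[j + 1][col[j]]
                        for j in np.nonzero(nz)[0]])
        choice = consensus_column(pts, K1 - 1 - m, params, rule)
        if not choice.is_gap:
            new_row[c] = len(coords)
            coords.append(choice.value)
    new_coords = (np.stack(coords) if coords else np.empty((0, 3)))
    idx = H.idx.copy()
    idx[0] = new_row
    return Correspondence(idx, [new_coords] + list(H.row_coords[1:]))
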