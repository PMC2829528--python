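"""Conserved-core evaluation metrics.

The *strict core* of a multiple structure alignment is the set of
columns with 100% conservation — no protein has a gap — in which the
K superposed Cα triples all lie within a distance cutoff (4.0 Å by
default) of each other.  The *core RMSD* summarizes how tightly the
structures agree on those columns: by default the average over all
K(K-1)/2 structure pairs of the RMSD computed over core columns in
the final frames, with no re-superposition.  A consensus-referenced
variant of both (distances measured to the consensus row instead of
all pairs) is available for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .multialign import GAP, Correspondence

__all__ = ["CoreReport", "strict_core_columns", "strict_core", "core_rmsd",
           "core_report"]


@dataclass(frozen=True)
class CoreReport:
    """Strict-core summary of an alignment.

    ``core_percent`` expresses the core size as a percentage of the
    length of the shortest protein; ``core_rmsd`` is ``None`` when no
    core was found (distinct from a perfect core of RMSD 0.0).
    """

    core_columns: tuple[int, ...]
    core_size: int
    core_percent: float
    core_rmsd: float | None


def _as_correspondence(obj) -> Correspondence:
    H = getattr(obj, "correspondence", obj)
    if not isinstance(H, Correspondence):
        raise TypeError("expected an AlignmentResult or Correspondence")
    return H


def strict_core_columns(obj, cutoff: float = 4.0,
                        reference: str = "pairs") -> list[int]:
    """Column indices of the strict core.

    A column qualifies iff every protein (consensus row excluded) has
    a residue there and, with ``reference="pairs"`` (default), all
    pairwise distances among the K transformed triples are <= cutoff;
    with ``reference="consensus"`` the consensus entry must be a
    triple and every protein triple must lie within cutoff of it.
    May be empty — the alignment then has no core at this cutoff.
    """
    H = _as_correspondence(obj)
    K = H.n_proteins
    core: list[int] = []
    prot_idx = H.idx[1:]
    full = np.all(prot_idx != GAP, axis=0)
    for c in np.nonzero(full)[0]:
        pts = np.stack([H.row_coords[j + 1][prot_idx[j, c]]
                        for j in range(K)])
        if reference == "pairs":
            d = pts[:, None, :] - pts[None, :, :]
            ok = np.sqrt((d ** 2).sum(axis=2)).max() <= cutoff
        elif reference == "consensus":
            if H.idx[0, c] == GAP:
                continue
            x = H.row_coords[0][H.idx[0, c]]
            ok = np.sqrt(((pts - x) ** 2).sum(axis=1)).max() <= cutoff
        else:
            raise ValueError(f"unknown reference {reference!r}")
        if ok:
            core.append(int(c))
    return core


# alias matching the operation name used throughout the docs
strict_core = strict_core_columns


def core_rmsd(obj, core_columns, mode: str = "pairwise") -> float:
    """Core RMSD over the given columns, in the final frames (Å).

    ``"pairwise"`` (default): arithmetic mean over all structure pairs
    of each pair's RMSD across the core columns.  ``"consensus"``:
    mean over structures of the RMSD to the consensus row.
    Raises ``ValueError`` on an empty core — "no core" is not 0.0.
    """
    H = _as_correspondence(obj)
    cols = np.asarray(list(core_columns), dtype=int)
    if cols.size == 0:
        raise ValueError("no core: core RMSD is undefined")
    K = H.n_proteins
    pts = np.stack([
        H.row_coords[j + 1][H.idx[j + 1][cols]] for j in range(K)
    ])  # (K, ncore, 3)
    if mode == "pairwise":
        vals = []
        for i, j in combinations(range(K), 2):
            d = pts[i] - pts[j]
            vals.append(np.sqrt((d ** 2).sum(axis=1).mean()))
        return float(np.mean(vals))
    if mode == "consensus":
        ci = H.idx[0][cols]
        if np.any(ci == GAP):
            raise ValueError("consensus has gaps on core columns")
        x = H.row_coords[0][ci]
        vals = [np.sqrt(((pts[j] - x) ** 2).sum(axis=1).mean())
                for j in range(K)]
        return float(np.mean(vals))
    raise ValueError(f"unknown mode {mode!r}")


def core_report(obj, cutoff: float = 4.0, reference: str = "pairs",
                rmsd_mode: str = "pairwise") -> CoreReport:
    """Compute the full strict-core report for an alignment."""
    H = _as_correspondence(obj)
    cols = strict_core_columns(H, cutoff=cutoff, reference=reference)
    min_len = min(c.shape[0] for c in H.row_coords[1:])
    percent = 100.0 * len(cols) / min_len if min_len else 0.0
    rmsd_val = core_rmsd(H, cols, mode=rmsd_mode) if cols else None
    return CoreReport(tuple(cols), len(cols), percent, rmsd_val)
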