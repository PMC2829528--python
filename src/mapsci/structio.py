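"""Reading protein backbones from PDB files and writing all outputs.

A protein is reduced to the ordered sequence of its Cα coordinate
triples; everything downstream (alignment, superposition, consensus)
operates on that backbone trace.  Parsing is delegated to biotite;
this module adds the chain-selection plumbing, the Cα/altloc/residue
filtering rules, and the writers for transformed structures (PDB),
the consensus pseudo-structure (PDB with UNK residues) and the
multiple alignment (NBRF/PIR).
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TextIO, Union

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .geometry import RigidTransform

logger = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "ChainSelector",
    "parse_selector",
    "read_structure",
    "write_transformed_pdb",
    "write_consensus_pdb",
    "write_pir",
    "read_pir",
    "THREE_TO_ONE",
]

# Standard 20 amino acids plus selenomethionine (mapped to MET).
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M",
    "UNK": "X",  # unknown residue; also used for consensus pseudo-atoms
}


@dataclass
class Structure:
    """An ordered Cα backbone trace.

    ``coords`` is an (n, 3) float array in Å; ``residue_names`` holds
    3-letter codes and ``residue_numbers`` the author-assigned residue
    ids, both in backbone (file) order.
    """

    id: str
    coords: np.ndarray
    residue_names: list[str] = field(default_factory=list)
    residue_numbers: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if n < 1:
            raise ValueError("a structure must contain at least one residue")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if not self.residue_names:
            self.residue_names = ["UNK"] * n
        if not self.residue_numbers:
            self.residue_numbers = list(range(1, n + 1))
        if len(self.residue_names) != n or len(self.residue_numbers) != n:
            raise ValueError("residue annotations must match coordinate count")

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def residues(self) -> list[tuple[str, int, np.ndarray]]:
        return list(zip(self.residue_names, self.residue_numbers, self.coords))

    def sequence(self) -> str:
        """One-letter sequence; unknown residue names map to 'X'."""
        return "".join(THREE_TO_ONE.get(n, "X") for n in self.residue_names)

    def transformed(self, transform: RigidTransform) -> "Structure":
        return Structure(self.id, transform.apply(self.coords),
                         list(self.residue_names), list(self.residue_numbers))


@dataclass(frozen=True)
class ChainSelector:
    """A PDB path plus an optional single-character chain id."""

    path: str
    chain: str | None = None

    def __post_init__(self) -> None:
        if self.chain is not None and len(self.chain) != 1:
            raise ValueError("chain id must be a single character")


def parse_selector(text: str) -> ChainSelector:
    """Parse ``"path"`` or ``"path:C"`` into a :class:`ChainSelector`."""
    head, sep, tail = text.rpartition(":")
    if sep and len(tail) == 1 and head:
        return ChainSelector(head, tail)
    return ChainSelector(text, None)


def _validate_atom_lines(text: str, name: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise ValueError(
                f"{name}: malformed ATOM record at line {lineno} (too short)")
        try:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                float(line[lo:hi])
        except ValueError as exc:
            raise ValueError(
                f"{name}: malformed ATOM record at line {lineno}: "
                f"unparseable coordinate field") from exc


def read_structure(
    source: Union[str, os.PathLike, TextIO],
    selector: ChainSelector | str | None = None,
) -> Structure:
    """Read the Cα trace of one structure from a PDB file.

    Only the first model of multi-model files is used; for alternate
    locations the first conformer (altloc blank or 'A') is kept.
    Residues without a Cα atom, and residue types outside the standard
    twenty (plus MSE, read as MET), are skipped with a logged warning.
    Calcium ions (atom name CA, element Ca) are never confused with
    alpha-carbons.
    """
    if isinstance(selector, str):
        selector = parse_selector(selector)
    chain = selector.chain if selector is not None else None

    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "<stream>")
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"no such PDB file: {path}")
        text = path.read_text()
        name = path.name

    _validate_atom_lines(text, name)
    pdb = PDBFile.read(io.StringIO(text))
    atoms = pdb.get_structure(model=1, altloc="first")

    mask = (atoms.atom_name == "CA") & (atoms.element != "CA")
    if chain is not None:
        mask &= atoms.chain_id == chain
    ca = atoms[mask]

    keep = np.array([rn in THREE_TO_ONE for rn in ca.res_name], dtype=bool)
    n_dropped = int((~keep).sum())
    if n_dropped:
        dropped = sorted(set(ca.res_name[~keep]))
        logger.warning("%s: skipped %d non-standard residue(s): %s",
                       name, n_dropped, ", ".join(dropped))
    ca = ca[keep]

    if ca.array_length() == 0:
        where = f" in chain {chain!r}" if chain is not None else ""
        raise ValueError(f"{name}: no CA atoms{where}")

    if ca.array_length() and np.all(ca.res_name == "UNK"):
        logger.info("%s: all residues UNK (consensus pseudo-structure?)",
                    name)
    res_names = ["MET" if rn == "MSE" else str(rn) for rn in ca.res_name]
    stem = Path(name).stem if name != "<stream>" else "structure"
    sid = f"{stem}_{chain}" if chain is not None else stem
    return Structure(sid, ca.coord.astype(float),
                     res_names, [int(r) for r in ca.res_id])


def _write_ca_pdb(coords: np.ndarray, res_names: Sequence[str],
                  res_numbers: Sequence[int], sink) -> None:
    n = coords.shape[0]
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(coords, dtype=np.float32)
    arr.chain_id[:] = "A"
    arr.res_id = np.asarray(res_numbers, dtype=int)
    arr.res_name = np.asarray(res_names, dtype="U5")
    arr.atom_name[:] = "CA"
    arr.element[:] = "C"
    arr.hetero[:] = False
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(sink)


def write_transformed_pdb(structure: Structure, transform: RigidTransform,
                          sink) -> None:
    """Write a structure's Cα trace after applying a rigid transform.

    Coordinates are printed at PDB fixed-column precision (3 decimals),
    so a read/write round trip preserves them to 0.001 Å.
    """
    moved = transform.apply(structure.coords)
    _write_ca_pdb(moved, structure.residue_names, structure.residue_numbers,
                  sink)


def write_consensus_pdb(consensus_coords: np.ndarray, sink) -> None:
    """Write the consensus pseudo-structure as a chain of UNK Cα atoms."""
    coords = np.asarray(consensus_coords, dtype=float).reshape(-1, 3)
    n = coords.shape[0]
    _write_ca_pdb(coords, ["UNK"] * n, list(range(1, n + 1)), sink)


def _pir_record(name: str, description: str, seq: str) -> str:
    lines = [seq[i:i + 60] for i in range(0, len(seq), 60)] or [""]
    lines[-1] += "*"
    return f">P1;{name}\n{description}\n" + "\n".join(lines) + "\n"


def write_pir(correspondence, structures: Sequence[Structure], sink,
              include_consensus: bool = True) -> None:
    """Write a multiple alignment in NBRF/PIR format.

    One record per protein row (plus, optionally, the consensus as a
    run of 'X'/'-' characters), '-' for gaps, terminated by '*'.  All
    gapped sequences share the correspondence width.
    """
    K = correspondence.n_proteins
    if len(structures) != K:
        raise ValueError("one Structure per protein row is required")
    out = []
    if include_consensus:
        row = correspondence.idx[0]
        seq = "".join("X" if v >= 0 else "-" for v in row)
        out.append(_pir_record("consensus", "consensus pseudo-structure", seq))
    for j, s in enumerate(structures, start=1):
        letters = s.sequence()
        row = correspondence.idx[j]
        seq = "".join(letters[v] if v >= 0 else "-" for v in row)
        out.append(_pir_record(s.id, "structure alignment", seq))
    text = "".join(out)
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)


def read_pir(source: Union[str, os.PathLike, TextIO]) -> list[tuple[str, str]]:
    """Parse a PIR file into (name, gapped-sequence) pairs."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    entries: list[tuple[str, str]] = []
    name = None
    seq_parts: list[str] = []
    skip_desc = False
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                entries.append((name, "".join(seq_parts).rstrip("*")))
            name = line.split(";", 1)[1].strip() if ";" in line else line[1:].strip()
            seq_parts = []
            skip_desc = True
        elif skip_desc:
            skip_desc = False
        elif name is not None:
            seq_parts.append(line.strip())
    if name is not None:
        entries.append((name, "".join(seq_parts).rstrip("*")))
    return entries
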