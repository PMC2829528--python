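import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)


def make_pdb_text(records):
    """Build a minimal PDB text from (serial, name, resname, chain,
    resnum, x, y, z[, altloc]) tuples."""
    lines = []
    for rec in records:
        serial, name, resname, chain, resnum, x, y, z = rec[:8]
        altloc = rec[8] if len(rec) > 8 else " "
        lines.append(
            f"ATOM  {serial:>5d} {name:^4s}{altloc}{resname:<3s} "
            f"{chain}{resnum:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"  1.00  0.00           C"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


@pytest.fixture
def three_residue_pdb(tmp_path):
    text = make_pdb_text([
        (1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0),
        (2, "CA", "GLY", "A", 2, 3.8, 0.0, 0.0),
        (3, "CA", "SER", "A", 3, 7.6, 0.0, 0.0),
    ])
    p = tmp_path / "tri.pdb"
    p.write_text(text)
    return p
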