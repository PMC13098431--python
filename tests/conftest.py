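import numpy as np
import pytest

from sdrcensus.model_io import AtomRecord, Frame, Topology, Trajectory

PDB_3ATOM = """\
HETATM    1  OH  TYR A 164      10.000  10.000  10.000  1.00  0.00           O
HETATM    2  NZ  LYS A 168      12.000  10.000  10.000  1.00  0.00           N
HETATM    3  C4  NAD A 401      12.000  13.000  10.000  1.00  0.00           C
END
"""


@pytest.fixture
def pdb_3atom(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(PDB_3ATOM)
    return path


@pytest.fixture
def pdb_2model(tmp_path):
    body = PDB_3ATOM.replace("END\n", "")
    text = "MODEL     1\n" + body + "ENDMDL\nMODEL     2\n" + body + "ENDMDL\nEND\n"
    path = tmp_path / "two_models.pdb"
    path.write_text(text)
    return path


def make_topology(spec):
    """spec: list of (name, resname, resid) tuples, chain A."""
    atoms = [
        AtomRecord(serial=i + 1, name=n, resname=rn, resid=ri, chain="A", element=n[0])
        for i, (n, rn, ri) in enumerate(spec)
    ]
    return Topology(atoms)


def make_trajectory(topology, coords):
    """coords: (n_frames, n_atoms, 3) array-like."""
    coords = np.asarray(coords, dtype=float)
    return Trajectory(topology, [Frame(i, c) for i, c in enumerate(coords)])
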