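"""Shared fixtures: literal-format files and synthetic structures."""

import numpy as np
import pytest

from remdock.fixtures import make_cage, make_docking_case, make_ligand

BUTANE_MOL2 = """\
@<TRIPOS>MOLECULE
butane
4 3 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
      1 C1    0.0000  0.0000  0.0000 C.3 1 BUT  -0.0600
      2 C2    1.2600  0.0000  0.7600 C.3 1 BUT   0.0600
      3 C3    2.5200  0.0000  0.0000 C.3 1 BUT   0.0600
      4 C4    3.7800  0.0000  0.7600 C.3 1 BUT  -0.0600
@<TRIPOS>BOND
     1 1 2 1
     2 2 3 1
     3 3 4 1
"""

BENZENE_MOL2 = """\
@<TRIPOS>MOLECULE
benzene
6 6 0 0 0
SMALL
USER_CHARGES
@<TRIPOS>ATOM
      1 C1    1.3900  0.0000  0.0000 C.ar 1 BNZ 0.0000
      2 C2    0.6950  1.2038  0.0000 C.ar 1 BNZ 0.0000
      3 C3   -0.6950  1.2038  0.0000 C.ar 1 BNZ 0.0000
      4 C4   -1.3900  0.0000  0.0000 C.ar 1 BNZ 0.0000
      5 C5   -0.6950 -1.2038  0.0000 C.ar 1 BNZ 0.0000
      6 C6    0.6950 -1.2038  0.0000 C.ar 1 BNZ 0.0000
@<TRIPOS>BOND
     1 1 2 ar
     2 2 3 ar
     3 3 4 ar
     4 4 5 ar
     5 5 6 ar
     6 6 1 ar
"""

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      5  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      6  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      7  N   SER A   3       6.191   3.839   0.000  1.00  0.00           N
ATOM      8  CA  SER A   3       7.646   3.857   0.000  1.00  0.00           C
ATOM      9  OG  SER A   3       8.165   5.184   0.000  1.00  0.00           O
END
"""

ALTLOC_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       1.600   0.100   0.000  0.40  0.00           C
ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def butane_mol2(tmp_path):
    path = tmp_path / "butane.mol2"
    path.write_text(BUTANE_MOL2)
    return path


@pytest.fixture
def benzene_mol2(tmp_path):
    path = tmp_path / "benzene.mol2"
    path.write_text(BENZENE_MOL2)
    return path


@pytest.fixture
def small_pdb(tmp_path):
    path = tmp_path / "three_res.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path


@pytest.fixture
def cage():
    return make_cage(radius=6.0, n_atoms=60, seed=0)


@pytest.fixture
def alkane5():
    return make_ligand("alkane", 5, seed=0)


@pytest.fixture
def docking_case():
    return make_docking_case(seed=1)
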