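"""Shared fixtures: synthetic complexes and small hand-written PDB files."""

from __future__ import annotations

import pytest

from allofoot.synthetic import fab_hla_toy, hbond_pair_complex, separated_complex

THREE_RESIDUE_PDB = """\
ATOM      1  N   ALA A  10      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A  10       0.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A  10       1.100   1.200   0.000  1.00  0.00           C
ATOM      4  O   ALA A  10       1.100   2.440   0.000  1.00  0.00           O
ATOM      5  CB  ALA A  10       0.458  -1.530   0.000  1.00  0.00           C
ATOM      6  N   GLY A  11       2.800   0.000   0.000  1.00  0.00           N
ATOM      7  CA  GLY A  11       4.258   0.000   0.000  1.00  0.00           C
ATOM      8  C   GLY A  11       4.900   1.200   0.000  1.00  0.00           C
ATOM      9  O   GLY A  11       4.900   2.440   0.000  1.00  0.00           O
ATOM     10  N   ASP A  12       6.600   0.000   0.000  1.00  0.00           N
ATOM     11  CA  ASP A  12       8.058   0.000   0.000  1.00  0.00           C
ATOM     12  C   ASP A  12       8.700   1.200   0.000  1.00  0.00           C
ATOM     13  O   ASP A  12       8.700   2.440   0.000  1.00  0.00           O
ATOM     14  CB  ASP A  12       8.058  -1.530   0.000  1.00  0.00           C
ATOM     15  CG  ASP A  12       8.058  -3.000   0.000  1.00  0.00           C
ATOM     16  OD1 ASP A  12       6.958  -3.700   0.000  1.00  0.00           O
ATOM     17  OD2 ASP A  12       9.158  -3.700   0.000  1.00  0.00           O
TER      18
END
"""


@pytest.fixture(scope="session")
def fab_toy():
    """Flagship four-chain Fab-HLA toy with planted ground truth."""
    return fab_hla_toy()


@pytest.fixture(scope="session")
def hb_toy():
    return hbond_pair_complex()


@pytest.fixture(scope="session")
def apart_toy():
    return separated_complex()


@pytest.fixture
def three_residue_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_RESIDUE_PDB)
    return path
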