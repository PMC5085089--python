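import numpy as np
import pytest

from hbprop import (BackboneStructure, Residue, ResidueRef,
                    make_ideal_helix, place_amide_hydrogens)

THREE_RES_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.966   2.850   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.480   2.750   0.000  1.00  0.00           C
ATOM      8  O   GLY A   2       6.089   1.680   0.000  1.00  0.00           O
ATOM      9  N   SER A   3       6.110   3.920   0.000  1.00  0.00           N
ATOM     10  CA  SER A   3       7.560   3.990   0.000  1.00  0.00           C
ATOM     11  C   SER A   3       8.110   5.410   0.000  1.00  0.00           C
ATOM     12  O   SER A   3       7.360   6.390   0.000  1.00  0.00           O
ATOM     13  OG  SER A   3       8.120   3.280   1.150  1.00  0.00           O
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.458  10.000  10.000  1.00  0.00           C
ATOM      3  C   ALA A   1      12.009  11.420  10.000  1.00  0.00           C
ATOM      4  O   ALA A   1      11.251  12.390  10.000  1.00  0.00           O
ENDMDL
END
"""

ALTLOC_PDB = """\
ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.40  0.00           N
ATOM      2  N  BALA A   1       9.000   9.000   9.000  0.60  0.00           N
ATOM      3  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      4  C  AALA A   1       2.000   1.400   0.000  0.50  0.00           C
ATOM      5  C  BALA A   1       5.000   5.400   0.000  0.50  0.00           C
ATOM      6  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
END
"""


@pytest.fixture
def three_res_pdb():
    return THREE_RES_PDB


@pytest.fixture
def two_model_pdb():
    return TWO_MODEL_PDB


@pytest.fixture
def altloc_pdb():
    return ALTLOC_PDB


@pytest.fixture(scope="session")
def helix18():
    """18-residue ideal alpha-helix with amide hydrogens placed."""
    return place_amide_hydrogens(make_ideal_helix(18))


def make_residue(seq, res_name="GLY", chain="A", origin=(0.0, 0.0, 0.0),
                 extra=None, donor=True):
    """Hand-built residue with a plausible local backbone geometry."""
    o = np.asarray(origin, dtype=float)
    atoms = {
        "N": o,
        "CA": o + np.array([1.458, 0.0, 0.0]),
        "C": o + np.array([2.0, 1.4, 0.0]),
        "O": o + np.array([1.25, 2.39, 0.0]),
    }
    if extra:
        atoms.update({k: o + np.asarray(v, dtype=float)
                      for k, v in extra.items()})
    return Residue(ResidueRef(chain, seq, "", res_name), atoms,
                   donor_capable=donor)


@pytest.fixture
def extended_chain():
    """Residues strung far apart along x: no hydrogen bonds possible."""
    residues = [make_residue(i + 1, origin=(10.0 * i, 0.0, 0.0),
                             donor=(i > 0)) for i in range(8)]
    return place_amide_hydrogens(
        BackboneStructure(residues, source_label="extended"))
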