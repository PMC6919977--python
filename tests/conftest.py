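import numpy as np
import pytest

from dbdscreen.pharmacophore import Feature, PharmacophoreModel

GLY_PDB = """\
HEADER    TOY PEPTIDE
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      12.560   6.071  -6.342  1.00  0.00           C
ATOM      3  C   GLY A   1      13.256   7.420  -6.520  1.00  0.00           C
END
"""

PROTEIN_DNA_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.450   0.000   0.000  1.00  0.00           C
ATOM      3  C   GLY A   1       2.200   1.300   0.000  1.00  0.00           C
ATOM      4  P   DA  B   1      20.000   0.000   0.000  1.00  0.00           P
ATOM      5  OP1 DA  B   1      21.200   0.800   0.000  1.00  0.00           O
ATOM      6  C1' DA  B   1      20.000   3.000   0.000  1.00  0.00           C
ATOM      7  P   DT  B   2      26.000   0.000   0.000  1.00  0.00           P
ATOM      8  OP1 DT  B   2      27.200   0.800   0.000  1.00  0.00           O
ATOM      9  C1' DT  B   2      26.000   3.000   0.000  1.00  0.00           C
END
"""

NO_ATOM_PDB = "HEADER    EMPTY ENTRY\nREMARK    no coordinates deposited\nEND\n"


@pytest.fixture
def gly_pdb_text():
    return GLY_PDB


@pytest.fixture
def protein_dna_pdb_text():
    return PROTEIN_DNA_PDB


@pytest.fixture
def no_atom_pdb_text():
    return NO_ATOM_PDB


@pytest.fixture
def five_feature_model():
    """A small well-posed model with two required anchors."""
    feats = [
        Feature("H", np.array([0.0, 0.0, 0.0])),
        Feature("H", np.array([3.5, 0.0, 0.0])),
        Feature("HBA", np.array([1.5, 3.0, 0.0])),
        Feature("HBD", np.array([0.0, 1.5, 3.0])),
        Feature("HBA", np.array([4.0, 2.0, 2.0])),
    ]
    return PharmacophoreModel(features=feats, required_ids={0, 2}, name="fixture")
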