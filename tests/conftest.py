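import numpy as np
import pytest

from mapshb import structure_io
from mapshb.structure_io import Atom, ProteinStructure, Residue
from mapshb.synthetic_data import (
    GeneratorConfig,
    ToyBondSpec,
    build_toy_structure,
    generate_feature_table,
)

FIVE_DONOR_PROBS = {"TYR": 0.86, "SER": 0.53, "THR": 0.40, "HIS": 0.29, "ARG": 0.10}


def make_residue(name, chain_id="A", seq=1, serial=0, atoms=()):
    return Residue(
        name=name, chain_id=chain_id, seq_index=seq, serial_index=serial,
        atoms=list(atoms),
    )


@pytest.fixture
def tyr_asp_structure():
    """Toy structure with one planted Tyr OH -> Asp OD1 SHB (R=2.65, 165 deg)."""
    s = build_toy_structure(ToyBondSpec(donor="TYR", acceptor="ASP", r=2.65, angle=165.0))
    return structure_io.assign_secondary_structure(s)


@pytest.fixture(scope="session")
def donor_only_balanced_1200():
    cfg = GeneratorConfig.donor_only(n_records=1200, seed=5, marginal_mode="balanced")
    return generate_feature_table(cfg)


@pytest.fixture(scope="session")
def prevalence_table_1200():
    cfg = GeneratorConfig.donor_only(n_records=1200, seed=5, marginal_mode="prevalence")
    return generate_feature_table(cfg)


MINIMAL_PDB = """\
HEADER    HYDROLASE                               01-JAN-20   1ABC
TITLE     TEST PROTEIN ALPHA
REMARK   2 RESOLUTION.    1.05 ANGSTROMS.
REMARK   3   R VALUE            (WORKING SET) : 0.180
REMARK   3   FREE R VALUE                     : 0.210
EXPDTA    X-RAY DIFFRACTION
MODEL        1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      12.759   7.092  -4.973  1.00 10.00           C
ATOM      4  O   ALA A   1      13.164   7.796  -5.900  1.00 10.00           O
ATOM      5  N   SER A   2      13.256   7.186  -3.742  1.00 10.00           N
ATOM      6  CA ASER A   2      14.340   8.110  -3.420  0.40 10.00           C
ATOM      7  CA BSER A   2      14.360   8.130  -3.440  0.60 10.00           C
ATOM      8  C   SER A   2      15.650   7.680  -4.080  1.00 10.00           C
ATOM      9  O   SER A   2      16.000   6.500  -4.000  1.00 10.00           O
ATOM     10  N   GLY A   3      16.380   8.640  -4.650  1.00 10.00           N
ATOM     11  CA  GLY A   3      17.680   8.380  -5.260  1.00 10.00           C
ATOM     12  C   GLY A   3      18.780   8.500  -4.210  1.00 10.00           C
ATOM     13  O   GLY A   3      18.620   9.180  -3.190  1.00 10.00           O
HETATM   14  O   HOH A 101      20.000  20.000  20.000  1.00 10.00           O
HETATM   15  O   HOH A 102      21.000  21.000  21.000  1.00 10.00           O
HETATM   16  O   HOH A 103      22.000  22.000  22.000  1.00 10.00           O
HETATM   17 ZN    ZN A 201      25.000  25.000  25.000  1.00 10.00          ZN
ENDMDL
MODEL        2
ATOM      1  N   ALA A   1      99.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      99.639   6.071  -5.147  1.00 10.00           C
ATOM      3  C   ALA A   1      99.759   7.092  -4.973  1.00 10.00           C
ATOM      4  O   ALA A   1      99.164   7.796  -5.900  1.00 10.00           O
ENDMDL
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p
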