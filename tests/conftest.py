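import numpy as np
import pytest

from rcvkit.synthetic import ToyDimerSpec, default_selections, make_toy_dimer


@pytest.fixture(scope="session")
def dimer():
    """Toy dimer reference: (spec, topology, single-frame trajectory, selections)."""
    spec = ToyDimerSpec()
    topo, ref = make_toy_dimer(spec)
    return spec, topo, ref, default_selections(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  C   ALA A   1      12.689   7.143  -4.973  1.00  0.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA ASER A   1       2.000   0.000   0.000  0.60  0.00           C
ATOM      3  CA BSER A   1       2.500   0.500   0.000  0.40  0.00           C
ATOM      4  C   SER A   1       3.000   0.000   0.000  1.00  0.00           C
END
"""

TWO_CHAIN_PDB = """\
ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY B   1       0.000  10.000   0.000  1.00  0.00           C
END
"""


@pytest.fixture()
def pdb_file(tmp_path):
    def write(content, name="test.pdb"):
        path = tmp_path / name
        path.write_text(content)
        return path

    return write
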