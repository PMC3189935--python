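import numpy as np
import pytest

from rindock.fixtures import FixtureSpec, make_benchmark_case, make_complex_and_decoys

TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  N   GLY A   2       3.332   1.536   0.000  1.00  0.00           N
ATOM      6  CA  GLY A   2       3.988   2.839   0.000  1.00  0.00           C
ATOM      7  C   GLY A   2       5.504   2.693   0.000  1.00  0.00           C
ATOM      8  O   GLY A   2       6.030   1.583   0.000  1.00  0.00           O
ATOM      9  N   SER A   3       6.224   3.815   0.000  1.00  0.00           N
ATOM     10  CA  SER A   3       7.679   3.821   0.000  1.00  0.00           C
ATOM     11  CB  SER A   3       8.226   5.247   0.000  1.00  0.00           C
ATOM     12  OG  SER A   3       9.641   5.226   0.000  1.00  0.00           O
TER
END
"""


@pytest.fixture(scope="session")
def tiny_pdb(tmp_path_factory):
    path = tmp_path_factory.mktemp("pdb") / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


@pytest.fixture(scope="session")
def small_complex():
    """A compact synthetic docking case shared by scoring/energy tests."""
    spec = FixtureSpec(seed=1, n_residues=60, ligand_residues=16, n_decoys=8)
    return make_complex_and_decoys(spec)


@pytest.fixture(scope="session")
def signal_ensemble():
    """20 planted-signal cases: network carries signal, energy is noise."""
    return [
        make_benchmark_case(FixtureSpec(seed=s, energy_noise=10.0), case_id=f"sig{s:02d}")
        for s in range(20)
    ]


@pytest.fixture(scope="session")
def zero_signal_ensemble():
    """Cases with a random docking site and an informative energy score."""
    return [
        make_benchmark_case(
            FixtureSpec(seed=100 + s, signal=0.0, energy_noise=1.0),
            case_id=f"null{s:02d}",
        )
        for s in range(8)
    ]
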