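import numpy as np
import pytest

from mdpa import build_hessian, decompose, make_toy_clamp
from mdpa.synthetic import make_convex_blob

MINIMAL_PDB = """\
SITE     1 AC1  2 GLY A   1  GLY A   3
ATOM      1  N   GLY A   1      -1.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  GLY A   3       7.600   0.000   0.000  1.00  0.00           C
HETATM    5  C1  ABC A 101       2.000   3.000   0.000  1.00  0.00           C
HETATM    6  O1  ABC A 101       2.500   3.500   0.000  1.00  0.00           O
HETATM    7  H1  ABC A 101       2.500   4.500   0.000  1.00  0.00           H
HETATM    8  O   HOH A 201      10.000  10.000  10.000  1.00  0.00           O
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    p = tmp_path / "minimal.pdb"
    p.write_text(MINIMAL_PDB)
    return p


@pytest.fixture
def minimal_pdb_nosite(tmp_path):
    lines = [l for l in MINIMAL_PDB.splitlines() if not l.startswith("SITE")]
    p = tmp_path / "minimal_nosite.pdb"
    p.write_text("\n".join(lines) + "\n")
    return p


@pytest.fixture(scope="session")
def toy():
    """Default clamp complex (seed 7) used across modules."""
    return make_toy_clamp(seed=7)


@pytest.fixture(scope="session")
def toy_network(toy):
    return decompose(build_hessian(toy.structure))


@pytest.fixture(scope="session")
def small_cloud():
    """Connected random 20-atom cloud (compact enough for 12 Å contacts)."""
    rng = np.random.default_rng(42)
    coords = rng.uniform(-7.0, 7.0, size=(20, 3))
    from mdpa.structures import CoarseStructure

    return CoarseStructure(
        source_id="cloud20",
        chains=["A"] * 20,
        resnums=list(range(1, 21)),
        icodes=[""] * 20,
        resnames=["GLY"] * 20,
        coords=coords,
    )


@pytest.fixture(scope="session")
def small_network(small_cloud):
    return decompose(build_hessian(small_cloud))


@pytest.fixture(scope="session")
def blob():
    return make_convex_blob(n=30, seed=11)
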