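from __future__ import annotations

import numpy as np
import pytest

from conforma.model import DomainDefinition
from conforma.synth import ToyStructureSpec, make_two_domain_pair

# canonical toy: two 40-residue domains, a clean 12-degree hinge
TOY_THETA = 12.0


@pytest.fixture(scope="session")
def toy_pair():
    """Noise-free open/closed conformer pair with a 12-degree hinge."""
    spec = ToyStructureSpec(theta_deg=TOY_THETA, noise_sigma=0.0, seed=0)
    return make_two_domain_pair(spec)


@pytest.fixture(scope="session")
def toy_domains():
    return {
        "A": DomainDefinition("domA", [("A", 1, 40)]),
        "B": DomainDefinition("domB", [("A", 41, 80)]),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


# a minimal hand-written PDB: two ALA residues + one water, one CA altloc pair
TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 10.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 10.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  N   ALA A   2       3.332   1.536   0.000  1.00 10.00           N
ATOM      6  CA AALA A   2       4.000   2.800   0.100  0.60 10.00           C
ATOM      7  CA BALA A   2       4.100   2.900   0.200  0.40 10.00           C
ATOM      8  C   ALA A   2       5.500   2.700   0.000  1.00 10.00           C
ATOM      9  O   ALA A   2       6.100   1.600   0.000  1.00 10.00           O
ATOM     10  H   ALA A   2       3.000   1.000   1.000  1.00 10.00           H
HETATM   11  O   HOH A 101       8.000   8.000   8.000  1.00 20.00           O
END
"""


@pytest.fixture()
def tiny_pdb_path(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path
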