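import numpy as np
import pytest

from torsionqa.structure import read_structure, write_pdb
from torsionqa.synth import PeptideSpec, build_peptide

MIXED_SEQUENCE = "ALKSFDENVTGYWRQHIMCP"


@pytest.fixture(scope="session")
def helix_spec():
    return PeptideSpec("A" * 10, backbone_torsions=(-57.0, -47.0, 180.0),
                       identifier="helix")


@pytest.fixture(scope="session")
def helix(helix_spec):
    return build_peptide(helix_spec)


@pytest.fixture(scope="session")
def mixed_spec():
    rng = np.random.default_rng(42)
    n = len(MIXED_SEQUENCE)
    bb = [(-120.0 + rng.uniform(-30, 30), 130.0 + rng.uniform(-30, 30), 180.0)
          for _ in range(n)]
    chi = [(float(rng.choice([-60.0, 60.0, 180.0]) + rng.uniform(-10, 10)),
            float(rng.choice([-60.0, 60.0, 180.0]) + rng.uniform(-10, 10)))
           for _ in range(n)]
    return PeptideSpec(MIXED_SEQUENCE, backbone_torsions=bb, chi_torsions=chi,
                       identifier="mixed")


@pytest.fixture(scope="session")
def mixed(mixed_spec):
    return build_peptide(mixed_spec)


@pytest.fixture()
def mixed_pdb(mixed, tmp_path):
    path = tmp_path / "mixed.pdb"
    write_pdb(mixed, path)
    return path


@pytest.fixture()
def reread_mixed(mixed_pdb):
    return read_structure(mixed_pdb)
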