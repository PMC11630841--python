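import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from famrescue import FamilySpec, MockBackend, MockResponseSpec, generate_family


@pytest.fixture(scope="session")
def small_family():
    """One deterministic 60-member synthetic family with its truth table."""
    spec = FamilySpec("PFTEST", n_members=60, seed=42)
    models, annotations, truth = generate_family(spec)
    return spec, models, annotations, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(20240)


@pytest.fixture()
def mock_backend(small_family):
    spec, models, annotations, truth = small_family
    spans = {a.protein_id: a.span for a in annotations}
    return MockBackend(models, spans, MockResponseSpec(seed=7))


MINIMAL_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 70.00           C
ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00 80.00           C
ATOM      3  CA  SER A   3       7.600   0.000   0.000  1.00 90.00           C
END
"""


@pytest.fixture()
def minimal_pdb(tmp_path):
    path = tmp_path / "mini.pdb"
    path.write_text(MINIMAL_PDB)
    return path
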