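from pathlib import Path

import pytest
from hypothesis import settings

from radstaff import PanelSpec, default_weight_table, generate_center

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

REPO_ROOT = Path(__file__).resolve().parents[1]
REFERENCE_DIR = REPO_ROOT / "examples" / "reference_centers"


@pytest.fixture(scope="session")
def table():
    return default_weight_table()


@pytest.fixture(scope="session")
def reference_dir():
    return REFERENCE_DIR


@pytest.fixture(scope="session")
def synthetic_inventories():
    """A deterministic batch of diverse synthetic centers."""
    spec = PanelSpec(n_centers=40, seed=1234)
    return [generate_center(spec, i) for i in range(spec.n_centers)]
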