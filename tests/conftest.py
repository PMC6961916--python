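import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # golden_fixtures helper

from endoatlas.synthetic import SyntheticConfig, generate_all


@pytest.fixture(scope="session")
def default_data():
    """Full-size synthetic input set at the default study conditions."""
    return generate_all(SyntheticConfig(seed=11))


@pytest.fixture()
def small_config():
    """A reduced panel for fast structural tests."""
    return SyntheticConfig(n_genes=60, n_informative=16, seed=3)
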