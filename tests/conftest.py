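import numpy as np
import pytest

from evopt import FactorSpec, build_worksheet
from evopt.io import load_table2, load_table4

# Factor settings of the published phase-I screen: 28 +/- 2 degC,
# pH 6 +/- 2, 80 +/- 10 %WB.
PHASE1_FACTORS = (
    FactorSpec("temperature", "degC", 28.0, 2.0),
    FactorSpec("pH", "pH", 6.0, 2.0),
    FactorSpec("wb_percent", "%WB", 80.0, 10.0),
)


@pytest.fixture(scope="session")
def table4_ws():
    """Packaged phase-I worksheet: 10 runs, 2 cycles."""
    return load_table4()


@pytest.fixture(scope="session")
def table2_ds():
    """Packaged 9-record surrogate training table."""
    return load_table2()


@pytest.fixture
def phase1_factors():
    return PHASE1_FACTORS


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
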