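import numpy as np
import pytest

from rdnapanel import build_default_genome


@pytest.fixture(scope="session")
def genome():
    """Default six-chromosome genome model (500 markers per chromosome)."""
    return build_default_genome()


@pytest.fixture(scope="session")
def small_genome():
    """Coarser marker map for tests that loop over many meioses."""
    return build_default_genome(markers_per_chrom=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)
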