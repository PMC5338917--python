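import warnings

import numpy as np
import pytest

from regsnp.simulate import SimulationConfig, simulate_all

# lifelines emits pandas future warnings on some stacks; irrelevant here
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture
def rng():
    return np.random.default_rng(20160709)


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def sim_dataset(sim_config):
    """One full synthetic cohort shared across tests (read-only)."""
    return simulate_all(sim_config)


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=5_000, max_len=60):
    """Small-coordinate random intervals so per-base oracles stay cheap."""
    from regsnp.intervals import GenomicInterval

    out = []
    for _ in range(n):
        c = chroms[rng.integers(0, len(chroms))]
        start = int(rng.integers(0, span - max_len))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(c, start, start + length))
    return out
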