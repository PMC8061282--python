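import numpy as np
import pytest

from bantamscan import gwas
from bantamscan.simdata import SimConfig, simulate


@pytest.fixture(scope="session")
def demo_pop():
    """One default bantamization simulation shared across test modules."""
    return simulate(SimConfig(seed=11))


@pytest.fixture(scope="session")
def demo_gm(demo_pop):
    return demo_pop.to_genotype_matrix()


@pytest.fixture(scope="session")
def demo_scans(demo_pop, demo_gm):
    return [
        gwas.run_group_scan(demo_gm, demo_pop.samples, g)[0] for g in (1, 2, 3)
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
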