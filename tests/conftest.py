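import numpy as np
import pytest

import ilc2kit as k
from ilc2kit.mir_target import RnaSeq


@pytest.fixture(scope="session")
def mir3p() -> RnaSeq:
    return RnaSeq("mmu-miR-142-3p", "UGUAGUGUUUCCUACUUUAUGGA")


@pytest.fixture(scope="session")
def mir5p() -> RnaSeq:
    return RnaSeq("mmu-miR-142-5p", "CAUAAAGUAGAAAGCACUACU")


@pytest.fixture(scope="session")
def small_fit():
    """A small simulated dataset fitted once (MAP), shared across
    tests that only read the result."""
    cfg = k.SimCountConfig(n_genes=40, n_per_cell=4, n_batches=2,
                           prop_de=0.25, seed=42)
    cm, truth = k.simulate_counts(cfg)
    cmf = k.filter_low_counts(cm)
    sf = k.size_factors_per_batch(cmf)
    ps = k.fit_hierarchical_nb(cmf, sf, k.ModelConfig(seed=7))
    return cmf, truth, sf, ps


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
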