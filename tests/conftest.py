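import numpy as np
import pytest

from memtop import SimConfig, simulate_ms2, simulate_proteoform
from memtop.fragments import generate_by_ions


@pytest.fixture(scope="session")
def gpcr_like():
    """Default GPCR-like synthetic proteoform and topology (seeded)."""
    cfg = SimConfig(seed=11)
    p, topo = simulate_proteoform(cfg)
    return cfg, p, topo


@pytest.fixture(scope="session")
def gpcr_like_ms2(gpcr_like):
    """MS2 simulation plus theoretical ledger for the default proteoform."""
    cfg, p, topo = gpcr_like
    result = simulate_ms2(p, topo, cfg)
    theory = generate_by_ions(p)
    return cfg, p, topo, result, theory


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
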