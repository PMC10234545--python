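import numpy as np
import pytest

import lncwave as lw


@pytest.fixture(scope="session")
def small_synth_seqs():
    """A small seeded two-class dataset shared across tests."""
    cfg = lw.SynthConfig(n_per_class=30, length_range=(250, 1200), seed=11)
    return lw.generate_dataset(cfg)


@pytest.fixture(scope="session")
def small_feature_table(small_synth_seqs):
    return lw.assemble(small_synth_seqs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
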