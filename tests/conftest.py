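import numpy as np
import pytest

from cribsc import synth


@pytest.fixture(scope="session")
def small_pool():
    """A small paired pool with planted DE, shared across tests."""
    up = [(1, f"g{i:04d}", 2.0) for i in range(100, 110)]
    cfg = synth.SynthConfig(
        seed=7, n_patients=4, cells_per_patient=400, n_genes=400,
        de_spec=up,
    )
    return synth.generate_paired_scrna(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
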