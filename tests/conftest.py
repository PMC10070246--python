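import numpy as np
import pytest

from multitau import lattice, synthdata


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_spatial_run():
    """One shared small spatial-lattice run (r=1, subcritical)."""
    cfg = lattice.LatticeConfig(
        L=32, variant="spatial", rule="linear",
        p_s=0.88, p_r=(0.95 - 0.88) / 8, p_ext=1e-3, steps=20_000, seed=7,
    )
    return lattice.simulate(cfg)


@pytest.fixture(scope="session")
def fixture_sessions():
    """Tiny deterministic synthetic sessions (OU and lattice backends)."""
    return synthdata.make_fixture_suite(seed=3)
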