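import numpy as np
import pytest

from repeatbind import simulate


def small_config(seed: int = 7) -> simulate.SimConfig:
    """A desk-scale study configuration for fast unit tests."""
    return simulate.SimConfig(
        seed=seed,
        background_length=60_000,
        n_control_tiles=60,
        repeats=simulate.RepeatMix(n_cobound=8, n_a_only=4, n_b_only=4, n_background=80),
        sva=simulate.SvaConfig(n_elements=12),
        alphoid=simulate.AlphoidConfig(n_arrays=2),
    )


@pytest.fixture(scope="session")
def small_genome():
    return simulate.generate_repeat_genome(small_config())


@pytest.fixture(scope="session")
def small_tiles(small_genome):
    return simulate.build_tiles(small_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
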