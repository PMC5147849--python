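import pytest

from hscompete import SimulationConfig


@pytest.fixture
def small_config() -> SimulationConfig:
    """A small, fast configuration for unit tests."""
    return SimulationConfig(
        grid_width=9,
        grid_height=9,
        n_cells=10,
        site_mean=3.0,
        site_sd=1.0,
        initial_release=(20, 20, 20),
        n_steps=30,
        n_replicates=2,
        seed=42,
    )
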