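import numpy as np
import pytest

from burstnoise import ClonePanelConfig, TelegraphParams


@pytest.fixture
def bursty_params() -> TelegraphParams:
    """A well-characterized bursty parameter set (b = 5, f = 1)."""
    return TelegraphParams(k_on=1.0, k_off=50.0, T=250.0, d_m=1.0)


@pytest.fixture
def small_panel_cfg() -> ClonePanelConfig:
    """A clone panel small enough for fast unit tests."""
    return ClonePanelConfig(
        n_clones=5,
        n_cells_fish=300,
        n_events_flow=4000,
        seed=7,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
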