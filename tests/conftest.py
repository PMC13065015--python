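import numpy as np
import pandas as pd
import pytest

from pfascohort import SimConfig, generate_bundle


@pytest.fixture(scope="session")
def small_bundle():
    """A small noise-free bundle shared by read-only tests."""
    cfg = SimConfig(n_children=2000, seed=3, noise_rate=0.0)
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def noisy_bundle():
    cfg = SimConfig(n_children=2000, seed=4)
    return generate_bundle(cfg)


def make_history(years, ronneby, contaminated):
    """Address-history DataFrame helper."""
    return pd.DataFrame({
        "calendar_year": list(years),
        "in_ronneby": list(ronneby),
        "contaminated_water": list(contaminated),
    })


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
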