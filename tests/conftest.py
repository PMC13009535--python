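import numpy as np
import pytest

from connvar import synthdata as sd


@pytest.fixture(scope="session")
def small_cfg() -> sd.SynthConfig:
    """Desk-scale-but-small configuration shared across unit tests."""
    return sd.SynthConfig(
        n_group_a=12,
        n_group_b=28,
        n_parcels=30,
        n_networks=5,
        n_runs=2,
        frames_per_run=80,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_geometry(small_cfg):
    return sd.make_geometry(small_cfg)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return sd.generate_cohort(small_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
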