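import numpy as np
import pytest

from memdetect.synth import SynthConfig, gen_dataset, gen_profiles, gen_topology_calls


@pytest.fixture(scope="session")
def small_cfg():
    return SynthConfig(n_per_class=20, length_range=(50, 150), seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    """20+20 synthetic proteins with profiles and topology calls."""
    ds = gen_dataset(small_cfg)
    ds.profiles = gen_profiles(ds, small_cfg)
    ds.calls = gen_topology_calls(ds, small_cfg)
    return ds


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
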