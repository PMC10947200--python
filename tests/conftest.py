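import numpy as np
import pytest

from skinquant.segmentation import ColorRuleOracle
from skinquant.synthdata import SynthParams, generate_section


def make_section(seed=0, noise_std=0.0, **kw):
    """A small noise-free synthetic section (deterministic per seed)."""
    params = SynthParams(seed=seed, noise_std=noise_std, **kw)
    return generate_section(params)


@pytest.fixture(scope="session")
def clean_section():
    return make_section(seed=3)


@pytest.fixture(scope="session")
def tissue_oracle():
    return ColorRuleOracle("tissue")


@pytest.fixture(scope="session")
def cell_oracle():
    return ColorRuleOracle("cells")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
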