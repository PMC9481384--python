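import numpy as np
import pytest

from midsim.community_gen import ParameterIntervals, sample_community
from midsim.core_model import CommunitySpec, NoiseSample


def single_species_community(mu=0.5, alpha=0.05, d=0.1, c=0.0, gamma=0.0,
                             Z=50.0, K=1.0, x0=1.0, S0=1e12) -> CommunitySpec:
    """One species on one substrate; defaults give a pure logistic run
    (saturated substrate, production and consumption switched off)."""
    return CommunitySpec(mu=[mu], alpha=[alpha], beta=[[0.0]], K=[[K]],
                         d=[d], c=[c], gamma=[gamma], Z=[Z],
                         r=[1.0], h=[1.0], x0=[x0], S0=[S0])


@pytest.fixture
def logistic_community() -> CommunitySpec:
    return single_species_community()


@pytest.fixture
def small_community() -> CommunitySpec:
    """Reproducible 5-species / 3-substrate community from the defaults."""
    return sample_community(5, 3, ParameterIntervals(),
                            np.random.default_rng(42))


@pytest.fixture
def medium_community() -> CommunitySpec:
    return sample_community(12, 4, ParameterIntervals(),
                            np.random.default_rng(7))


def zero_noise(M: int) -> NoiseSample:
    return NoiseSample.zeros(M)
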