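import numpy as np
import pytest

from sodbci.synthgen import NodeTimingModel, ParadigmConfig, SubjectProfile, default_nodes


@pytest.fixture
def cfg() -> ParadigmConfig:
    return ParadigmConfig()


@pytest.fixture
def quiet_profile() -> SubjectProfile:
    """Noiseless, jitter-free subject: ground truth is exact."""
    return SubjectProfile(
        noise_sd=0.0, p300_latency_jitter_sd=0.0, seed=0
    )


@pytest.fixture
def easy_profile() -> SubjectProfile:
    """Low-noise subject for fast, reliable pipeline tests."""
    return SubjectProfile(noise_sd=3.0, p300_latency_jitter_sd=2.0, seed=7)


@pytest.fixture
def still_nodes() -> list[NodeTimingModel]:
    """Four nodes with no delay and no flash jitter."""
    return default_nodes((0.0, 0.0, 0.0, 0.0), flash_jitter_sd=0.0)


@pytest.fixture
def delayed_nodes() -> list[NodeTimingModel]:
    """The quarter-period delay grid, without flash jitter."""
    return default_nodes((0.0, 15.625, 31.25, 46.875), flash_jitter_sd=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
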