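import numpy as np
import pytest

from eci.features import build_layout, to_spatiotemporal
from eci.model import TrainSpec, train_component
from eci.preprocess import standard_chain, window
from eci.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    # low-noise, high-SNR fixture: unit tests need decisive class structure,
    # not the harder SNR regime of the full recovery study
    return SimConfig(n_participants_per_domain=3, trials_per_session=12, seed=5,
                     noise_rms_uv=4.0)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def small_clean(small_cohort):
    clean, _log = standard_chain(small_cohort)
    return clean


@pytest.fixture(scope="session")
def layout60(small_cohort):
    return build_layout(small_cohort.channel_labels)


@pytest.fixture(scope="session")
def small_tensor(small_clean, layout60):
    return to_spatiotemporal(window(small_clean, 200.0, 400.0), layout60)


@pytest.fixture(scope="session")
def trained_awareness(small_tensor):
    return train_component(small_tensor, "awareness", TrainSpec(seed=3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)
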