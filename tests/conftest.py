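import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")

from mcmflow import (
    EventTable,
    NoiseModel,
    classify_phases,
    derive_thresholds,
    model_hesc,
    simulate_negative_control,
    simulate_sample,
)


@pytest.fixture(scope="session")
def hesc_model():
    return model_hesc()


@pytest.fixture(scope="session")
def noiseless():
    return NoiseModel.noiseless()


@pytest.fixture(scope="session")
def noisy():
    return NoiseModel()


@pytest.fixture(scope="session")
def hesc_sample(hesc_model, noisy):
    """A realistic stained hESC-like sample plus its matched control."""
    sample = simulate_sample(hesc_model, noisy, 20000, seed=11, sample_id="hesc_1")
    control = simulate_negative_control(hesc_model, noisy, 20000, seed=12)
    return sample, control


@pytest.fixture(scope="session")
def hesc_calls(hesc_sample):
    sample, control = hesc_sample
    thresholds = derive_thresholds(control)
    return classify_phases(sample.events, thresholds)


def make_events(sample_id="test", **channels) -> EventTable:
    """Tiny hand-built event table; channels given as keyword arrays."""
    return EventTable(pd.DataFrame({k: np.asarray(v, dtype=float) for k, v in channels.items()}),
                      metadata={"sample_id": sample_id})
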