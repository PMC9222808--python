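import numpy as np
import pytest

from harpipe import (
    SensorStream,
    extract_features,
    shoaib_like_config,
    simulate_dataset,
)
from harpipe.pipeline import SHOAIB_PIPELINE


def make_stream(samples, rate_hz=50.0, label="Walk", subject="S01",
                sensor_kind="accelerometer", device="pocket", labels=None):
    samples = np.asarray(samples, dtype=float)
    if labels is None:
        labels = np.full(len(samples), label, dtype=object)
    return SensorStream(
        device_position=device,
        sensor_kind=sensor_kind,
        rate_hz=rate_hz,
        samples=samples,
        labels=np.asarray(labels, dtype=object),
        subject_id=subject,
    )


@pytest.fixture(scope="session")
def small_recordings():
    """3 subjects x 13 activities, short blocks: fast but full-structure
    (block lengths give every class >= 10 windows, enough for 10-fold)."""
    config = shoaib_like_config(seed=11, n_subjects=3, duration_scale=0.04)
    recordings, _ = simulate_dataset(config)
    return recordings


@pytest.fixture(scope="session")
def small_features(small_recordings):
    return extract_features(small_recordings, SHOAIB_PIPELINE)
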