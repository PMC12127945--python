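import numpy as np
import pytest

from cxrqc.intensity import apply_windowing
from cxrqc.synthetic import DatasetConfig, PhantomSpec, TextItem, generate_phantom


@pytest.fixture(scope="session")
def frontal_phantom():
    """Clean upright frontal phantom with its truth."""
    return generate_phantom(PhantomSpec(projection="frontal", seed=101))


@pytest.fixture(scope="session")
def lateral_phantom():
    return generate_phantom(PhantomSpec(projection="lateral", seed=102))


@pytest.fixture(scope="session")
def text_phantom():
    """Frontal phantom with a projection token and a side marker."""
    spec = PhantomSpec(
        projection="frontal", seed=103, blur_sigma=0.6,
        text_items=[TextItem("PA", 6, 6), TextItem("L", 8, 190)])
    return generate_phantom(spec)


def windowed(record):
    m = record.metadata
    return apply_windowing(record.image, m.window_center, m.window_width)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def quiet_config():
    """Generator conditions without geometric degradations."""
    return DatasetConfig(pad_prob=0.0, collim_prob=0.0, rotation_prob=0.0,
                        missing_metadata_rate=0.0)
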