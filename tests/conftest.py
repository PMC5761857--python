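import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pcdquant import AngiogramSimSpec, CapillarySegmenter, generate_angiogram

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_angiogram():
    """One study-sized synthetic angiogram (304 px, 40% capillary fraction)."""
    return generate_angiogram(AngiogramSimSpec(capillary_fraction=0.40, seed=11))


@pytest.fixture(scope="session")
def default_segmentation(default_angiogram):
    """Full-pipeline segmentation of the default angiogram (x6 resize)."""
    img, _ = default_angiogram
    return CapillarySegmenter().fit(None).transform(img)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
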