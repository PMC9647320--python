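import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imsair import (
    DetectionConfig,
    DeviceConfig,
    ReferenceLibrary,
    detect_peaks,
    generate_spectrum,
)
from imsair.simulate import specs_from_library

settings.register_profile(
    "default",
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def device():
    return DeviceConfig()


@pytest.fixture(scope="session")
def library():
    return ReferenceLibrary.load_default()


@pytest.fixture(scope="session")
def composite_spectrum(library):
    """Noise-free spectrum with every library entry at amplitude 1 V."""
    return generate_spectrum(specs_from_library(library), noise_sd=0.0)


@pytest.fixture(scope="session")
def composite_peaks(composite_spectrum):
    return detect_peaks(composite_spectrum, DetectionConfig())


@pytest.fixture(scope="session")
def composite_analytes(composite_peaks):
    return [p for p in composite_peaks if not p.is_rip]
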