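import numpy as np
import pytest

from aqueductflow import AqueductGeometry, FluidProperties, SyntheticSpec, generate_recording


@pytest.fixture(scope="session")
def geom():
    return AqueductGeometry()


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture
def clean_spec():
    """Noise-free two-component synthetic spec, one window long."""
    return SyntheticSpec(
        duration=360.0,
        sampling_rate=200.0,
        sensor_distance_L=0.06,
        cardiac_grad_amplitude=1.5,
        cardiac_freq=1.1,
        resp_grad_amplitude=0.5,
        resp_freq=0.25,
        drift_amplitude=0.0,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def clean_recording(clean_spec):
    return generate_recording(clean_spec, patient_id="p1", start_clock="22:00:00")
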