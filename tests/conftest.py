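import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plaquecr import pipeline, synth

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def coincident_phantom():
    """Noiseless phantom whose POR and intensity peaks coincide (CR 1.85)."""
    spec = synth.PhantomSpec()  # defaults: both peaks at z = 40 mm, CR 1.85
    return spec, synth.simulate_phantom(spec)


@pytest.fixture(scope="session")
def coincident_profile(coincident_phantom):
    _, phantom = coincident_phantom
    return pipeline.measure_phantom_patient(phantom)


@pytest.fixture(scope="session")
def offset_phantom():
    """Noiseless phantom with the intensity peak 10 mm above the POR peak.

    Designed so the CR read at the POR-peak slice is 1.69 and at the
    intensity-peak slice 1.91.
    """
    spec = synth.PhantomSpec(
        z_por_peak=35.0, z_intensity_peak=45.0, cr_target=1.91
    )
    return spec, synth.simulate_phantom(spec)


@pytest.fixture(scope="session")
def offset_profile(offset_phantom):
    _, phantom = offset_phantom
    return pipeline.measure_phantom_patient(phantom)


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
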