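import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from densestrain import phantom as ph
from densestrain import pipeline

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

#: a typical control-like deformation: moderate contraction, twist and
#: longitudinal shortening, no scar, no wall-motion heterogeneity
CONTROL_PARAMS = {
    "contraction_ratio": 0.8,
    "twist_deg": 4.0,
    "longitudinal_stretch": 0.87,
    "scar_sectors": (),
}


@pytest.fixture(scope="session")
def control_subject():
    """Noiseless control subject (3 SA + 3 LA slices)."""
    return ph.generate_subject("ctrl", "control", dict(CONTROL_PARAMS),
                               snr=np.inf, seed=7)


@pytest.fixture(scope="session")
def control_subject_snr20():
    return ph.generate_subject("ctrl", "control", dict(CONTROL_PARAMS),
                               snr=20.0, seed=7)


@pytest.fixture(scope="session")
def control_table(control_subject):
    return pipeline.analyze_subject(control_subject, pipeline.RunConfig())


@pytest.fixture(scope="session")
def sa_geom():
    """Basal-sized short-axis annulus on the default reconstructed grid."""
    return ph.PhantomGeometry("short-axis", endo_radius_mm=25.0, epi_radius_mm=35.0)


@pytest.fixture(scope="session")
def contraction():
    """Area-preserving contraction 25 mm -> 22 mm endocardial radius."""
    return ph.DeformationParams(endo_radius_deformed_mm=22.0)
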