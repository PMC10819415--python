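import numpy as np
import pytest

from mpdeep import BeamParameters, MediumProperties


@pytest.fixture(scope="session")
def beam() -> BeamParameters:
    """Characterised instrument beam: 1040 nm focused to a 0.55 µm waist."""
    return BeamParameters()


@pytest.fixture(scope="session")
def reference_beam() -> BeamParameters:
    """Beam with the axial scale pinned by the measured focal-volume geometry."""
    return BeamParameters.from_focal_geometry()


@pytest.fixture(scope="session")
def medium() -> MediumProperties:
    """Medium-dense scattering sample: le = 120 µm, La = 0.5 mm, 10% fill."""
    return MediumProperties()


def axial_density_oracle(z, beam, order, inv_le=0.0):
    """Independent closed-form lateral reduction used by quadrature oracles."""
    w2 = beam.waist_um**2 * (1.0 + (z / beam.axial_scale_um) ** 2)
    return (beam.waist_um**2 / w2) ** order * np.pi * w2 / (2 * order) * np.exp(order * z * inv_le)
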