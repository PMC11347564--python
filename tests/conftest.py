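import math

import numpy as np
import pytest

from oamtwist.beam_optics import BeamParameters, GridSpec, lg_field
from oamtwist.interferogram_synth import CameraModel, ReferenceWave, interfere


def make_grid(params: BeamParameters, nx: int = 256, span_rings: float = 7.0) -> GridSpec:
    """Grid whose span is ``span_rings`` doughnut radii."""
    ring = params.waist_w0 * math.sqrt(max(abs(params.ell), 1) / 2.0)
    return GridSpec(nx, nx, pitch=ring * span_rings / nx)


@pytest.fixture(scope="session")
def beam_l3() -> BeamParameters:
    return BeamParameters(wavelength=640e-9, waist_w0=1e-3, ell=3, p=0)


@pytest.fixture(scope="session")
def beam_l5() -> BeamParameters:
    return BeamParameters(wavelength=640e-9, waist_w0=1.5e-3, ell=5, p=0)


@pytest.fixture(scope="session")
def grid_l3(beam_l3) -> GridSpec:
    return make_grid(beam_l3)


@pytest.fixture(scope="session")
def grid_l5(beam_l5) -> GridSpec:
    return make_grid(beam_l5)


def petal_image(params: BeamParameters, grid: GridSpec, rotation: float = 0.0) -> np.ndarray:
    """Clean on-axis petal interferogram with the pattern rotated by ``rotation``."""
    from oamtwist.beam_optics import ComplexField

    f = lg_field(params, grid, z=0.0)
    rotated = ComplexField(
        grid=grid, z=0.0, amplitude=f.amplitude * np.exp(1j * params.ell * rotation)
    )
    img, _ = interfere(rotated, ReferenceWave(), CameraModel())
    return img
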