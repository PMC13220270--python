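import numpy as np
import pytest

from protonpath.channel import SearchSpec, build_grid
from protonpath.kinetics import PsiCalibration, PyranineCalibration
from protonpath.synthetic import ChannelFixtureSpec, make_channel_structure


@pytest.fixture(scope="session")
def hpts_calibration():
    """The printed pyranine calibration used throughout: pH=1.931·log10(R)+7.926."""
    return PyranineCalibration(a=1.931, b=7.926)


@pytest.fixture(scope="session")
def psi_calibration():
    return PsiCalibration(slope=2000.0, intercept=0.0)


@pytest.fixture(scope="session")
def straight_fixture():
    """40 Å straight channel of 3 Å lumen through a membrane slab."""
    spec = ChannelFixtureSpec(length=40.0, lumen_radius=3.0, seed=0)
    structure, truth = make_channel_structure(spec)
    return spec, structure, truth


@pytest.fixture(scope="session")
def straight_grid(straight_fixture):
    _, structure, truth = straight_fixture
    search = SearchSpec(start=truth.point_at(truth.length / 2))
    grid = build_grid(structure, search, spacing=0.8, margin=[-2.0, -2.0, 4.0])
    return grid, search
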