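import numpy as np
import pytest

from osteoplate import FemurParameterSet, design_plate
from osteoplate.bone import PlanarSurface, generate_bone_surface
from osteoplate.feature_model import complete_plate_fixture
from osteoplate.plate_geometry import build_feature_points, build_skeleton
from osteoplate.reference import PLATE_A


@pytest.fixture(scope="session")
def mean_femur():
    return FemurParameterSet.mean_shape()


@pytest.fixture(scope="session")
def mean_bone(mean_femur):
    return generate_bone_surface(mean_femur)


@pytest.fixture(scope="session")
def mean_build(mean_femur):
    """Full end-to-end build for the mean-shape femur (topology checked)."""
    return design_plate(mean_femur)


@pytest.fixture(scope="session")
def plate_a_params():
    return complete_plate_fixture(PLATE_A)


@pytest.fixture(scope="session")
def template_skeleton(plate_a_params):
    """Free-space (template mode) eagle skeleton built from Plate A."""
    grid = build_feature_points(plate_a_params, bone=None, n_profile=9)
    return build_skeleton(grid)


@pytest.fixture()
def flat_bone():
    return PlanarSurface(extent=320.0, halfwidth=40.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
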