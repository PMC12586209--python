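import numpy as np
import pytest

import femfall as ff


@pytest.fixture(scope="session")
def table_params() -> ff.CohortParams:
    return ff.CohortParams()


@pytest.fixture(scope="session")
def coarse_phantom_spec() -> ff.FemurPhantomSpec:
    """Small, quick phantom used by meshing/FE tests."""
    return ff.FemurPhantomSpec(
        head_radius=16.0, neck_radius=11.0, neck_length=32.0,
        neck_shaft_angle=125.0, shaft_radius=12.0, shaft_length=45.0,
        cortical_thickness=3.0, cortical_density=0.9, trabecular_density=0.3,
        voxel_spacing=3.0)


@pytest.fixture(scope="session")
def coarse_phantom(coarse_phantom_spec) -> ff.DensityVolume:
    return ff.generate_femur_phantom(coarse_phantom_spec, seed=0)


@pytest.fixture(scope="session")
def coarse_mesh(coarse_phantom) -> ff.TetMesh:
    return ff.mesh_from_volume(coarse_phantom, target_edge=8.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
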