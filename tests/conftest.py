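import numpy as np
import pytest
import trimesh

from densecranio.mesh_core import TriangleMesh
from densecranio.synthetic import (
    SyntheticPopulationSpec,
    generate_population,
)


@pytest.fixture(scope="session")
def sphere_mesh() -> TriangleMesh:
    """Unit-ish sphere (radius 50 mm) used as an analytic surface."""
    m = trimesh.creation.icosphere(subdivisions=2)
    return TriangleMesh(np.asarray(m.vertices) * 50.0, np.asarray(m.faces))


@pytest.fixture(scope="session")
def base_and_population():
    """Small synthetic cohort shared by registration/transfer tests."""
    spec = SyntheticPopulationSpec(n_individuals=5, seed=11)
    return generate_population(spec)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
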