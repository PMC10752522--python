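import numpy as np
import pytest

from splenosim.geometry import CellShapeSpec, MacrophageSpec, make_rbc_mesh


@pytest.fixture(scope="session")
def biconcave_mesh_500():
    return make_rbc_mesh(CellShapeSpec(n_vertices=500), seed=0)


@pytest.fixture(scope="session")
def biconcave_mesh_small():
    return make_rbc_mesh(CellShapeSpec(n_vertices=200), seed=0)


@pytest.fixture(scope="session")
def macrophage_spec():
    return MacrophageSpec(radius=11.0, cap_height=11.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
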