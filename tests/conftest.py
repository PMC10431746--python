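import numpy as np
import pytest

from sensomap.forward import sphere_forward
from sensomap.mesh import make_cortical_mesh
from sensomap.sensors import make_helmet_array


@pytest.fixture(scope="session")
def mesh162():
    return make_cortical_mesh(subdivisions=2)


@pytest.fixture(scope="session")
def mesh642():
    return make_cortical_mesh(subdivisions=3)


@pytest.fixture(scope="session")
def helmet48():
    return make_helmet_array(n_sensors=48)


@pytest.fixture(scope="session")
def leadfield162(mesh162, helmet48):
    return sphere_forward(mesh162, helmet48, normalize=True)


@pytest.fixture(scope="session")
def strong_vertex(leadfield162):
    """Vertex best seen by the array (largest constrained column norm)."""
    return int(np.argmax(np.linalg.norm(leadfield162.constrained, axis=0)))
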