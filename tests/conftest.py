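import numpy as np
import pytest

from surfreho.mesh import CortexMask, icosphere
from surfreho.preprocess import SurfaceTimeSeries


@pytest.fixture(scope="session")
def ico1():
    """42-vertex icosphere, radius 30 mm."""
    return icosphere(1, 30.0)


@pytest.fixture(scope="session")
def ico2():
    """162-vertex icosphere, radius 50 mm."""
    return icosphere(2, 50.0)


@pytest.fixture(scope="session")
def ico3():
    """642-vertex icosphere, radius 50 mm (default cohort mesh)."""
    return icosphere(3, 50.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def noise_ts(ico1, rng):
    """I.i.d. noise time series on the small icosphere."""
    return SurfaceTimeSeries(
        rng.standard_normal((ico1.n_vertices, 60)), ico1, tr=2.0
    )


def regular_vertex(mesh):
    """A degree-6 vertex whose one-ring contains only degree-6 vertices.

    Such a vertex has exactly 18 two-ring neighbors (the two-ring size is
    set by the seed's and its one-ring's degrees).
    """
    from surfreho.mesh import kring_neighbors

    deg = mesh.vertex_degrees()
    for v in range(mesh.n_vertices):
        if deg[v] != 6:
            continue
        ring = kring_neighbors(mesh, v, 1)
        if all(deg[u] == 6 for u in ring):
            return v
    raise AssertionError("no regular vertex on this mesh")
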