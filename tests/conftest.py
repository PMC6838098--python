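import numpy as np
import pytest

from invasim.meshing import TriMesh, structured_mesh


@pytest.fixture
def unit_square_mesh() -> TriMesh:
    return structured_mesh((0.0, 0.0, 1.0, 1.0), 0.25)


@pytest.fixture
def perturbed_mesh() -> TriMesh:
    """Small irregular mesh (interior nodes jittered, orientation kept)."""
    mesh = structured_mesh((0.0, 0.0, 1.0, 1.0), 0.5)
    rng = np.random.default_rng(42)
    nodes = mesh.nodes.copy()
    interior = ~mesh.boundary_flags()
    nodes[interior] += rng.uniform(-0.08, 0.08, size=(interior.sum(), 2))
    out = TriMesh(nodes=nodes, triangles=mesh.triangles)
    assert (out.signed_areas() > 0).all()
    return out


@pytest.fixture
def single_right_triangle() -> TriMesh:
    """The unit right triangle (0,0), (1,0), (0,1)."""
    return TriMesh(
        nodes=np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]]),
        triangles=np.array([[0, 1, 2]]),
    )
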