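import numpy as np
import pytest

from cotransmap import SceneConfig, TriangleMesh, generate_scene


@pytest.fixture(scope="session")
def sphere_scene():
    """Concentric-sphere scene: 2000 A OMM, 135 A gap, no cristae."""
    cfg = SceneConfig(mesh_edge_target=100.0, rng_seed=11)
    return generate_scene(cfg)


@pytest.fixture(scope="session")
def coarse_sphere_scene():
    """Coarser concentric-sphere scene for brute-force comparisons."""
    cfg = SceneConfig(mesh_edge_target=160.0, rng_seed=12)
    return generate_scene(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def single_triangle_mesh():
    """Unit right triangle in the z=0 plane."""
    return TriangleMesh(
        vertices=np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]),
        faces=np.array([[0, 1, 2]]),
    )


def flat_grid_mesh(n: int = 20, spacing: float = 50.0) -> TriangleMesh:
    """A flat square grid in the z=0 plane, two triangles per cell."""
    xs = np.arange(n + 1) * spacing
    xv, yv = np.meshgrid(xs, xs, indexing="ij")
    verts = np.column_stack([xv.ravel(), yv.ravel(), np.zeros((n + 1) ** 2)])
    faces = []
    for i in range(n):
        for j in range(n):
            a = i * (n + 1) + j
            b = a + 1
            c = a + (n + 1)
            d = c + 1
            faces.append([a, b, d])
            faces.append([a, d, c])
    return TriangleMesh(vertices=verts, faces=np.asarray(faces))
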