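"""Shared geometry fixtures (session-scoped: meshes are reused, not rebuilt)."""

import numpy as np
import pytest

from anatlayout.grid1020 import build_grid
from anatlayout.mesh import HeadScan, build_head_mesh
from anatlayout.synthetic import SyntheticHeadSpec, make_head, place_array

SPHERE_R = 100.0


def sphere_scan(n: int, r: float = SPHERE_R, seed: int = 1) -> HeadScan:
    spec = SyntheticHeadSpec(shape="sphere", semi_axes=(r, r, r), n_surface_points=n, seed=seed)
    return make_head(spec)


@pytest.fixture(scope="session")
def sphere_scan_5000():
    return sphere_scan(5000)


@pytest.fixture(scope="session")
def sphere_mesh_5000(sphere_scan_5000):
    return build_head_mesh(sphere_scan_5000)


@pytest.fixture(scope="session")
def sphere_grid_5000(sphere_mesh_5000, sphere_scan_5000):
    return build_grid(sphere_mesh_5000, sphere_scan_5000.fiducials)


@pytest.fixture(scope="session")
def ellipsoid_scan():
    """Jittered ellipsoid head: the Cz-refinement benchmark geometry."""
    spec = SyntheticHeadSpec(
        shape="ellipsoid",
        semi_axes=(80.0, 100.0, 95.0),
        n_surface_points=3000,
        surface_jitter_sd=1.0,
        seed=1,
    )
    return make_head(spec)


@pytest.fixture(scope="session")
def ellipsoid_mesh(ellipsoid_scan):
    return build_head_mesh(ellipsoid_scan)


@pytest.fixture(scope="session")
def symmetric_scan():
    """Left-right mirror-symmetric spherical head (points plus their x-mirror)."""
    base = sphere_scan(2500, seed=3)
    pts = base.points
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    return HeadScan(points=np.vstack([pts, mirrored]), fiducials=base.fiducials)


@pytest.fixture(scope="session")
def symmetric_mesh(symmetric_scan):
    return build_head_mesh(symmetric_scan)


@pytest.fixture(scope="session")
def symmetric_grid(symmetric_mesh, symmetric_scan):
    return build_grid(symmetric_mesh, symmetric_scan.fiducials)


@pytest.fixture(scope="session")
def array40(sphere_scan_5000):
    return place_array(sphere_scan_5000, 40, coverage="whole_head", standoff=6.5, seed=2)


def octahedron_mesh(scale: float = 100.0):
    from anatlayout.mesh import HeadMesh

    pts = scale * np.array(
        [
            [1, 0, 0],
            [-1, 0, 0],
            [0, 1, 0],
            [0, -1, 0],
            [0, 0, 1],
            [0, 0, -1],
        ],
        dtype=float,
    )
    return HeadMesh.from_points(pts, origin=np.zeros(3))
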