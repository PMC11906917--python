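"""Synthetic heads, fiducials, sensor arrays, scalar fields and cohorts.

Stands in for real digitised geometry: parametric sphere/ellipsoid heads
sampled on a Fibonacci lattice with optional radial jitter, fiducials on a
(possibly tilted) canonical ring, quasi-uniform sensor arrays at a standoff
from the scalp, and smooth Gaussian-of-arc-distance per-channel fields that
emulate leadfield magnitudes.  Everything is deterministic under its seed.

Canonical frame: +x right (RPA), +y anterior (NAS), +z superior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InputError
from .geodesic import scalp_distance
from .mesh import HeadMesh, HeadScan, build_head_mesh, project_to_scalp

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class SyntheticHeadSpec:
    """Parameters of one synthetic head."""

    shape: str = "ellipsoid"  # 'sphere' | 'ellipsoid'
    semi_axes: tuple[float, float, float] = (80.0, 100.0, 95.0)
    n_surface_points: int = 2000
    surface_jitter_sd: float = 0.0
    fiducial_ring_tilt: float = 0.0  # degrees, about the LPA-RPA (x) axis
    seed: int = 0

    def __post_init__(self) -> None:
        ax = tuple(float(v) for v in self.semi_axes)
        if self.shape == "sphere":
            ax = (ax[0], ax[0], ax[0])
        elif self.shape != "ellipsoid":
            raise InputError(f"unknown shape {self.shape!r}")
        if any(v <= 0 for v in ax):
            raise InputError("semi-axes must be positive")
        if self.n_surface_points < 100:
            raise InputError("need at least 100 surface points")
        if self.surface_jitter_sd < 0:
            raise InputError("jitter sd must be >= 0")
        self.semi_axes = ax


def fibonacci_directions(n: int, z_min: float = -1.0, z_max: float = 1.0) -> np.ndarray:
    """Quasi-uniform unit directions on the sphere band z in [z_min, z_max]."""
    i = np.arange(n)
    z = z_max - (z_max - z_min) * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    az = i * GOLDEN_ANGLE
    return np.column_stack([r * np.cos(az), r * np.sin(az), z])


def _ellipsoid_surface(directions: np.ndarray, semi_axes) -> np.ndarray:
    """Radially map unit directions onto the ellipsoid surface."""
    a, b, c = semi_axes
    scale = 1.0 / np.sqrt(
        (directions[:, 0] / a) ** 2
        + (directions[:, 1] / b) ** 2
        + (directions[:, 2] / c) ** 2
    )
    return directions * scale[:, None]


def _rot_x(deg: float) -> np.ndarray:
    t = np.deg2rad(deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def make_head(spec: SyntheticHeadSpec) -> HeadScan:
    """Generate a head scan: jittered surface cloud + exact on-surface
    fiducials on the (tilted) canonical ring."""
    rng = np.random.default_rng(spec.seed)
    dirs = fibonacci_directions(spec.n_surface_points)
    pts = _ellipsoid_surface(dirs, spec.semi_axes)
    if spec.surface_jitter_sd > 0:
        radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        pts = pts + radial * rng.normal(0.0, spec.surface_jitter_sd, size=(len(pts), 1))

    ring = _rot_x(spec.fiducial_ring_tilt)
    canonical = {
        "NAS": np.array([0.0, 1.0, 0.0]),
        "INI": np.array([0.0, -1.0, 0.0]),
        "LPA": np.array([-1.0, 0.0, 0.0]),
        "RPA": np.array([1.0, 0.0, 0.0]),
    }
    fiducials = {
        k: _ellipsoid_surface((ring @ v)[None, :], spec.semi_axes)[0]
        for k, v in canonical.items()
    }
    return HeadScan(points=pts, fiducials=fiducials)


def place_array(
    scan: HeadScan,
    n_sensors: int,
    coverage: str = "whole_head",
    standoff: float = 6.5,
    seed: int = 0,
) -> pd.DataFrame:
    """Quasi-uniform labelled sensor array over the scalp.

    ``coverage='cap'`` stays above the fiducial ring; ``'whole_head'``
    extends below the circumference (face-ward sensors included).  Sensors
    sit ``standoff`` mm outward along the local face normal.
    """
    if n_sensors < 1:
        raise InputError("need at least one sensor")
    if coverage == "cap":
        z_min = 0.15
    elif coverage == "whole_head":
        z_min = -0.25
    else:
        raise InputError(f"unknown coverage {coverage!r}")
    rng = np.random.default_rng(seed)
    az0 = rng.uniform(0.0, 2.0 * np.pi)
    dirs = fibonacci_directions(n_sensors, z_min=z_min, z_max=0.995)
    c, s = np.cos(az0), np.sin(az0)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    dirs = dirs @ rot.T

    mesh = build_head_mesh(scan)
    rows = []
    for i, d in enumerate(dirs):
        hit, normal = project_to_scalp(mesh.origin + d * mesh.bbox_diagonal, mesh, return_normal=True)
        p = hit + standoff * normal
        rows.append({"label": f"S{i:02d}", "x": p[0], "y": p[1], "z": p[2]})
    return pd.DataFrame(rows)


def make_field(
    mesh_or_scan,
    sensors: pd.DataFrame,
    target_point: np.ndarray,
    sigma: float = 40.0,
) -> pd.Series:
    """Per-channel Gaussian-of-arc-distance values in (0, 1].

    Emulates a leadfield-magnitude profile peaked at the channel whose scalp
    projection is nearest (along the scalp) to the target point.
    """
    if sigma <= 0:
        raise InputError("sigma must be positive")
    mesh = mesh_or_scan if isinstance(mesh_or_scan, HeadMesh) else build_head_mesh(mesh_or_scan)
    target = project_to_scalp(np.asarray(target_point, dtype=float), mesh)
    values = {}
    for row in sensors.itertuples(index=False):
        sp = project_to_scalp(np.array([row.x, row.y, row.z]), mesh)
        d = scalp_distance(mesh, target, sp)
        values[row.label] = float(np.exp(-(d * d) / (2.0 * sigma * sigma)))
    return pd.Series(values, name="value")


@dataclass
class Subject:
    """One synthetic cohort member: geometry plus its placement transform."""

    scan: HeadScan
    sensors: pd.DataFrame
    rotation: np.ndarray
    translation: np.ndarray
    head_spec: SyntheticHeadSpec


def _random_rotation(rng: np.random.Generator, yaw_deg: float, tilt_deg: float) -> np.ndarray:
    """Head-position-like rotation: free-ish yaw, small pitch and roll."""
    yaw = np.deg2rad(rng.uniform(-yaw_deg, yaw_deg))
    pitch = np.deg2rad(rng.uniform(-tilt_deg, tilt_deg))
    roll = np.deg2rad(rng.uniform(-tilt_deg, tilt_deg))
    cz_, sz_ = np.cos(yaw), np.sin(yaw)
    cy_, sy_ = np.cos(pitch), np.sin(pitch)
    cx_, sx_ = np.cos(roll), np.sin(roll)
    rz = np.array([[cz_, -sz_, 0], [sz_, cz_, 0], [0, 0, 1.0]])
    ry = np.array([[cy_, 0, sy_], [0, 1.0, 0], [-sy_, 0, cy_]])
    rx = np.array([[1.0, 0, 0], [0, cx_, -sx_], [0, sx_, cx_]])
    return rz @ ry @ rx


def make_cohort(
    base_spec: SyntheticHeadSpec,
    n_subjects: int,
    geometry_jitter: float = 3.0,
    n_sensors: int = 56,
    coverage: str = "whole_head",
    standoff: float = 6.5,
    seed: int = 0,
    yaw_deg: float = 20.0,
    tilt_deg: float = 8.0,
) -> list[Subject]:
    """Cohort of jittered heads carrying the same nominal array.

    Per subject: random semi-axis perturbation (sd ``geometry_jitter`` mm),
    array placement in the canonical frame, then a rigid rotation plus a
    small translation applied to *all* of that subject's 3D inputs.
    """
    if n_subjects < 1:
        raise InputError("need at least one subject")
    root = np.random.SeedSequence(seed)
    subjects = []
    for si, ss in enumerate(root.spawn(n_subjects)):
        rng = np.random.default_rng(ss)
        axes = tuple(
            float(max(a + rng.normal(0.0, geometry_jitter), 40.0))
            for a in base_spec.semi_axes
        )
        spec = replace(
            base_spec,
            shape="ellipsoid",
            semi_axes=axes,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        scan = make_head(spec)
        sensors = place_array(
            scan, n_sensors, coverage=coverage, standoff=standoff,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        R = _random_rotation(rng, yaw_deg, tilt_deg)
        t = rng.uniform(-10.0, 10.0, size=3)
        scan_t = scan.transformed(rotation=R, translation=t)
        pos = sensors[["x", "y", "z"]].to_numpy() @ R.T + t
        sensors_t = sensors.copy()
        sensors_t[["x", "y", "z"]] = pos
        subjects.append(
            Subject(scan=scan_t, sensors=sensors_t, rotation=R, translation=t, head_spec=spec)
        )
    return subjects
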