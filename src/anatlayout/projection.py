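"""Anatomical 3D -> 2D sensor projection.

Every sensor is mapped *independently of all other sensors*: its scalp
projection is measured against the subject's own 10-20 frame, so the 2D
position of a channel never depends on which other channels happen to be
present.  Eccentricity is the ratio of the on-scalp distance Cz->sensor to
the on-scalp distance Cz->circumference taken in the same measurement
plane; the polar angle interpolates the crossing point's position along the
circumference between its two bracketing landmarks.

Angle convention (mathematical, counter-clockwise, nose up):
T4 (right ear) at 0 deg, FPz at 90, T3 at 180, Oz at 270.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import GeometryError, InputError
from .geodesic import plane_intersection, scalp_distance
from .grid1020 import Grid1020, build_grid
from .mesh import HeadMesh, HeadScan, build_head_mesh, project_to_scalp

#: polar-angle offset (degrees) of each quadrant's *start* landmark,
#: traversing the circumference FPz -> T3 -> Oz -> T4
QUADRANT_OFFSETS = {"FPz": 90.0, "T3": 180.0, "Oz": 270.0, "T4": 0.0}

_QUADRANT_ORDER = ("FPz", "T3", "Oz", "T4")


def eccentricity_from_distances(d_cz_sensor: float, d_cz_circumference: float) -> float:
    """Radial 2D coordinate from the two on-scalp distances.

    1.0 places the sensor on the head circle; ratios above 1 land outside
    it (face/mouth sensors).
    """
    if d_cz_circumference <= 0:
        raise InputError("distance Cz->circumference must be positive")
    if d_cz_sensor < 0:
        raise InputError("distance Cz->sensor must be non-negative")
    return d_cz_sensor / d_cz_circumference


def angle_from_arcs(arc_to_crossing: float, quadrant_arc: float, quadrant_start: str) -> float:
    """Polar angle (degrees) from the circumference-arc ratio.

    ``arc_to_crossing`` is measured along the circumference from the
    quadrant's start landmark to the crossing point; ``quadrant_arc`` is
    that quadrant's full arc.
    """
    if quadrant_start not in QUADRANT_OFFSETS:
        raise InputError(f"unknown quadrant start landmark {quadrant_start!r}")
    if quadrant_arc <= 0:
        raise InputError("quadrant arc must be positive")
    if not (0.0 <= arc_to_crossing <= quadrant_arc * (1 + 1e-9)):
        raise InputError("arc to crossing must lie within the quadrant")
    frac = arc_to_crossing / quadrant_arc
    return float(np.mod(QUADRANT_OFFSETS[quadrant_start] + 90.0 * frac, 360.0))


@dataclass
class SensorLocation2D:
    """A single channel's place on the 2D head circle."""

    label: str
    eccentricity: float
    angle: float  # degrees in [0, 360)
    xy: np.ndarray
    scalp_point: np.ndarray | None = None
    circumference_point: np.ndarray | None = None

    @classmethod
    def from_polar(cls, label: str, eccentricity: float, angle: float, **kw) -> "SensorLocation2D":
        angle = float(np.mod(angle, 360.0))
        rad = np.deg2rad(angle)
        xy = np.array([eccentricity * np.cos(rad), eccentricity * np.sin(rad)])
        return cls(label=label, eccentricity=float(eccentricity), angle=angle, xy=xy, **kw)


@dataclass
class Layout2D:
    """Ordered per-channel 2D locations plus plot-outline metadata."""

    channels: dict[str, SensorLocation2D]
    outline: dict = field(
        default_factory=lambda: {
            "radius": 1.0,
            "nose_angle": 90.0,
            "ear_angles": [180.0, 0.0],
        }
    )

    def __len__(self) -> int:
        return len(self.channels)

    def __getitem__(self, label: str) -> SensorLocation2D:
        return self.channels[label]

    @property
    def labels(self) -> list[str]:
        return list(self.channels)

    @property
    def xy(self) -> np.ndarray:
        return np.array([c.xy for c in self.channels.values()])

    def subset(self, labels: Iterable[str]) -> "Layout2D":
        labels = list(labels)
        missing = [l for l in labels if l not in self.channels]
        if missing:
            raise InputError(f"labels not in layout: {missing}")
        return Layout2D(
            channels={l: self.channels[l] for l in labels},
            outline=dict(self.outline),
        )


def _circumference_crossings(grid: Grid1020, normal: np.ndarray) -> list[tuple[float, np.ndarray]]:
    """(arc position, point) of each crossing of the measurement plane with
    the circumference polyline."""
    o = grid.mesh.origin
    pts = grid.circumference
    cum = grid.circumference_cumarc
    closed = np.vstack([pts, pts[:1]])
    sd = (closed - o) @ normal
    eps = 1e-9 * grid.mesh.bbox_diagonal
    out: list[tuple[float, np.ndarray]] = []
    m = len(pts)
    for i in range(m):
        s0, s1 = sd[i], sd[i + 1]
        if abs(s0) <= eps:
            out.append((float(cum[i]), closed[i].copy()))
        elif (s0 > eps and s1 < -eps) or (s0 < -eps and s1 > eps):
            t = s0 / (s0 - s1)
            p = closed[i] + t * (closed[i + 1] - closed[i])
            pos = float(cum[i] + t * (cum[i + 1] - cum[i]))
            out.append((pos, p))
    # dedupe near-identical crossings (plane through a polyline vertex)
    deduped: list[tuple[float, np.ndarray]] = []
    for pos, p in sorted(out, key=lambda x: x[0]):
        if deduped and np.linalg.norm(p - deduped[-1][1]) <= 10 * eps:
            continue
        deduped.append((pos, p))
    if (
        len(deduped) > 1
        and np.linalg.norm(deduped[0][1] - deduped[-1][1]) <= 10 * eps
    ):
        deduped.pop()
    return deduped


def _quadrant_of(grid: Grid1020, arc_pos: float) -> tuple[str, float]:
    """Bracketing quadrant start landmark and arc offset within it."""
    total = grid.total_circumference
    arc_pos = float(np.mod(arc_pos, total))
    for lm in reversed(_QUADRANT_ORDER):
        start = grid.landmark_arc_positions[lm]
        if arc_pos >= start - 1e-9 * total:
            return lm, max(0.0, arc_pos - start)
    return "FPz", arc_pos  # pragma: no cover - arc_pos >= 0 always matches


def locate_sensor(
    mesh: HeadMesh, grid: Grid1020, sensor: np.ndarray, label: str = ""
) -> SensorLocation2D:
    """Map one 3D sensor position to its 2D head-circle location."""
    sensor = np.asarray(sensor, dtype=float).reshape(3)
    mesh = grid.mesh  # use the Cz-augmented mesh for all measurements
    s = project_to_scalp(sensor, mesh)
    cz = grid.cz

    if np.linalg.norm(s - cz) <= 10 * mesh.eps_hull:
        # at the pole the angle is undefined; 0 by convention
        return SensorLocation2D.from_polar(label, 0.0, 0.0, scalp_point=s, circumference_point=None)

    try:
        plane = plane_intersection(mesh, cz, s)
    except GeometryError as exc:
        raise GeometryError(
            f"sensor {label!r}: scalp point is antipodal to Cz through the "
            f"origin; measurement plane undefined"
        ) from exc

    d_cz_s = plane.distance("shorter")

    crossings = _circumference_crossings(grid, plane.normal)
    if not crossings:
        raise GeometryError(
            f"sensor {label!r}: measurement plane does not cross the circumference"
        )
    # choose the crossing on the sensor's side: smallest wrapped in-plane
    # angular separation from the scalp point, angles measured about the
    # plane normal from Cz
    o = mesh.origin
    e1 = (cz - o) / np.linalg.norm(cz - o)
    e2 = np.cross(plane.normal, e1)

    def _phi(q: np.ndarray) -> float:
        w = q - o
        return float(np.arctan2(w @ e2, w @ e1))

    phi_s = _phi(s)
    best = min(
        crossings,
        key=lambda c: abs(float(np.angle(np.exp(1j * (_phi(c[1]) - phi_s))))),
    )
    arc_pos, c_pt = best

    d_cz_c = scalp_distance(mesh, cz, c_pt)
    ecc = eccentricity_from_distances(d_cz_s, d_cz_c)

    quadrant, offset_arc = _quadrant_of(grid, arc_pos)
    angle = angle_from_arcs(
        min(offset_arc, grid.quadrant_arcs[quadrant]),
        grid.quadrant_arcs[quadrant],
        quadrant,
    )
    return SensorLocation2D.from_polar(
        label, ecc, angle, scalp_point=s, circumference_point=c_pt
    )


def _sensor_table(sensors) -> pd.DataFrame:
    """Normalise sensor input to a DataFrame with label, x, y, z columns."""
    if isinstance(sensors, pd.DataFrame):
        df = sensors.copy()
        required = {"label", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise InputError(f"sensor table needs columns {sorted(required)}")
    elif isinstance(sensors, Mapping):
        rows = [
            {"label": str(k), "x": v[0], "y": v[1], "z": v[2]} for k, v in sensors.items()
        ]
        df = pd.DataFrame(rows)
    else:
        raise InputError("sensors must be a DataFrame or a mapping label -> xyz")
    df["label"] = df["label"].astype(str)
    if df["label"].duplicated().any():
        dupes = df.loc[df["label"].duplicated(), "label"].tolist()
        raise InputError(f"duplicate sensor labels: {dupes}")
    if len(df) < 1:
        raise InputError("at least one sensor is required")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(coords)):
        raise InputError("sensor coordinates contain non-finite values")
    return df


def make_layout(
    scan: HeadScan,
    sensors,
    tol_cz: float = 1.0,
    grid: Grid1020 | None = None,
) -> Layout2D:
    """Anatomical 2D layout for a labelled sensor set.

    Each channel is located independently, so any subset of sensors yields
    exactly the positions it would have had in the full array.  Pass a
    prebuilt ``grid`` to skip mesh/grid construction.
    """
    df = _sensor_table(sensors)
    if grid is None:
        mesh = build_head_mesh(scan)
        grid = build_grid(mesh, scan.fiducials, tol_cz=tol_cz)
    channels = {}
    for row in df.itertuples(index=False):
        pos = np.array([row.x, row.y, row.z], dtype=float)
        channels[row.label] = locate_sensor(grid.mesh, grid, pos, label=row.label)
    return Layout2D(channels=channels)
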