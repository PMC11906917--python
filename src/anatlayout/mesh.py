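"""Convex scalp surface: construction from digitised head points and queries.

The scalp model is deliberately the *convex hull* of the digitised points:
measuring along a convex surface with a plane section mimics pulling a tape
measure across the head, and concavities (eye sockets, below-ear dips) are
exactly what a tape measure bridges over.

Coordinates are millimetres throughout.  The head-centre ``origin`` is the
midpoint of the two preauricular fiducials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Mapping

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .errors import GeometryError, InputError

FIDUCIAL_LABELS = ("NAS", "INI", "LPA", "RPA")
REQUIRED_FIDUCIALS = ("NAS", "LPA", "RPA")

#: on-surface tolerance, relative to the mesh bounding-box diagonal
EPS_HULL_REL = 1e-6

#: heads smaller than this (bounding-box diagonal) are assumed to be in
#: metres by mistake and rejected
_MIN_PLAUSIBLE_DIAG_MM = 2.0


def _as_point(p, name: str = "point") -> np.ndarray:
    p = np.asarray(p, dtype=float).reshape(-1)
    if p.shape != (3,):
        raise InputError(f"{name} must be a 3-vector, got shape {p.shape}")
    if not np.all(np.isfinite(p)):
        raise InputError(f"{name} contains non-finite values: {p}")
    return p


@dataclass
class HeadScan:
    """Raw digitised head shape plus labelled fiducials, one coordinate frame.

    Parameters
    ----------
    points
        (N, 3) array of digitised head-surface coordinates in mm.
    fiducials
        Mapping with at least ``NAS``, ``LPA``, ``RPA`` (``INI`` optional),
        each a 3-vector in the same frame as ``points``.
    """

    points: np.ndarray
    fiducials: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InputError(f"points must be (N, 3), got {pts.shape}")
        if not np.all(np.isfinite(pts)):
            raise InputError("head points contain non-finite values")
        self.points = pts

        fids: dict[str, np.ndarray] = {}
        for label, coord in dict(self.fiducials).items():
            if label not in FIDUCIAL_LABELS:
                raise InputError(f"unknown fiducial label {label!r}")
            fids[label] = _as_point(coord, f"fiducial {label}")
        for label in REQUIRED_FIDUCIALS:
            if label not in fids:
                raise InputError(f"required fiducial {label!r} is missing")
        self.fiducials = fids

        allpts = np.vstack([pts, *fids.values()])
        if len(allpts) < 4:
            raise InputError("need at least 4 points to form a 3D head shape")
        diag = float(np.linalg.norm(allpts.max(axis=0) - allpts.min(axis=0)))
        if diag < _MIN_PLAUSIBLE_DIAG_MM:
            raise InputError(
                f"head extent is {diag:.3g} units -- coordinates look like "
                "metres; supply millimetres"
            )
        # rank of the centred cloud must be 3 (non-coplanar)
        centred = allpts - allpts.mean(axis=0)
        svals = np.linalg.svd(centred, compute_uv=False)
        if svals[2] <= 1e-9 * svals[0]:
            raise GeometryError("head points are (nearly) coplanar; hull is degenerate")

    @property
    def all_points(self) -> np.ndarray:
        """Head points with the fiducials appended."""
        return np.vstack([self.points, *self.fiducials.values()])

    def transformed(self, rotation=None, translation=None, scale: float = 1.0) -> "HeadScan":
        """Return a rigidly transformed / uniformly scaled copy."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else _as_point(translation, "translation")
        pts = scale * (self.points @ R.T) + t
        fids = {k: scale * (R @ v) + t for k, v in self.fiducials.items()}
        return HeadScan(points=pts, fiducials=fids)


@dataclass
class HeadMesh:
    """Convex, watertight triangular scalp mesh with an interior origin."""

    vertices: np.ndarray
    faces: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.intp)
        self.origin = _as_point(self.origin, "origin")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise InputError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise InputError("faces must be (F, 3)")
        # origin strictly inside every face half-space
        d = self.signed_distance(self.origin[None, :])[0]
        if d >= -self.eps_hull:
            raise GeometryError("origin is not strictly inside the mesh")

    # -- cached geometry ---------------------------------------------------

    @cached_property
    def bbox_diagonal(self) -> float:
        return float(
            np.linalg.norm(self.vertices.max(axis=0) - self.vertices.min(axis=0))
        )

    @cached_property
    def eps_hull(self) -> float:
        return EPS_HULL_REL * self.bbox_diagonal

    @cached_property
    def equations(self) -> np.ndarray:
        """(F, 4) outward face planes ``n . x + d = 0`` with unit ``n``."""
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        n = np.cross(b - a, c - a)
        norms = np.linalg.norm(n, axis=1)
        if np.any(norms <= 0):
            raise GeometryError("mesh contains a degenerate (zero-area) face")
        n = n / norms[:, None]
        centroid = self.vertices.mean(axis=0)
        flip = np.einsum("ij,ij->i", n, a - centroid) < 0
        n[flip] *= -1.0
        d = -np.einsum("ij,ij->i", n, a)
        return np.hstack([n, d[:, None]])

    @cached_property
    def edges(self) -> np.ndarray:
        """(E, 2) unique undirected edges (sorted vertex index pairs)."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    # -- queries -----------------------------------------------------------

    def signed_distance(self, pts: np.ndarray) -> np.ndarray:
        """Max signed distance of each point to the face half-spaces.

        Negative inside, ~0 on the surface, positive outside.
        """
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        eq = self.equations
        return (pts @ eq[:, :3].T + eq[:, 3]).max(axis=1)

    def contains(self, pts: np.ndarray, tol: float | None = None) -> np.ndarray:
        tol = self.eps_hull if tol is None else tol
        return self.signed_distance(pts) <= tol

    def surface_area(self) -> float:
        a = self.vertices[self.faces[:, 0]]
        b = self.vertices[self.faces[:, 1]]
        c = self.vertices[self.faces[:, 2]]
        return float(0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1).sum())

    def validate(self, full: bool = False) -> None:
        """Assert watertightness, Euler characteristic and (optionally)
        global convexity.  Raises :class:`GeometryError` on violation."""
        f = self.faces
        e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
        e = np.sort(e, axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        if not np.all(counts == 2):
            raise GeometryError("mesh is not watertight: edge not shared by exactly 2 faces")
        V, E, F = len(self.vertices), len(uniq), len(f)
        if V - E + F != 2:
            raise GeometryError(f"Euler characteristic {V - E + F} != 2")
        if full:
            d = self.signed_distance(self.vertices)
            if d.max() > self.eps_hull:
                raise GeometryError(
                    f"mesh not convex: vertex protrudes by {d.max():.3g} mm"
                )

    # -- modification ------------------------------------------------------

    def with_vertex(self, p: np.ndarray) -> "HeadMesh":
        """Return a copy with surface point ``p`` inserted as a mesh vertex.

        The containing face is split 1->3; if ``p`` falls on an edge the two
        adjacent faces are split 2->4, preserving watertightness.  If ``p``
        coincides with an existing vertex, the mesh is returned unchanged.
        """
        p = _as_point(p)
        if abs(float(self.signed_distance(p[None])[0])) > 10 * self.eps_hull:
            raise GeometryError("point to insert is not on the mesh surface")
        # coincides with an existing vertex?
        dv = np.linalg.norm(self.vertices - p, axis=1)
        if dv.min() <= self.eps_hull:
            return self
        # locate the face(s) whose plane contains p and whose triangle holds it
        eq = self.equations
        plane_dist = np.abs(p @ eq[:, :3].T + eq[:, 3])
        cand = np.argsort(plane_dist)[:12]
        host = None
        bary = None
        for fi in cand:
            bc = self._barycentric(int(fi), p)
            if bc is not None and bc.min() >= -1e-9:
                host, bary = int(fi), bc
                break
        if host is None:
            raise GeometryError("could not locate a face containing the point")

        new_idx = len(self.vertices)
        verts = np.vstack([self.vertices, p[None]])
        i0, i1, i2 = (int(v) for v in self.faces[host])
        on_edge = bary < 1e-9
        if np.count_nonzero(on_edge) == 1:
            # p lies on the edge opposite the near-zero barycentric vertex:
            # split both faces sharing that edge (2 -> 4)
            opp = int(np.argmax(on_edge))
            tri = [i0, i1, i2]
            e0, e1 = (tri[k] for k in range(3) if k != opp)
            vopp = tri[opp]
            nb = self._face_with_edge(e0, e1, exclude=host)
            other = next(int(v) for v in self.faces[nb] if v not in (e0, e1))
            faces = [list(f) for j, f in enumerate(self.faces) if j not in (host, nb)]
            faces += [
                [vopp, e0, new_idx],
                [vopp, new_idx, e1],
                [other, e0, new_idx],
                [other, new_idx, e1],
            ]
        else:
            faces = [list(f) for j, f in enumerate(self.faces) if j != host]
            faces += [[i0, i1, new_idx], [i1, i2, new_idx], [i2, i0, new_idx]]
        out = HeadMesh(vertices=verts, faces=np.asarray(faces, dtype=np.intp), origin=self.origin)
        out.validate(full=False)
        return out

    def _barycentric(self, fi: int, p: np.ndarray) -> np.ndarray | None:
        a, b, c = self.vertices[self.faces[fi]]
        v0, v1, v2 = b - a, c - a, p - a
        d00, d01, d11 = v0 @ v0, v0 @ v1, v1 @ v1
        d20, d21 = v2 @ v0, v2 @ v1
        den = d00 * d11 - d01 * d01
        if den <= 0:
            return None
        v = (d11 * d20 - d01 * d21) / den
        w = (d00 * d21 - d01 * d20) / den
        return np.array([1.0 - v - w, v, w])

    def _face_with_edge(self, e0: int, e1: int, exclude: int) -> int:
        for j, f in enumerate(self.faces):
            if j == exclude:
                continue
            if e0 in f and e1 in f:
                return j
        raise GeometryError("watertightness violated: edge has no second face")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_points(cls, points: np.ndarray, origin: np.ndarray) -> "HeadMesh":
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3 or len(points) < 4:
            raise InputError("need an (N>=4, 3) point array to build a hull")
        try:
            hull = ConvexHull(points)
        except QhullError as exc:
            raise GeometryError(f"convex hull failed (degenerate points?): {exc}") from exc
        keep = np.asarray(hull.vertices, dtype=np.intp)
        remap = np.full(len(points), -1, dtype=np.intp)
        remap[keep] = np.arange(len(keep))
        verts = points[keep]
        faces = remap[hull.simplices]
        mesh = cls(vertices=verts, faces=faces, origin=np.asarray(origin, dtype=float))
        mesh.validate(full=False)
        return mesh


def build_head_mesh(scan: HeadScan) -> HeadMesh:
    """Hull the digitised head points (fiducials included) into a scalp mesh.

    The origin is the midpoint of LPA and RPA.  Points interior to the hull
    are silently absorbed.
    """
    origin = 0.5 * (scan.fiducials["LPA"] + scan.fiducials["RPA"])
    mesh = HeadMesh.from_points(scan.all_points, origin)
    inside = mesh.contains(scan.all_points, tol=mesh.eps_hull)
    if not np.all(inside):
        worst = float(mesh.signed_distance(scan.all_points).max())
        raise GeometryError(f"hull does not enclose all inputs (worst {worst:.3g} mm)")
    return mesh


def project_to_scalp(p: np.ndarray, mesh: HeadMesh, return_normal: bool = False):
    """Ray-cast ``p`` onto the scalp along the line through the head origin.

    Points outside the mesh are pulled inward toward the origin; interior
    points are pushed outward away from it.  Either way the result is the
    unique intersection of the ray ``origin -> p`` with the convex surface.
    """
    p = _as_point(p, "sensor position")
    u = p - mesh.origin
    r = np.linalg.norm(u)
    if r <= mesh.eps_hull:
        raise GeometryError("cannot project the origin itself: ray undefined")
    u = u / r
    eq = mesh.equations
    num = -(eq[:, 3] + eq[:, :3] @ mesh.origin)
    den = eq[:, :3] @ u
    valid = den > 1e-15
    if not np.any(valid):
        raise GeometryError("ray does not exit the mesh (mesh corrupt?)")
    t = num[valid] / den[valid]
    k = int(np.argmin(t))
    hit = mesh.origin + float(t[k]) * u
    if return_normal:
        face_idx = np.flatnonzero(valid)[k]
        return hit, eq[face_idx, :3].copy()
    return hit
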