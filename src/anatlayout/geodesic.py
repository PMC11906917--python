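"""On-scalp distance measurement by origin-crossing plane sections.

Any two scalp points together with the head origin define a unique plane
(unless collinear).  Because the scalp mesh is convex, the intersection of
that plane with the mesh is a closed convex planar loop; ordering the
intersection points by polar angle about the plane normal gives a strict
indexing, and summing consecutive chord lengths between the two anchor
points approximates the on-surface distance -- a digital tape measure.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .errors import GeometryError, InputError
from .mesh import HeadMesh

#: relative tolerance (x bounding-box diagonal) for on-plane tests
EPS_PLANE_REL = 1e-9

_TWO_PI = 2.0 * np.pi


@dataclass
class MeasurementPlane:
    """A plane section of the scalp mesh through the head origin.

    ``path`` is the closed loop of section points ordered by strictly
    increasing polar angle about ``normal`` (angle 0 at anchor ``a``); the
    loop implicitly closes from the last point back to the first.
    """

    normal: np.ndarray
    path: np.ndarray
    anchor_index_a: int
    anchor_index_b: int
    origin: np.ndarray
    angles: np.ndarray

    def __len__(self) -> int:
        return len(self.path)

    @property
    def a(self) -> np.ndarray:
        return self.path[self.anchor_index_a]

    @property
    def b(self) -> np.ndarray:
        return self.path[self.anchor_index_b]

    @cached_property
    def segment_lengths(self) -> np.ndarray:
        """(K,) chord lengths, entry i spanning path[i] -> path[i+1] (cyclic)."""
        nxt = np.roll(self.path, -1, axis=0)
        return np.linalg.norm(nxt - self.path, axis=1)

    @cached_property
    def total_length(self) -> float:
        return float(self.segment_lengths.sum())

    # -- arcs --------------------------------------------------------------

    def _arc_indices(self, start: str, forward: bool) -> np.ndarray:
        i = self.anchor_index_a if start == "a" else self.anchor_index_b
        j = self.anchor_index_b if start == "a" else self.anchor_index_a
        k = len(self.path)
        if forward:
            n = (j - i) % k
            return (i + np.arange(n + 1)) % k
        n = (i - j) % k
        return (i - np.arange(n + 1)) % k

    def arc(self, start: str = "a", which: str = "shorter") -> tuple[np.ndarray, float]:
        """Ordered polyline and arc length from one anchor to the other.

        ``which``: ``'forward'`` (increasing polar angle), ``'backward'``,
        or ``'shorter'``.
        """
        if start not in ("a", "b"):
            raise InputError("start must be 'a' or 'b'")
        if which == "shorter":
            fwd = self.arc_length(start, "forward")
            which = "forward" if fwd <= self.total_length - fwd else "backward"
        if which not in ("forward", "backward"):
            raise InputError("which must be 'forward', 'backward' or 'shorter'")
        idx = self._arc_indices(start, which == "forward")
        pts = self.path[idx]
        length = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
        return pts, length

    def arc_length(self, start: str = "a", which: str = "shorter") -> float:
        if which == "shorter":
            fwd = self.arc_length(start, "forward")
            return min(fwd, self.total_length - fwd)
        i = self.anchor_index_a if start == "a" else self.anchor_index_b
        j = self.anchor_index_b if start == "a" else self.anchor_index_a
        k = len(self.path)
        if which == "forward":
            n = (j - i) % k
            idx = (i + np.arange(n)) % k
        elif which == "backward":
            n = (i - j) % k
            idx = (j + np.arange(n)) % k
        else:
            raise InputError("which must be 'forward', 'backward' or 'shorter'")
        return float(self.segment_lengths[idx].sum())

    def distance(self, which: str = "shorter") -> float:
        """Tape-measure distance between the two anchors."""
        return self.arc_length("a", which)


def plane_intersection(mesh: HeadMesh, a: np.ndarray, b: np.ndarray) -> MeasurementPlane:
    """Section the mesh with the plane through ``a``, ``b`` and the origin.

    Both anchors are injected into the path exactly (not snapped to mesh
    crossings), so anchor-to-anchor distances are exact at the endpoints.
    """
    o = mesh.origin
    a = np.asarray(a, dtype=float).reshape(3)
    b = np.asarray(b, dtype=float).reshape(3)
    va, vb = a - o, b - o
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    n = np.cross(va, vb)
    nn = np.linalg.norm(n)
    if nn <= 1e-12 * na * nb or na == 0 or nb == 0:
        raise GeometryError(
            "measurement plane undefined: the two points and the origin are collinear"
        )
    n = n / nn
    eps = EPS_PLANE_REL * mesh.bbox_diagonal

    # candidate section points: mesh vertices on the plane + edge crossings
    s = (mesh.vertices - o) @ n
    cand = [mesh.vertices[np.abs(s) <= eps]]
    ei, ej = mesh.edges[:, 0], mesh.edges[:, 1]
    si, sj = s[ei], s[ej]
    crossing = ((si > eps) & (sj < -eps)) | ((si < -eps) & (sj > eps))
    if np.any(crossing):
        t = si[crossing] / (si[crossing] - sj[crossing])
        vi = mesh.vertices[ei[crossing]]
        vj = mesh.vertices[ej[crossing]]
        cand.append(vi + t[:, None] * (vj - vi))
    pts = np.vstack(cand)

    # drop candidates duplicating an anchor; anchors are inserted exactly
    merge_tol = max(eps, 1e-12)
    if len(pts):
        keep = (np.linalg.norm(pts - a, axis=1) > merge_tol) & (
            np.linalg.norm(pts - b, axis=1) > merge_tol
        )
        pts = pts[keep]

    e1 = va / na
    e2 = np.cross(n, e1)

    def _angle(q: np.ndarray) -> np.ndarray:
        w = q - o
        return np.mod(np.arctan2(w @ e2, w @ e1), _TWO_PI)

    ang_b = float(_angle(b[None])[0])
    all_pts = np.vstack([a[None], b[None], pts])
    all_ang = np.concatenate([[0.0], [ang_b], _angle(pts) if len(pts) else np.empty(0)])
    anchor_flag = np.zeros(len(all_pts), dtype=int)  # 1 -> a, 2 -> b
    anchor_flag[0], anchor_flag[1] = 1, 2

    order = np.argsort(all_ang, kind="stable")
    all_pts, all_ang, anchor_flag = all_pts[order], all_ang[order], anchor_flag[order]

    # merge consecutive duplicates (plane through a mesh vertex yields repeats),
    # never discarding an anchor
    kept_pts: list[np.ndarray] = []
    kept_ang: list[float] = []
    kept_flag: list[int] = []
    for p, th, fl in zip(all_pts, all_ang, anchor_flag):
        if kept_pts and np.linalg.norm(p - kept_pts[-1]) <= merge_tol:
            if fl and not kept_flag[-1]:
                kept_pts[-1], kept_ang[-1], kept_flag[-1] = p, th, fl
            continue
        kept_pts.append(p)
        kept_ang.append(float(th))
        kept_flag.append(int(fl))
    # cyclic wrap: last may duplicate first (anchors a != b can never be the
    # duplicated pair -- they would have failed the collinearity check)
    if len(kept_pts) > 2 and np.linalg.norm(kept_pts[-1] - kept_pts[0]) <= merge_tol:
        if kept_flag[-1] and not kept_flag[0]:
            kept_pts[0], kept_flag[0] = kept_pts[-1], kept_flag[-1]
        kept_pts.pop(), kept_ang.pop(), kept_flag.pop()

    path = np.asarray(kept_pts)
    flags = np.asarray(kept_flag)
    if len(path) < 3:
        raise GeometryError("degenerate plane section (fewer than 3 loop points)")
    idx_a = int(np.flatnonzero(flags == 1)[0])
    idx_b = int(np.flatnonzero(flags == 2)[0])
    return MeasurementPlane(
        normal=n,
        path=path,
        anchor_index_a=idx_a,
        anchor_index_b=idx_b,
        origin=o.copy(),
        angles=np.asarray(kept_ang),
    )


def scalp_distance(
    mesh: HeadMesh, a: np.ndarray, b: np.ndarray, which: str = "shorter"
) -> float:
    """On-scalp distance between two surface points (mm).

    Symmetric; by default the shorter of the two arcs around the section
    loop, matching tape-measure practice.
    """
    a = np.asarray(a, dtype=float).reshape(3)
    b = np.asarray(b, dtype=float).reshape(3)
    if np.linalg.norm(a - b) <= EPS_PLANE_REL * mesh.bbox_diagonal:
        return 0.0
    return plane_intersection(mesh, a, b).distance(which)


def point_at_arc_length(
    plane: MeasurementPlane,
    s: float,
    start: str = "a",
    which: str = "shorter",
) -> np.ndarray:
    """Point ``s`` mm along the section loop from an anchor.

    Walks in the direction of the chosen anchor-to-anchor arc but is not
    limited by the far anchor: ``s`` may continue past it around the loop
    (modulo the loop length).  Negative ``s`` walks the other way.
    """
    if which == "shorter":
        fwd = plane.arc_length(start, "forward")
        which = "forward" if fwd <= plane.total_length - fwd else "backward"
    i = plane.anchor_index_a if start == "a" else plane.anchor_index_b
    k = len(plane.path)
    step = 1 if which == "forward" else -1
    s = float(np.mod(s, plane.total_length))
    pos = i
    remaining = s
    while True:
        seg_idx = pos if step == 1 else (pos - 1) % k
        seg_len = float(plane.segment_lengths[seg_idx])
        if remaining <= seg_len or seg_len <= 0:
            nxt = (pos + step) % k
            t = remaining / seg_len if seg_len > 0 else 0.0
            return plane.path[pos] + t * (plane.path[nxt] - plane.path[pos])
        remaining -= seg_len
        pos = (pos + step) % k


def point_at_fraction(
    plane: MeasurementPlane,
    f: float,
    start: str = "a",
    which: str = "shorter",
) -> np.ndarray:
    """Point at arc-length fraction ``f`` of the anchor-to-anchor arc.

    ``f = 0`` returns the start anchor, ``f = 1`` the other anchor.
    """
    if not (0.0 <= f <= 1.0):
        raise InputError(f"fraction must be in [0, 1], got {f}")
    pts, length = plane.arc(start=start, which=which)
    if f == 0.0:
        return pts[0].copy()
    if f == 1.0:
        return pts[-1].copy()
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    target = f * length
    i = int(np.searchsorted(cum, target, side="right") - 1)
    i = min(i, len(seg) - 1)
    denom = seg[i] if seg[i] > 0 else 1.0
    t = (target - cum[i]) / denom
    return pts[i] + t * (pts[i + 1] - pts[i])
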