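"""Subject-specific 10-20 reference frame on the scalp mesh.

Builds the vertex point Cz (equidistant along the scalp from NAS/INI and
from LPA/RPA), the four circumference landmarks FPz, T3, Oz, T4 at 80% of
the Cz->fiducial arcs, and the closed head-circumference path connecting
them.  This frame is what makes the 2D projection anatomical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import GeometryError, InputError
from .geodesic import plane_intersection, point_at_fraction, scalp_distance
from .mesh import HeadMesh, project_to_scalp

logger = logging.getLogger(__name__)

#: landmark -> source fiducial, in circumference traversal order
LANDMARK_FIDUCIALS = (("FPz", "NAS"), ("T3", "LPA"), ("Oz", "INI"), ("T4", "RPA"))

#: fraction of the Cz->fiducial arc at which circumference landmarks sit
LANDMARK_FRACTION = 0.8

DEFAULT_TOL_CZ = 1.0  # mm
DEFAULT_MAX_ITER = 100


@dataclass
class Grid1020:
    """The anatomical reference frame for 2D projection."""

    cz: np.ndarray
    landmarks: dict[str, np.ndarray]
    circumference: np.ndarray  # (M, 3) closed polyline, starts at FPz
    quadrant_arcs: dict[str, float]  # keyed by the quadrant's start landmark
    cz_arc_to_landmark: dict[str, float]
    fiducials: dict[str, np.ndarray]
    mesh: HeadMesh  # scalp mesh with Cz inserted as a vertex
    landmark_arc_positions: dict[str, float] = field(default_factory=dict)

    @property
    def total_circumference(self) -> float:
        return float(sum(self.quadrant_arcs.values()))

    @property
    def circumference_cumarc(self) -> np.ndarray:
        """(M+1,) cumulative arc length at each circumference point, the
        final entry closing the loop back to the start."""
        closed = np.vstack([self.circumference, self.circumference[:1]])
        seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def to_json(self) -> str:
        payload = {
            "cz": self.cz.tolist(),
            "landmarks": {k: v.tolist() for k, v in self.landmarks.items()},
            "circumference": self.circumference.tolist(),
            "quadrant_arcs": self.quadrant_arcs,
            "cz_arc_to_landmark": self.cz_arc_to_landmark,
            "fiducials": {k: v.tolist() for k, v in self.fiducials.items()},
            "landmark_arc_positions": self.landmark_arc_positions,
        }
        return json.dumps(payload, indent=1)


def _fid(fiducials: Mapping[str, np.ndarray], label: str) -> np.ndarray:
    try:
        return np.asarray(fiducials[label], dtype=float).reshape(3)
    except KeyError as exc:
        raise InputError(f"fiducial {label!r} required here") from exc


def superior_direction(fiducials: Mapping[str, np.ndarray]) -> np.ndarray:
    """Unit vector pointing out of the top of the head.

    With correctly labelled fiducials, (RPA - LPA) x (NAS - INI) is the
    right-handed 'rightward x forward = upward' body axis, independent of the
    numeric coordinate frame.
    """
    lr = _fid(fiducials, "RPA") - _fid(fiducials, "LPA")
    ap = _fid(fiducials, "NAS") - _fid(fiducials, "INI")
    n = np.cross(lr, ap)
    nn = np.linalg.norm(n)
    if nn <= 1e-9 * np.linalg.norm(lr) * np.linalg.norm(ap) or nn == 0:
        raise GeometryError("fiducials are collinear; superior direction undefined")
    return n / nn


def estimate_cz_initial(mesh: HeadMesh, fiducials: Mapping[str, np.ndarray]) -> np.ndarray:
    """First Cz estimate: scalp intersection of the superior axis through
    the origin."""
    up = superior_direction(fiducials)
    return project_to_scalp(mesh.origin + up * mesh.bbox_diagonal, mesh)


def estimate_inion(
    mesh: HeadMesh,
    nas: np.ndarray,
    lpa: np.ndarray,
    rpa: np.ndarray,
) -> np.ndarray:
    """Estimate INI when occluded: mirror NAS through the coronal plane
    spanned by the preauricular axis and the superior direction, then
    ray-cast back onto the scalp.

    This is an approximation -- on asymmetric heads the true inion may sit
    above or below the estimate.
    """
    nas = np.asarray(nas, dtype=float).reshape(3)
    o = mesh.origin
    axis = np.asarray(rpa, dtype=float) - np.asarray(lpa, dtype=float)
    an = np.linalg.norm(axis)
    if an == 0:
        raise GeometryError("LPA and RPA coincide")
    axis = axis / an
    w = nas - o
    w_perp = w - (w @ axis) * axis  # anterior offset of NAS from the coronal plane
    if np.linalg.norm(w_perp) <= 1e-9 * max(np.linalg.norm(w), 1.0):
        raise GeometryError("NAS lies on the preauricular axis; cannot mirror")
    mirrored = o + (w - 2.0 * w_perp)
    return project_to_scalp(mirrored, mesh)


def _pair_residuals(
    mesh: HeadMesh, cz: np.ndarray, fiducials: Mapping[str, np.ndarray]
) -> dict[str, float]:
    d = {k: scalp_distance(mesh, cz, _fid(fiducials, k)) for k in ("NAS", "INI", "LPA", "RPA")}
    return {
        "ap": d["NAS"] - d["INI"],
        "lr": d["LPA"] - d["RPA"],
    }


def refine_cz(
    mesh: HeadMesh,
    fiducials: Mapping[str, np.ndarray],
    cz0: np.ndarray,
    tol_cz: float = DEFAULT_TOL_CZ,
    max_iter: int = DEFAULT_MAX_ITER,
    return_info: bool = False,
):
    """Iteratively translate Cz along the scalp until it is equidistant
    (within ``tol_cz``) from NAS/INI and from LPA/RPA.

    Each sweep nudges Cz toward the farther fiducial of each imbalanced
    pair, along that fiducial's measurement plane, by half the distance
    imbalance -- a bisection-like contraction on a convex surface.
    """
    cz = np.asarray(cz0, dtype=float).reshape(3).copy()
    pairs = (("NAS", "INI", "ap"), ("LPA", "RPA", "lr"))
    inner_tol = 0.5 * tol_cz
    iterations = 0
    res = _pair_residuals(mesh, cz, fiducials)
    for iterations in range(max_iter):
        if all(abs(v) <= inner_tol for v in res.values()):
            break
        for p_lab, q_lab, key in pairs:
            imb = res[key]
            if abs(imb) <= inner_tol:
                continue
            far = p_lab if imb > 0 else q_lab
            plane = plane_intersection(mesh, cz, _fid(fiducials, far))
            d_far = plane.distance("shorter")
            step = min(abs(imb) / 2.0, d_far)
            cz = point_at_fraction(plane, step / d_far, start="a", which="shorter")
            res = _pair_residuals(mesh, cz, fiducials)
    else:
        res = _pair_residuals(mesh, cz, fiducials)
        if not all(abs(v) <= tol_cz for v in res.values()):
            raise GeometryError(
                "Cz refinement did not converge: residuals "
                f"NAS/INI = {res['ap']:.3f} mm, LPA/RPA = {res['lr']:.3f} mm "
                f"after {max_iter} iterations (tol {tol_cz} mm)"
            )
    if return_info:
        return cz, {"iterations": iterations, "residual_ap": res["ap"], "residual_lr": res["lr"]}
    return cz


def build_grid(
    mesh: HeadMesh,
    fiducials: Mapping[str, np.ndarray],
    tol_cz: float = DEFAULT_TOL_CZ,
    max_iter: int = DEFAULT_MAX_ITER,
) -> Grid1020:
    """Construct the full 10-20 reference frame on ``mesh``.

    If INI is absent it is estimated from the remaining three fiducials.
    Fiducials are ray-cast onto the hull surface first so that all arc
    measurements use true surface points.
    """
    fids = {k: np.asarray(v, dtype=float).reshape(3) for k, v in fiducials.items()}
    if "INI" not in fids:
        fids["INI"] = estimate_inion(mesh, fids["NAS"], fids["LPA"], fids["RPA"])
        logger.warning("INI missing: estimated from NAS/LPA/RPA at %s", fids["INI"])
    fids_s = {k: project_to_scalp(v, mesh) for k, v in fids.items()}

    cz0 = estimate_cz_initial(mesh, fids_s)
    cz, info = refine_cz(mesh, fids_s, cz0, tol_cz=tol_cz, max_iter=max_iter, return_info=True)
    logger.info(
        "Cz converged in %d iterations (residuals %.3f / %.3f mm)",
        info["iterations"], info["residual_ap"], info["residual_lr"],
    )
    mesh_cz = mesh.with_vertex(cz)

    landmarks: dict[str, np.ndarray] = {}
    cz_arcs: dict[str, float] = {}
    for lm_label, fid_label in LANDMARK_FIDUCIALS:
        plane = plane_intersection(mesh_cz, cz, fids_s[fid_label])
        d = plane.distance("shorter")
        landmarks[lm_label] = point_at_fraction(plane, LANDMARK_FRACTION, "a", "shorter")
        cz_arcs[lm_label] = LANDMARK_FRACTION * d

    order = [lm for lm, _ in LANDMARK_FIDUCIALS]
    circ_points: list[np.ndarray] = []
    quadrant_arcs: dict[str, float] = {}
    for k, start_lm in enumerate(order):
        end_lm = order[(k + 1) % len(order)]
        plane = plane_intersection(mesh_cz, landmarks[start_lm], landmarks[end_lm])
        pts, length = plane.arc(start="a", which="shorter")
        if length <= 0:
            raise GeometryError(f"degenerate circumference quadrant {start_lm}->{end_lm}")
        quadrant_arcs[start_lm] = length
        circ_points.extend(pts[:-1])  # end point opens the next quadrant
    circumference = np.asarray(circ_points)

    positions: dict[str, float] = {}
    acc = 0.0
    for lm in order:
        positions[lm] = acc
        acc += quadrant_arcs[lm]

    return Grid1020(
        cz=cz,
        landmarks=landmarks,
        circumference=circumference,
        quadrant_arcs=quadrant_arcs,
        cz_arc_to_landmark=cz_arcs,
        fiducials=fids_s,
        mesh=mesh_cz,
        landmark_arc_positions=positions,
    )
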