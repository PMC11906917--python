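import numpy as np
import pytest

from anatlayout.errors import GeometryError
from anatlayout.geodesic import scalp_distance
from anatlayout.grid1020 import (
    build_grid,
    estimate_cz_initial,
    estimate_inion,
    refine_cz,
)
from anatlayout.mesh import HeadScan, build_head_mesh, project_to_scalp
from anatlayout.synthetic import SyntheticHeadSpec, make_head

from conftest import SPHERE_R, sphere_scan


def quadrant_arc_analytic(r: float) -> float:
    """Great-circle arc between adjacent landmarks at colatitude 72 deg,
    90 deg apart in azimuth (spherical law of cosines)."""
    colat = np.deg2rad(72.0)
    gamma = np.arccos(np.cos(colat) ** 2)
    return r * gamma


class TestEstimateCzInitial:
    def test_sphere_equatorial_fiducials(self, sphere_mesh_5000, sphere_scan_5000):
        cz0 = estimate_cz_initial(sphere_mesh_5000, sphere_scan_5000.fiducials)
        assert np.allclose(cz0, [0.0, 0.0, SPHERE_R], atol=1.0)

    def test_tilted_ring(self):
        spec = SyntheticHeadSpec(
            shape="sphere", semi_axes=(90.0,) * 3, n_surface_points=3000,
            fiducial_ring_tilt=10.0, seed=4,
        )
        scan = make_head(spec)
        mesh = build_head_mesh(scan)
        cz0 = estimate_cz_initial(mesh, scan.fiducials)
        t = np.deg2rad(10.0)
        expected = 90.0 * np.array([0.0, -np.sin(t), np.cos(t)])
        assert np.allclose(cz0, expected, atol=1.0)

    def test_ellipsoid_equatorial_fiducials(self):
        spec = SyntheticHeadSpec(
            shape="ellipsoid", semi_axes=(80.0, 100.0, 95.0), n_surface_points=3000, seed=4
        )
        scan = make_head(spec)
        mesh = build_head_mesh(scan)
        cz0 = estimate_cz_initial(mesh, scan.fiducials)
        assert np.allclose(cz0, [0.0, 0.0, 95.0], atol=1.0)

    def test_collinear_fiducials_rejected(self, sphere_mesh_5000):
        bad = {
            "NAS": np.array([0.0, 90.0, 0.0]),
            "INI": np.array([0.0, -90.0, 0.0]),
            "LPA": np.array([0.0, 45.0, 0.0]),
            "RPA": np.array([0.0, -45.0, 0.0]),
        }
        with pytest.raises(GeometryError):
            estimate_cz_initial(sphere_mesh_5000, bad)


class TestRefineCz:
    def test_already_converged_returns_unchanged(self, sphere_mesh_5000, sphere_scan_5000):
        cz0 = estimate_cz_initial(sphere_mesh_5000, sphere_scan_5000.fiducials)
        cz, info = refine_cz(
            sphere_mesh_5000, sphere_scan_5000.fiducials, cz0, return_info=True
        )
        assert info["iterations"] == 0
        assert np.array_equal(cz, cz0)

    def test_displaced_start_converges_to_pole(self, sphere_mesh_5000, sphere_scan_5000):
        # start 15 mm along the scalp toward LPA
        start = project_to_scalp(np.array([-15.0, 0.0, 99.0]), sphere_mesh_5000)
        cz = refine_cz(sphere_mesh_5000, sphere_scan_5000.fiducials, start)
        assert np.linalg.norm(cz - [0.0, 0.0, SPHERE_R]) < 2.0

    def test_residuals_within_tolerance_on_jittered_ellipsoid(
        self, ellipsoid_mesh, ellipsoid_scan
    ):
        fids = {k: project_to_scalp(v, ellipsoid_mesh) for k, v in ellipsoid_scan.fiducials.items()}
        # shift NAS anteriorly along the scalp to break symmetry
        fids["NAS"] = project_to_scalp(fids["NAS"] + np.array([0.0, 0.0, 12.0]), ellipsoid_mesh)
        cz0 = estimate_cz_initial(ellipsoid_mesh, fids)
        cz = refine_cz(ellipsoid_mesh, fids, cz0, tol_cz=1.0)
        d = {k: scalp_distance(ellipsoid_mesh, cz, v) for k, v in fids.items()}
        assert abs(d["NAS"] - d["INI"]) <= 1.0
        assert abs(d["LPA"] - d["RPA"]) <= 1.0


class TestEstimateInion:
    def test_sphere_mirror(self, sphere_mesh_5000, sphere_scan_5000):
        f = sphere_scan_5000.fiducials
        ini = estimate_inion(sphere_mesh_5000, f["NAS"], f["LPA"], f["RPA"])
        assert np.allclose(ini, [0.0, -SPHERE_R, 0.0], atol=1.0)

    def test_ellipsoid_lands_on_minus_y_surface(self, ellipsoid_mesh, ellipsoid_scan):
        f = ellipsoid_scan.fiducials
        ini = estimate_inion(ellipsoid_mesh, f["NAS"], f["LPA"], f["RPA"])
        assert ini[1] < -90.0
        assert abs(float(ellipsoid_mesh.signed_distance(ini[None])[0])) <= 10 * ellipsoid_mesh.eps_hull

    def test_feeds_refinement_on_jittered_heads(self):
        for seed in range(5):
            spec = SyntheticHeadSpec(
                shape="ellipsoid",
                semi_axes=(82.0, 98.0, 93.0),
                n_surface_points=800,
                surface_jitter_sd=1.5,
                seed=seed,
            )
            scan = make_head(spec)
            del scan.fiducials["INI"]
            mesh = build_head_mesh(scan)
            grid = build_grid(mesh, scan.fiducials)  # estimates INI internally
            assert "INI" in grid.fiducials


class TestBuildGrid:
    def test_sphere_landmarks_and_arcs(self, sphere_grid_5000):
        grid = sphere_grid_5000
        expected_cz_arc = 0.8 * SPHERE_R * np.pi / 2
        for lm, arc in grid.cz_arc_to_landmark.items():
            assert arc == pytest.approx(expected_cz_arc, rel=0.01), lm
        for lm, pos in grid.landmarks.items():
            colat = np.degrees(np.arccos(pos[2] / np.linalg.norm(pos)))
            assert colat == pytest.approx(72.0, abs=0.5), lm
        analytic = quadrant_arc_analytic(SPHERE_R)
        for lm, arc in grid.quadrant_arcs.items():
            assert arc == pytest.approx(analytic, rel=0.01), lm

    def test_landmark_at_point_eight_of_fiducial_arc(self, sphere_grid_5000, sphere_mesh_5000):
        grid = sphere_grid_5000
        for lm, fid in (("FPz", "NAS"), ("T3", "LPA"), ("Oz", "INI"), ("T4", "RPA")):
            d_lm = scalp_distance(grid.mesh, grid.cz, grid.landmarks[lm])
            d_fid = scalp_distance(grid.mesh, grid.cz, grid.fiducials[fid])
            assert abs(d_lm - 0.8 * d_fid) <= 0.5

    def test_circumference_closed_through_landmarks_in_order(self, sphere_grid_5000):
        grid = sphere_grid_5000
        assert np.allclose(grid.circumference[0], grid.landmarks["FPz"])
        cum = grid.circumference_cumarc
        assert cum[-1] == pytest.approx(grid.total_circumference, rel=1e-9)
        for lm in ("FPz", "T3", "Oz", "T4"):
            pos = grid.landmark_arc_positions[lm]
            idx = int(np.argmin(np.linalg.norm(grid.circumference - grid.landmarks[lm], axis=1)))
            assert cum[idx] == pytest.approx(pos, abs=1e-6)

    def test_quadrant_arcs_positive_and_consistent(self, sphere_grid_5000):
        assert all(v > 0 for v in sphere_grid_5000.quadrant_arcs.values())
        arcs = np.array(list(sphere_grid_5000.cz_arc_to_landmark.values()))
        assert arcs.std() / arcs.mean() < 0.01

    def test_mirror_symmetric_head(self, symmetric_grid, symmetric_mesh):
        grid = symmetric_grid
        d_left = scalp_distance(grid.mesh, grid.landmarks["FPz"], grid.landmarks["T3"])
        d_right = scalp_distance(grid.mesh, grid.landmarks["FPz"], grid.landmarks["T4"])
        assert d_left == pytest.approx(d_right, abs=1e-6)

    def test_scale_equivariance(self):
        scan = sphere_scan(800, seed=6)
        k = 1.3
        grid1 = build_grid(build_head_mesh(scan), scan.fiducials)
        scan_k = scan.transformed(scale=k)
        grid2 = build_grid(build_head_mesh(scan_k), scan_k.fiducials)
        for lm in grid1.quadrant_arcs:
            assert grid2.quadrant_arcs[lm] == pytest.approx(k * grid1.quadrant_arcs[lm], rel=1e-6)
            assert grid2.cz_arc_to_landmark[lm] == pytest.approx(
                k * grid1.cz_arc_to_landmark[lm], rel=1e-6
            )

    def test_determinism(self, ellipsoid_scan):
        mesh = build_head_mesh(ellipsoid_scan)
        g1 = build_grid(mesh, ellipsoid_scan.fiducials)
        g2 = build_grid(mesh, ellipsoid_scan.fiducials)
        assert np.array_equal(g1.cz, g2.cz)
        assert np.array_equal(g1.circumference, g2.circumference)
        assert g1.quadrant_arcs == g2.quadrant_arcs

    def test_json_serialisation(self, sphere_grid_5000):
        import json

        payload = json.loads(sphere_grid_5000.to_json())
        assert set(payload["landmarks"]) == {"FPz", "T3", "Oz", "T4"}
        assert np.allclose(payload["cz"], sphere_grid_5000.cz)
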