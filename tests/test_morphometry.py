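"""Mesh morphometry: centerlines, section diameters, landmark profiles."""

import numpy as np
import pandas as pd
import pytest
import trimesh

import aortameta as am
from aortameta.config import DIAMETER_NAMES, LandmarkConfig
from aortameta.morphometry import (
    agreement_report,
    cross_section_diameter,
    extract_centerline,
    find_min_diameter,
    measure_landmarks,
)


class TestCenterline:
    def test_cylinder_centerline_lies_on_axis(self, cylinder_mesh,
                                              cylinder_centerline):
        cl = cylinder_centerline
        assert float(np.max(np.linalg.norm(cl.points[:, :2], axis=1))) < 1e-3
        assert abs(cl.length - 60.0) < 0.1

    def test_quarter_torus_arc_length(self):
        theta = np.linspace(0, np.pi / 2, 200)
        centers = 20.0 * np.column_stack(
            [np.cos(theta), np.sin(theta), np.zeros_like(theta)])
        tube = am.sweep_tube(centers, np.full(200, 5.0), n_circ=48)
        cl = extract_centerline(tube, [25.0, 0.0, 0.0])
        expected = np.pi / 2 * 20.0
        assert abs(cl.length - expected) / expected < 0.01

    def test_rigid_motion_equivariance(self, cylinder_mesh):
        cl = extract_centerline(cylinder_mesh, [5.0, 0.0, 0.0])
        T = trimesh.transformations.rotation_matrix(0.7, [1, 2, 0.5],
                                                    point=[3, -2, 8])
        T[:3, 3] += [4.0, -7.0, 2.5]
        moved = cylinder_mesh.copy()
        moved.apply_transform(T)
        hint = (T @ np.array([5.0, 0.0, 0.0, 1.0]))[:3]
        cl2 = extract_centerline(moved, hint)
        assert abs(cl.length - cl2.length) / cl.length < 1e-6
        back = (np.linalg.inv(T) @ np.column_stack(
            [cl2.points, np.ones(len(cl2.points))]).T).T[:, :3]
        # same station count and matching geometry after undoing the motion
        assert len(back) == len(cl.points)
        assert float(np.abs(back - cl.points).max()) < 1e-6

    def test_arc_length_strictly_increasing(self, stenosed_centerline):
        assert np.all(np.diff(stenosed_centerline.arc_length) > 0)
        norms = np.linalg.norm(stenosed_centerline.tangents, axis=1)
        assert np.allclose(norms, 1.0, atol=1e-9)


class TestCrossSectionDiameter:
    def test_cylinder_diameter_everywhere(self, cylinder_mesh,
                                          cylinder_centerline):
        for s in (10.0, 30.0, 50.0):
            d = cross_section_diameter(cylinder_mesh, cylinder_centerline, s)
            assert abs(d - 10.0) / 10.0 < 5e-3

    def test_elliptic_section_equivalent_diameter(self):
        """Elliptic cylinder with semi-axes 4 and 9 -> 2 sqrt(ab) = 12 mm."""
        z = np.linspace(0.0, 40.0, 60)
        centers = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        tube = am.sweep_tube(centers, np.full_like(z, 1.0), n_circ=256)
        stretched = trimesh.Trimesh(
            vertices=tube.vertices * np.array([4.0, 9.0, 1.0]),
            faces=tube.faces, process=False)
        cl = extract_centerline(stretched, [4.0, 0.0, 0.0])
        d = cross_section_diameter(stretched, cl, 20.0)
        assert abs(d - 12.0) / 12.0 < 5e-3

    def test_small_plane_tilt_barely_changes_diameter(self, cylinder_mesh,
                                                      cylinder_centerline):
        from aortameta.morphometry import _section_near

        origin = cylinder_centerline.point_at(30.0)
        exact = _section_near(cylinder_mesh, origin, [0, 0, 1.0], origin)[0]
        tilted_normal = np.array([np.sin(np.radians(2.0)), 0.0,
                                  np.cos(np.radians(2.0))])
        tilted = _section_near(cylinder_mesh, origin, tilted_normal, origin)[0]
        d_exact = 2 * np.sqrt(exact / np.pi)
        d_tilted = 2 * np.sqrt(tilted / np.pi)
        assert abs(d_tilted - d_exact) / d_exact < 5e-3

    def test_out_of_range_arc_length_rejected(self, cylinder_mesh,
                                              cylinder_centerline):
        with pytest.raises(ValueError, match="outside"):
            cross_section_diameter(cylinder_mesh, cylinder_centerline, 1e4)


class TestMinDiameterSearch:
    def test_constant_tube_returns_constant(self, cylinder_mesh,
                                            cylinder_centerline):
        _, d0 = find_min_diameter(cylinder_mesh, cylinder_centerline,
                                  (10.0, 50.0))
        assert abs(d0 - 10.0) / 10.0 < 5e-3

    def test_gaussian_narrowing_depth_and_location(self):
        """Depth-0.4 narrowing of a radius-6 tube: D0 = 7.2 mm at the throat."""
        z = np.linspace(0.0, 120.0, 240)
        centers = np.column_stack([np.zeros_like(z), np.zeros_like(z), z])
        radii = 6.0 * (1.0 - 0.4 * np.exp(-0.5 * ((z - 60.0) / 5.0) ** 2))
        tube = am.sweep_tube(centers, radii, n_circ=64)
        cl = extract_centerline(tube, [6.0, 0.0, 0.0])
        s_star, d0 = find_min_diameter(tube, cl, (20.0, 100.0))
        assert abs(d0 - 7.2) / 7.2 < 0.01
        assert abs(s_star - 60.0) < 1.0

    def test_never_beats_brute_force_scan(self, stenosed_mesh,
                                          stenosed_centerline):
        cl = stenosed_centerline
        lo, hi = 0.58 * cl.length, 0.92 * cl.length
        _, d0 = find_min_diameter(stenosed_mesh, cl, (lo, hi))
        rng = np.random.default_rng(0)
        grid = np.concatenate([np.arange(lo, hi, 0.4),
                               rng.uniform(lo, hi, 60)])
        scan = [cross_section_diameter(stenosed_mesh, cl, s) for s in grid]
        assert d0 <= min(scan) * 1.005

    def test_empty_range_rejected(self, cylinder_mesh, cylinder_centerline):
        with pytest.raises(ValueError, match="range"):
            find_min_diameter(cylinder_mesh, cylinder_centerline, (30.0, 30.0))


@pytest.fixture(scope="module")
def measured(stenosed_aorta, stenosed_mesh, stenosed_centerline):
    branches = am.make_branch_meshes(stenosed_aorta)
    return measure_landmarks(stenosed_mesh, stenosed_centerline,
                             LandmarkConfig(), branches)


class TestMeasureLandmarks:
    def test_profile_matches_generator_truth(self, measured, stenosed_aorta):
        a = stenosed_aorta
        L = a.total_length
        cfg = LandmarkConfig()
        desc = np.linspace(cfg.descending_range[0] * L,
                           cfg.descending_range[1] * L, 3000)
        truth = {
            "D1": float(a.diameter(cfg.d1_offset_mm)),
            "D2": float(a.diameter(cfg.d2_fraction * L)),
            "D3": float(a.diameter(cfg.d3_fraction * L)),
            "D5": float(a.diameter(cfg.d5_fraction * L)),
            "D0": float(a.diameter(desc).min()),
            "D4": float(a.diameter(desc).max()),
            "DBCA": 5.0, "DLCCA": 3.5, "DLSCA": 4.0,
        }
        got = measured.as_dict()
        for name, expected in truth.items():
            assert abs(got[name] - expected) / expected < 0.02, name

    def test_d0_is_global_minimum_of_profile(self, measured):
        got = measured.as_dict()
        assert got["D0"] <= got["D3"] and got["D0"] <= got["D4"]

    def test_uniform_scaling_scales_all_diameters(self, stenosed_aorta,
                                                  stenosed_mesh,
                                                  stenosed_centerline):
        k = 1.7
        scaled_mesh = trimesh.Trimesh(vertices=stenosed_mesh.vertices * k,
                                      faces=stenosed_mesh.faces, process=False)
        branches = {n: trimesh.Trimesh(vertices=b.vertices * k, faces=b.faces,
                                       process=False)
                    for n, b in am.make_branch_meshes(stenosed_aorta).items()}
        cl = extract_centerline(scaled_mesh, [0.0, 2.0 * k, 0.0], step=k)
        cfg = LandmarkConfig(d1_offset_mm=10.0 * k, branch_offset_mm=2.0 * k)
        scaled = measure_landmarks(scaled_mesh, cl, cfg, branches)
        base = measure_landmarks(stenosed_mesh, stenosed_centerline,
                                 LandmarkConfig(),
                                 am.make_branch_meshes(stenosed_aorta))
        for name in DIAMETER_NAMES:
            ratio = getattr(scaled, name) / getattr(base, name)
            assert abs(ratio - k) / k < 0.02, name

    def test_no_narrowing_makes_d0_close_to_d3(self):
        a = am.SyntheticAorta()
        a.branches.extend(am.default_branches(a))
        mesh = am.make_tube_mesh(a, n_circ=48, n_axial=300)
        cl = extract_centerline(mesh, [0.0, 2.0, 0.0])
        prof = measure_landmarks(mesh, cl, LandmarkConfig(),
                                 am.make_branch_meshes(a))
        # smooth taper only: the descending minimum sits near the D3 level
        assert abs(prof.D0 - prof.D3) / prof.D3 < 0.1

    def test_missing_branch_is_named(self, stenosed_aorta, stenosed_mesh,
                                     stenosed_centerline):
        branches = am.make_branch_meshes(stenosed_aorta)
        del branches["LCCA"]
        with pytest.raises(ValueError, match="LCCA"):
            measure_landmarks(stenosed_mesh, stenosed_centerline,
                              LandmarkConfig(), branches)


class TestAgreementReport:
    def _profiles(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        base = pd.DataFrame(
            {name: rng.normal(10, 2, n).clip(1) for name in DIAMETER_NAMES})
        return base

    def test_identical_measurements_give_r_one(self):
        auto = self._profiles()
        rep = agreement_report(auto, auto.copy())
        assert np.allclose(rep["r"], 1.0)

    def test_noise_attenuates_r_to_known_factor(self):
        """manual = auto + independent noise attenuates r towards
        1/sqrt(1 + sd_noise^2/var_auto)."""
        rng = np.random.default_rng(1)
        auto = self._profiles(n=500, seed=1)
        sd_noise = 1.5
        manual = auto + rng.normal(0, sd_noise, auto.shape)
        rep = agreement_report(auto, manual)
        for name in DIAMETER_NAMES:
            expected = 1.0 / np.sqrt(1.0 + sd_noise ** 2 / auto[name].var())
            assert abs(rep.loc[name, "r"] - expected) < 0.1

    def test_constant_column_reported_as_nan_with_warning(self):
        auto = self._profiles(n=10)
        manual = auto.copy()
        manual["D3"] = 7.0
        with pytest.warns(UserWarning, match="D3"):
            rep = agreement_report(auto, manual)
        assert np.isnan(rep.loc["D3", "r"])

    def test_too_few_pairs_rejected(self):
        auto = self._profiles(n=2)
        with pytest.raises(ValueError, match="3"):
            agreement_report(auto, auto.copy())
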