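import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import fiberslice as fs


def angle_between(a, b):
    return np.degrees(np.arccos(np.clip(np.dot(a, b), -1.0, 1.0)))


class TestCurve3D:
    def test_arc_length_accumulates_segment_lengths(self):
        c = fs.Curve3D([[0, 0, 0], [3, 4, 0], [3, 4, 5]])
        np.testing.assert_allclose(c.arc_length, [0, 5, 10])
        assert c.total_length == 10

    def test_coincident_consecutive_points_rejected(self):
        with pytest.raises(ValueError, match="coincide"):
            fs.Curve3D([[0, 0, 0], [0, 0, 0], [1, 0, 0]])


class TestComputeTangents:
    def test_straight_line_gives_constant_tangent(self):
        pts = np.stack([np.linspace(0, 9, 10), np.zeros(10), np.zeros(10)], 1)
        t = fs.compute_tangents(fs.Curve3D(pts))
        np.testing.assert_allclose(t, np.tile([1, 0, 0], (10, 1)), atol=1e-12)

    def test_two_point_curve_uses_one_sided_difference(self):
        t = fs.compute_tangents(fs.Curve3D([[0, 0, 0], [0, 3, 4]]))
        np.testing.assert_allclose(t, [[0, 0.6, 0.8], [0, 0.6, 0.8]])

    def test_circle_tangent_perpendicular_to_radius(self):
        th = np.deg2rad(np.arange(0, 360, 1.0))
        pts = np.stack([np.cos(th), np.sin(th), np.zeros_like(th)], 1)
        t = fs.compute_tangents(fs.Curve3D(pts))
        dots = np.abs(np.einsum("ij,ij->i", t[1:-1], pts[1:-1]))
        assert dots.max() < 1e-4


class TestRotationAboutAxis:
    def test_zero_angle_is_identity(self):
        np.testing.assert_allclose(
            fs.rotation_about_axis([0.3, -1.2, 0.5], 0.0), np.eye(3), atol=1e-12)

    def test_right_hand_sense_about_z(self):
        R = fs.rotation_about_axis([0, 0, 1], 90.0)
        np.testing.assert_allclose(R @ [1, 0, 0], [0, 1, 0], atol=1e-12)

    def test_matches_quaternion_composition(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            axis = rng.normal(size=3)
            angle = rng.uniform(-180, 180)
            R = fs.rotation_about_axis(axis, angle)
            half = Rotation.from_rotvec(
                np.deg2rad(angle / 2) * axis / np.linalg.norm(axis))
            np.testing.assert_allclose(R, (half * half).as_matrix(), atol=1e-10)

    def test_zero_axis_rejected(self):
        with pytest.raises(ValueError):
            fs.rotation_about_axis([0, 0, 0], 10.0)


class TestAlignPlaneToTangent:
    def test_z_tangent_gives_reference_axes(self):
        u, v = fs.align_plane_to_tangent([0, 0, 1])
        np.testing.assert_allclose(u, [0, 1, 0], atol=1e-12)
        np.testing.assert_allclose(np.abs(v), [1, 0, 0], atol=1e-12)

    def test_x_tangent_plane_contains_z_axis(self):
        u, v = fs.align_plane_to_tangent([1, 0, 0])
        assert abs(np.dot(u, [1, 0, 0])) < 1e-12
        assert abs(np.dot(v, [1, 0, 0])) < 1e-12

    def test_random_tangents_give_orthonormal_triads(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            t = rng.normal(size=3)
            t /= np.linalg.norm(t)
            u, v = fs.align_plane_to_tangent(t)
            for val in (np.linalg.norm(u) - 1, np.linalg.norm(v) - 1,
                        np.dot(u, v), np.dot(u, t), np.dot(v, t)):
                assert abs(val) < 1e-9


class TestConsistentFrames:
    def test_straight_line_frames_do_not_rotate(self):
        pts = np.stack([np.linspace(0, 9, 10), np.zeros(10), np.zeros(10)], 1)
        curve = fs.Curve3D(pts)
        ff = fs.propagate_consistent_frames(curve, fs.compute_tangents(curve))
        for i in range(1, 10):
            np.testing.assert_allclose(ff.normals[i], ff.normals[0], atol=1e-12)

    def test_planar_inflection_does_not_flip_normals(self):
        # the raw Frenet normal flips ~180 deg across a curvature sign change
        x = np.linspace(-5, 5, 101)
        pts = np.stack([x, x ** 3 / 25, np.zeros_like(x)], axis=1)
        curve = fs.Curve3D(pts)
        tangents = fs.compute_tangents(curve)
        ff = fs.propagate_consistent_frames(curve, tangents)
        steps = [angle_between(ff.normals[i], ff.normals[i + 1])
                 for i in range(100)]
        assert max(steps) < 5.0
        # failing baseline: normalized second differences (Frenet normals)
        sec = np.gradient(tangents, axis=0)
        mid = len(x) // 2
        n_before = sec[mid - 3] / np.linalg.norm(sec[mid - 3])
        n_after = sec[mid + 3] / np.linalg.norm(sec[mid + 3])
        assert angle_between(n_before, n_after) > 150.0

    def test_helix_beats_brute_force_grid_search(self, helix_curve):
        tangents = fs.compute_tangents(helix_curve)
        ff = fs.propagate_consistent_frames(helix_curve, tangents)
        rng = np.random.default_rng(0)
        for i in rng.choice(np.arange(1, 200), size=25, replace=False):
            u0, _ = fs.align_plane_to_tangent(tangents[i])
            best = -2.0
            for theta in range(1, 181):
                R = fs.rotation_about_axis(tangents[i], float(theta))
                cand = R @ u0
                best = max(best, np.dot(ff.normals[i - 1], cand),
                           np.dot(ff.normals[i - 1], -cand))
            achieved = np.dot(ff.normals[i - 1], ff.normals[i])
            assert achieved >= best - 1e-9

    def test_normal_turns_no_faster_than_tangent(self, helix_curve):
        tangents = fs.compute_tangents(helix_curve)
        ff = fs.propagate_consistent_frames(helix_curve, tangents)
        for i in range(len(ff) - 1):
            dn = angle_between(ff.normals[i], ff.normals[i + 1])
            dt = angle_between(tangents[i], tangents[i + 1])
            assert dn <= dt + 1e-6

    def test_degenerate_projection_falls_back_with_warning(self, caplog):
        curve = fs.Curve3D([[0, 0, 0], [0, 1, 0]])
        tangents = np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0]])
        with caplog.at_level("WARNING"):
            ff = fs.propagate_consistent_frames(curve, tangents)
        assert "degenerate" in caplog.text
        assert abs(np.dot(ff.normals[1], tangents[1])) < 1e-9

    def test_triads_orthonormal(self, helix_curve):
        tangents = fs.compute_tangents(helix_curve)
        ff = fs.propagate_consistent_frames(helix_curve, tangents)
        for i in range(len(ff)):
            M = np.stack([ff.normals[i], ff.binormals[i], ff.tangents[i]])
            np.testing.assert_allclose(M @ M.T, np.eye(3), atol=1e-6)


class TestPlaneGrid:
    def test_unit_grid_offsets(self):
        g = fs.build_plane_grid(1, 1, 1.0)
        assert g.shape == (3, 3, 2)
        np.testing.assert_allclose(sorted(set(g[..., 0].ravel())), [-1, 0, 1])
        np.testing.assert_allclose(g[1, 1], [0, 0])

    def test_center_element_always_zero(self):
        for R, C in [(1, 1), (2, 3), (5, 2)]:
            g = fs.build_plane_grid(R, C, 0.37)
            np.testing.assert_allclose(g[R, C], [0, 0], atol=1e-12)

    def test_a1_template_length(self):
        g = fs.build_plane_grid(2, 3, 0.5)
        assert g.shape[:2] == (5, 7)
        a1 = g[2, -1] - g[2, 0]
        assert np.linalg.norm(a1) == pytest.approx(3.0)

    def test_invalid_extents_rejected(self):
        with pytest.raises(ValueError):
            fs.build_plane_grid(0, 3, 1.0)


def _reslice_line(vol, n_pts=10, lo=5.0, hi=14.0, R=3, C=3, ds=0.5,
                  interp="trilinear"):
    line = fs.Curve3D(np.stack([np.linspace(lo, hi, n_pts)] * 3, axis=1))
    tangents = fs.compute_tangents(line)
    ff = fs.propagate_consistent_frames(line, tangents)
    grid = fs.build_plane_grid(R, C, ds)
    return line, fs.reslice_volume(vol, line, ff, grid, interpolation=interp)


class TestReslice:
    def test_constant_volume_reslices_to_constant(self):
        vol = fs.ImageVolume(np.full((20, 20, 20), 7.0), (1, 1, 1))
        _, stack = _reslice_line(vol)
        assert np.all(stack.intensities[stack.valid] == pytest.approx(7.0))

    def test_trilinear_exact_on_affine_field(self):
        vol = fs.ImageVolume(
            np.fromfunction(lambda z, y, x: 2 * x + 3 * y + 5 * z, (20, 20, 20)),
            (1, 1, 1))
        _, stack = _reslice_line(vol)
        grid = fs.build_plane_grid(3, 3, 0.5)
        offs = grid.reshape(-1, 2)
        for i, pl in enumerate(stack.planes):
            pts = (pl.center[None, :] + offs[:, :1] * pl.u[None, :]
                   + offs[:, 1:] * pl.v[None, :])
            analytic = 2 * pts[:, 0] + 3 * pts[:, 1] + 5 * pts[:, 2]
            got = stack.intensities[i].ravel()
            ok = stack.valid[i].ravel()
            np.testing.assert_allclose(got[ok], analytic[ok], atol=1e-6)

    def test_plane_transforms_are_rigid(self):
        vol = fs.ImageVolume(np.zeros((20, 20, 20)), (1, 1, 1))
        _, stack = _reslice_line(vol)
        for pl in stack.planes:
            F = pl.transform()
            L = F[:3, :3]
            np.testing.assert_allclose(L @ L.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(L) == pytest.approx(1.0)

    def test_out_of_volume_samples_flagged_and_filled(self):
        vol = fs.ImageVolume(np.full((8, 8, 8), 9.0), (1, 1, 1))
        line = fs.Curve3D([[1, 3.5, 3.5], [6, 3.5, 3.5]])
        tangents = fs.compute_tangents(line)
        ff = fs.propagate_consistent_frames(line, tangents)
        grid = fs.build_plane_grid(6, 6, 1.0)
        stack = fs.reslice_volume(vol, line, ff, grid)
        assert not stack.valid.all()
        assert np.all(stack.intensities[~stack.valid] == 0.0)

    def test_unknown_interpolation_rejected(self):
        vol = fs.ImageVolume(np.zeros((8, 8, 8)), (1, 1, 1))
        with pytest.raises(ValueError, match="interpolation"):
            _reslice_line(vol, lo=2, hi=5, interp="nearest")

    def test_tube_phantom_stays_centered_in_slices(self):
        spec = fs.FiberPhantomSpec(kind="straight", length_um=20, tilt_deg=0,
                                   orientation_deg=0, radius_um=3.0,
                                   contrast=100.0, blur_sigma_um=0.0,
                                   noise_sigma=0.0)
        vol, truth = fs.make_phantom(spec, shape=(96, 96, 140),
                                     spacing=(0.25,) * 3)
        curve = fs.Curve3D(truth.centerline.points[::40])
        tangents = fs.compute_tangents(curve)
        ff = fs.propagate_consistent_frames(curve, tangents)
        grid = fs.build_plane_grid(20, 20, 0.25)
        stack = fs.reslice_volume(vol, curve, ff, grid)
        ds = 0.25
        for i in range(stack.n_slices):
            sl = stack.intensities[i]
            total = sl.sum()
            assert total > 0
            rows, cols = np.mgrid[0:sl.shape[0], 0:sl.shape[1]]
            r_c = (rows * sl).sum() / total, (cols * sl).sum() / total
            center = ((sl.shape[0] - 1) / 2, (sl.shape[1] - 1) / 2)
            offset = np.hypot(r_c[0] - center[0], r_c[1] - center[1]) * ds
            assert offset < 0.5


class TestMapBack:
    def test_grid_center_maps_to_curve_point(self):
        vol = fs.ImageVolume(np.zeros((20, 20, 20)), (1, 1, 1))
        line, stack = _reslice_line(vol)
        for i in (0, 4, 9):
            np.testing.assert_allclose(
                fs.map_back([[i, 0, 0]], stack)[0], line.points[i], atol=1e-12)

    def test_rigid_round_trip(self):
        vol = fs.ImageVolume(np.zeros((20, 20, 20)), (1, 1, 1))
        _, stack = _reslice_line(vol)
        rng = np.random.default_rng(3)
        for _ in range(20):
            i = rng.integers(0, 10)
            a, b = rng.normal(size=2)
            world = fs.map_back([[i, a, b]], stack)[0]
            pl = stack.planes[i]
            rec = pl.center + a * pl.u + b * pl.v
            np.testing.assert_allclose(world, rec, atol=1e-9)

    def test_out_of_range_slice_rejected(self):
        vol = fs.ImageVolume(np.zeros((20, 20, 20)), (1, 1, 1))
        _, stack = _reslice_line(vol)
        with pytest.raises(IndexError):
            fs.map_back([[10.5, 0, 0]], stack)

    def test_segmented_tube_maps_near_true_centerline(self):
        spec = fs.FiberPhantomSpec(kind="straight", length_um=18, tilt_deg=0,
                                   orientation_deg=10, radius_um=1.5,
                                   contrast=100.0, blur_sigma_um=0.0,
                                   noise_sigma=0.0)
        vol, truth = fs.make_phantom(spec, shape=(72, 96, 96), spacing=(0.25,) * 3)
        curve = fs.Curve3D(truth.centerline.points[::30])
        tangents = fs.compute_tangents(curve)
        ff = fs.propagate_consistent_frames(curve, tangents)
        grid = fs.build_plane_grid(12, 12, 0.25)
        stack = fs.reslice_volume(vol, curve, ff, grid)
        mask = stack.intensities > 50.0
        sl, rr, cc = np.nonzero(mask)
        pts = np.stack([sl.astype(float), (cc - 12) * 0.25, (rr - 12) * 0.25], 1)
        cloud = fs.map_back(pts, stack)
        from scipy.spatial import cKDTree

        d, _ = cKDTree(truth.centerline.points).query(cloud)
        voxel_diag = np.sqrt(3) * 0.25
        assert np.mean(d <= 1.5 + voxel_diag) >= 0.95


class TestFlattenCpr:
    def test_constant_volume_flattens_constant(self):
        vol = fs.ImageVolume(np.full((20, 20, 20), 3.0), (1, 1, 1))
        _, stack = _reslice_line(vol)
        flat = fs.flatten_cpr(stack)
        inner = flat[:, 1:-1]   # edge columns may leave the volume
        np.testing.assert_allclose(inner[inner > 1.0], 3.0, atol=1e-12)

    def test_shape_is_slices_by_sweepline(self):
        vol = fs.ImageVolume(np.zeros((20, 20, 20)), (1, 1, 1))
        _, stack = _reslice_line(vol, n_pts=10, C=3)
        assert fs.flatten_cpr(stack).shape == (10, 7)

    def test_straight_tube_flattens_to_band(self):
        spec = fs.FiberPhantomSpec(kind="straight", length_um=20, tilt_deg=0,
                                   orientation_deg=0, radius_um=2.0,
                                   contrast=100.0, blur_sigma_um=0.0,
                                   noise_sigma=0.0)
        vol, truth = fs.make_phantom(spec, shape=(80, 80, 120),
                                     spacing=(0.25,) * 3)
        curve = fs.Curve3D(truth.centerline.points[::40])
        tangents = fs.compute_tangents(curve)
        ff = fs.propagate_consistent_frames(curve, tangents)
        grid = fs.build_plane_grid(16, 16, 0.25)
        stack = fs.reslice_volume(vol, curve, ff, grid)
        flat = fs.flatten_cpr(stack)
        # every row (slice) shows the bright tube around the center column
        bright = flat > 50.0
        width_rows = bright.sum(axis=1)
        expected = 2 * 2.0 / 0.25   # diameter / sample spacing
        assert np.all(width_rows >= 0.7 * expected)
        assert np.all(width_rows <= 1.3 * expected)
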