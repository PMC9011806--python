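"""Flow synthesis: trajectory protocol, reprojection geometry, noise."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from helpers import finite_difference_oracle

from dese.flow import (CameraModel, CameraPose, ClutteredScene, FlowField,
                       FrontoparallelWallScene, GroundPlaneScene,
                       add_estimation_noise, make_scene, make_trajectory,
                       render_flow, render_trajectory)


class TestTrajectoryProtocol:
    def test_frame_count_is_162(self):
        traj = make_trajectory(0, camera=CameraModel(grid=32))
        assert traj.n_frames == 162
        assert len(traj.poses) == 163
        assert traj.segment_index.size == 162

    def test_determinism(self):
        cam = CameraModel(grid=32)
        a = make_trajectory(42, camera=cam)
        b = make_trajectory(42, camera=cam)
        for pa, pb in zip(a.poses, b.poses):
            np.testing.assert_array_equal(pa.position, pb.position)
        np.testing.assert_array_equal(a.heading_az, b.heading_az)

    def test_protocol_ranges_over_seeds(self):
        cam = CameraModel(grid=32)
        for seed in range(10):
            tr = make_trajectory(seed, camera=cam)
            assert 1.0 <= tr.start_height <= 5.0
            assert np.all(tr.speeds_mps >= 1.0) and np.all(tr.speeds_mps <= 20.0)
            assert tr.is_transition.sum() == 4 * 3
            assert set(tr.segment_index) == {1, 2, 3, 4, 5}

    def test_invalid_overrides_rejected(self):
        with pytest.raises(ValueError):
            make_trajectory(0, speed_range=(5.0, 1.0))
        with pytest.raises(ValueError):
            make_trajectory(0, height_range=(0.0, 2.0))

    def test_collision_avoidance(self):
        scene = GroundPlaneScene()
        cam = CameraModel(grid=32)
        for seed in range(5):
            tr = make_trajectory(seed, camera=cam, scene=scene)
            assert all(p.position[1] >= 0.5 for p in tr.poses)


class TestRenderFlow:
    def test_foe_is_zero_flow_point(self, small_camera, cluttered_scene):
        # translate toward a known pixel: flow there vanishes and all other
        # vectors point radially away from it
        cam = small_camera
        r, c = 5, 9
        d = cam.pixel_ray(r, c)
        p0 = CameraPose(np.array([0.0, 3.0, 0.0]))
        p1 = CameraPose(p0.position + 0.2 * d)
        f = render_flow(cluttered_scene, p0, p1, cam)
        assert abs(f.u[r, c]) < 1e-6 and abs(f.v[r, c]) < 1e-6
        az, el = cam.pixel_angles()
        daz, dele = az - az[r, c], el - el[r, c]
        radial = f.u * daz + f.v * dele
        away = radial[f.valid & (np.hypot(daz, dele) > 2.0)]
        assert np.all(away > 0)

    def test_heading_matches_foe(self, small_camera, cluttered_scene):
        cam = small_camera
        d = cam.pixel_ray(7, 3)
        p0 = CameraPose(np.array([0.0, 2.0, 0.0]))
        f = render_flow(cluttered_scene, p0, CameraPose(p0.position + 0.1 * d), cam)
        az, el = cam.pixel_angles()
        assert abs(f.heading_az - az[7, 3]) < 1e-9
        assert abs(f.heading_el - el[7, 3]) < 1e-9

    @pytest.mark.parametrize("scene_kind", ["ground_plane", "frontoparallel_wall",
                                            "cluttered"])
    def test_matches_projection_oracle(self, scene_kind):
        cam = CameraModel(grid=10)
        rng = np.random.default_rng(3)
        scene = make_scene(scene_kind, seed=11)
        for _ in range(8):
            pos = np.array([rng.uniform(-1, 1), rng.uniform(2, 4),
                            rng.uniform(-1, 1)])
            rot = Rotation.from_euler("yx", rng.uniform(-5, 5, 2), degrees=True)
            step = rng.uniform(0.05, 0.3, 3) * np.array([0.3, 0.1, 1.0])
            rot1 = rot * Rotation.from_euler("y", rng.uniform(-1, 1), degrees=True)
            p0, p1 = CameraPose(pos, rot), CameraPose(pos + step, rot1)
            f = render_flow(scene, p0, p1, cam)
            ou, ov, omask = finite_difference_oracle(scene, p0, p1, cam)
            np.testing.assert_array_equal(f.valid, omask)
            np.testing.assert_allclose(f.u[omask], ou[omask], atol=1e-6)
            np.testing.assert_allclose(f.v[omask], ov[omask], atol=1e-6)

    def test_speed_scaling_linearity(self, small_camera, cluttered_scene):
        cam = small_camera
        d = cam.pixel_ray(8, 8)
        p0 = CameraPose(np.array([0.0, 3.0, 0.0]))
        f1 = render_flow(cluttered_scene, p0, CameraPose(p0.position + 0.01 * d), cam)
        f2 = render_flow(cluttered_scene, p0, CameraPose(p0.position + 0.02 * d), cam)
        m1, m2 = f1.speed(), f2.speed()
        sel = f1.valid & (m1 > 1e-4)
        np.testing.assert_allclose(m2[sel] / m1[sel], 2.0, rtol=0.01)
        a1 = np.arctan2(f1.v[sel], f1.u[sel])
        a2 = np.arctan2(f2.v[sel], f2.u[sel])
        diff = np.degrees(np.abs(np.angle(np.exp(1j * (a2 - a1)))))
        assert np.max(diff) < 0.1

    def test_ground_plane_depth_ordering(self, ground_scene):
        # along the vertical meridian below the horizon, flow magnitude
        # decreases with distance along the ground away from the camera
        cam = CameraModel(grid=64)
        p0 = CameraPose(np.array([0.0, 2.0, 0.0]))
        p1 = CameraPose(np.array([0.0, 2.0, 0.3]))
        f = render_flow(ground_scene, p0, p1, cam)
        col = cam.grid // 2
        mags = [f.speed()[r, col] for r in range(cam.grid)
                if f.valid[r, col]]
        assert len(mags) > 10
        assert np.all(np.diff(mags) > 0)  # rows run top (far) to bottom (near)

    def test_sky_pixels_marked_invalid(self, ground_scene):
        cam = CameraModel(grid=16)
        p0 = CameraPose(np.array([0.0, 2.0, 0.0]))
        f = render_flow(ground_scene, p0, CameraPose(np.array([0.0, 2.0, 0.1])), cam)
        assert not f.valid[0].any()          # top rows look above the horizon
        assert np.all(f.u[~f.valid] == 0)

    def test_wall_vs_ground_speed_spread(self):
        # approaching a wall yields a much narrower speed distribution than
        # translating over a ground plane (gradient of depths)
        cam = CameraModel(grid=32)
        wall = FrontoparallelWallScene(distance=10.0)
        ground = GroundPlaneScene()
        p0 = CameraPose(np.array([0.0, 2.0, 0.0]))
        p1 = CameraPose(np.array([0.0, 2.0, 0.3]))
        fw = render_flow(wall, p0, p1, cam)
        fg = render_flow(ground, p0, p1, cam)
        def riqr(f):
            s = f.speed()[f.valid & (f.speed() > 0)]
            q1, q2, q3 = np.quantile(s, [0.25, 0.5, 0.75])
            return (q3 - q1) / q2
        assert riqr(fg) > 2 * riqr(fw)


class TestEstimationNoise:
    def _flow(self, grid=100):
        rng = np.random.default_rng(0)
        u = rng.normal(0, 1, (grid, grid))
        v = rng.normal(0, 1, (grid, grid))
        valid = np.ones((grid, grid), bool)
        valid[:10] = False
        return FlowField(np.where(valid, u, 0), np.where(valid, v, 0),
                         valid, 0.0, 0.0)

    def test_identity_when_disabled(self):
        f = self._flow()
        g = add_estimation_noise(f, 0.0, 0.0, seed=1)
        assert g is f

    def test_noise_sd_within_two_percent(self):
        f = self._flow(grid=340)  # ~1e5 valid pixels
        g = add_estimation_noise(f, 0.1, 0.0, seed=2)
        du = (g.u - f.u)[f.valid]
        dv = (g.v - f.v)[f.valid]
        assert du.std() == pytest.approx(0.1, rel=0.02)
        assert dv.std() == pytest.approx(0.1, rel=0.02)

    def test_determinism(self):
        f = self._flow()
        g1 = add_estimation_noise(f, 0.1, 0.05, seed=9)
        g2 = add_estimation_noise(f, 0.1, 0.05, seed=9)
        np.testing.assert_array_equal(g1.u, g2.u)
        np.testing.assert_array_equal(g1.v, g2.v)

    def test_sky_outliers_only_on_invalid_pixels(self):
        f = self._flow()
        g = add_estimation_noise(f, 0.0, 0.5, seed=3)
        assert np.any(g.u[~f.valid] != 0)
        np.testing.assert_array_equal(g.u[f.valid], f.u[f.valid])


def test_render_trajectory_produces_one_field_per_frame(cluttered_scene):
    cam = CameraModel(grid=16)
    traj = make_trajectory(1, camera=cam, scene=cluttered_scene)
    flows = render_trajectory(cluttered_scene, traj)
    assert len(flows) == traj.n_frames == 162
    assert all(f.grid == 16 for f in flows)
    # ground truth carried through
    assert flows[0].heading_az == pytest.approx(traj.heading_az[0])
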