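"""Synthesis of ground-truth dense optic flow from parametric ego-motion.

A pinhole camera (90 x 90 deg field of view on a square pixel grid) moves
through a parametric depth scene along a seeded trajectory of five linear
segments (30 frames each, speeds 1-20 m/s, start height 1-5 m) joined by
3-frame transitions, 162 frames in all.  Flow between consecutive poses is
computed by back-projecting every pixel through the scene depth and
re-projecting under the next pose; displacements are expressed in angular
image coordinates (degrees/frame), so rotational flow during transitions
falls out naturally.

Conventions, used everywhere: image origin top-left, row-major; angular
coordinates are centered on the optical axis with azimuth positive
rightward and elevation positive upward, az = atan(x / f) per axis.
World frame: y up, ground plane at y = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

FPS = 30.0  #: protocol frame rate (frames per second)


# ---------------------------------------------------------------------------
# camera
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera on a square grid with a symmetric field of view."""

    grid: int = 256
    fov_deg: float = 90.0

    @property
    def degrees_per_pixel(self) -> float:
        # single global small-angle conversion factor used for pixel-unit IO
        return self.fov_deg / self.grid

    @property
    def tan_half(self) -> float:
        return math.tan(math.radians(self.fov_deg / 2.0))

    def pixel_plane_coords(self):
        """Image-plane coordinates (x right, y up) of all pixel centers, f = 1."""
        t = self.tan_half
        step = 2.0 * t / self.grid
        x = -t + step * (np.arange(self.grid) + 0.5)
        y = t - step * (np.arange(self.grid) + 0.5)
        return np.meshgrid(x, y)  # (col -> x, row -> y)

    def pixel_angles(self):
        """Per-pixel (azimuth, elevation) in degrees, exact per-axis atan mapping."""
        X, Y = self.pixel_plane_coords()
        return np.degrees(np.arctan(X)), np.degrees(np.arctan(Y))

    def ray_directions(self) -> np.ndarray:
        """Unit viewing rays in the camera frame (+z forward), shape (G, G, 3)."""
        X, Y = self.pixel_plane_coords()
        d = np.stack([X, Y, np.ones_like(X)], axis=-1)
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def pixel_ray(self, row: int, col: int) -> np.ndarray:
        """Unit viewing ray of one pixel center."""
        t = self.tan_half
        step = 2.0 * t / self.grid
        x = -t + step * (col + 0.5)
        y = t - step * (row + 0.5)
        d = np.array([x, y, 1.0])
        return d / np.linalg.norm(d)

    def project(self, points_cam: np.ndarray):
        """Angular coordinates (deg) of points in the camera frame; z <= 0 invalid."""
        z = points_cam[..., 2]
        valid = z > 0
        zsafe = np.where(valid, z, 1.0)
        az = np.degrees(np.arctan(points_cam[..., 0] / zsafe))
        el = np.degrees(np.arctan(points_cam[..., 1] / zsafe))
        return az, el, valid


@dataclass(frozen=True)
class CameraPose:
    """Camera position (meters, world frame) and camera-to-world rotation."""

    position: np.ndarray
    rotation: Rotation = field(default_factory=Rotation.identity)

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

class DepthScene:
    """Base class: a scene answers distance-to-surface queries along rays."""

    has_ground = False

    def ray_depth(self, origin: np.ndarray, dirs: np.ndarray) -> np.ndarray:
        """Distance along each unit ray to the nearest surface; inf = miss (sky)."""
        raise NotImplementedError

    def clearance(self, position: np.ndarray) -> float:
        """Distance from a camera position to the nearest scene surface."""
        return math.inf


class GroundPlaneScene(DepthScene):
    """Flat ground at y = 0; rays above the horizon miss (sky)."""

    has_ground = True

    def ray_depth(self, origin, dirs):
        dy = dirs[..., 1]
        t = np.where(dy < -1e-9, -origin[1] / np.where(dy < -1e-9, dy, -1.0), np.inf)
        return t

    def clearance(self, position):
        return float(position[1])


class FrontoparallelWallScene(DepthScene):
    """Infinite wall in the plane z = distance (world frame)."""

    def __init__(self, distance: float = 20.0):
        if distance <= 0:
            raise ValueError("wall distance must be positive")
        self.distance = float(distance)

    def ray_depth(self, origin, dirs):
        dz = dirs[..., 2]
        t = np.where(dz > 1e-9, (self.distance - origin[2]) / np.where(dz > 1e-9, dz, 1.0), np.inf)
        return np.where(t > 0, t, np.inf)

    def clearance(self, position):
        return float(self.distance - position[2])


class ClutteredScene(DepthScene):
    """Ground plane with smooth random depth modulation under an enclosing dome.

    Emulates movement through a structured environment: downward rays hit a
    ground whose depth is perturbed by a smooth multiplicative random field
    (nearby objects, surface texture), upward rays hit a distant dome (far
    walls, treeline, sky boxes) whose range is likewise modulated.  Every ray
    hits a finite positive depth, and for pure translation the rendered flow
    is exactly radial about the focus of expansion regardless of the depth
    texture.
    """

    has_ground = True

    def __init__(self, seed: int = 0, dome_radius: float = 50.0,
                 depth_jitter: float = 0.6, n_modes: int = 8):
        rng = np.random.default_rng(seed)
        self.dome_radius = float(dome_radius)
        self.depth_jitter = float(depth_jitter)
        self._freq = rng.normal(0.0, 3.0, size=(n_modes, 3))
        self._phase = rng.uniform(0.0, 2.0 * np.pi, size=n_modes)
        self._amp = rng.normal(0.0, 1.0, size=n_modes) / math.sqrt(n_modes)

    def _modulation(self, dirs: np.ndarray) -> np.ndarray:
        phase = np.tensordot(dirs, self._freq.T, axes=1) + self._phase
        f = np.sum(self._amp * np.sin(phase), axis=-1)
        return np.exp(np.clip(self.depth_jitter * f, -1.2, 1.2))

    def ray_depth(self, origin, dirs):
        mod = self._modulation(dirs)
        dy = dirs[..., 1]
        ground = np.where(dy < -1e-9, -origin[1] / np.where(dy < -1e-9, dy, -1.0), np.inf)
        # the dome occludes very oblique, distant ground rays
        depth = np.minimum(ground, self.dome_radius) * mod
        return np.maximum(depth, 0.05)

    def clearance(self, position):
        return float(position[1])


def make_scene(kind: str, seed: int = 0, **kwargs) -> DepthScene:
    """Factory for the three scene families."""
    if kind == "ground_plane":
        return GroundPlaneScene()
    if kind == "frontoparallel_wall":
        return FrontoparallelWallScene(**kwargs)
    if kind == "cluttered":
        return ClutteredScene(seed=seed, **kwargs)
    raise ValueError(f"unknown scene kind {kind!r}")


# ---------------------------------------------------------------------------
# flow fields
# ---------------------------------------------------------------------------

@dataclass
class FlowField:
    """Dense angular flow (degrees/frame) with ground-truth heading.

    ``u`` is the azimuthal and ``v`` the elevational displacement of the
    surface point seen at each pixel; ``valid`` marks pixels whose ray hit
    the scene in both frames.  ``heading_az``/``heading_el`` give the
    image-plane direction of translation (the focus of expansion for pure
    translation) in degrees.
    """

    u: np.ndarray
    v: np.ndarray
    valid: np.ndarray
    heading_az: float
    heading_el: float
    fov_deg: float = 90.0
    frame: int = 0

    def __post_init__(self):
        if self.u.shape != self.v.shape or self.u.shape != self.valid.shape:
            raise ValueError("u, v and valid must share a shape")
        if not np.all(np.isfinite(self.u[self.valid])) or not np.all(
            np.isfinite(self.v[self.valid])
        ):
            raise ValueError("flow must be finite on the valid mask")

    @property
    def grid(self) -> int:
        return self.u.shape[0]

    def speed(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


def heading_angles(direction_world: np.ndarray, rotation: Rotation):
    """Image-plane (azimuth, elevation) of a world translation direction."""
    d = rotation.inv().apply(direction_world)
    if d[2] <= 0:
        raise ValueError("heading direction lies behind the image plane")
    return (math.degrees(math.atan2(d[0], d[2])),
            math.degrees(math.atan2(d[1], d[2])))


def render_flow(scene: DepthScene, pose_t: CameraPose, pose_t1: CameraPose,
                camera: CameraModel = CameraModel(), frame: int = 0) -> FlowField:
    """Reprojection flow between two poses.

    Each pixel of frame t is back-projected through the scene depth and
    re-projected under the next pose; the flow is the difference of the
    angular image coordinates.  Rays that miss the scene (sky) or fall behind
    the next image plane are marked invalid and assigned zero flow.
    """
    dirs_cam = camera.ray_directions()
    dirs_world = pose_t.rotation.apply(dirs_cam.reshape(-1, 3)).reshape(dirs_cam.shape)
    depth = scene.ray_depth(pose_t.position, dirs_world)
    hit = np.isfinite(depth) & (depth > 0)
    dsafe = np.where(hit, depth, 1.0)
    points = pose_t.position + dsafe[..., None] * dirs_world
    pts_cam1 = pose_t1.rotation.inv().apply(
        (points - pose_t1.position).reshape(-1, 3)
    ).reshape(points.shape)
    az1, el1, front = camera.project(pts_cam1)
    az0, el0 = camera.pixel_angles()
    valid = hit & front
    u = np.where(valid, az1 - az0, 0.0)
    v = np.where(valid, el1 - el0, 0.0)
    t_world = pose_t1.position - pose_t.position
    if np.linalg.norm(t_world) == 0:
        h_az = h_el = 0.0
    else:
        h_az, h_el = heading_angles(t_world / np.linalg.norm(t_world), pose_t.rotation)
    return FlowField(u, v, valid, h_az, h_el, camera.fov_deg, frame)


def add_estimation_noise(flow: FlowField, sigma: float,
                         sky_outlier_rate: float = 0.02,
                         outlier_scale: float = 1.0,
                         seed: int = 0) -> FlowField:
    """Perturb flow like an imperfect dense estimator.

    Valid pixels get i.i.d. zero-mean Gaussian noise of ``sigma``
    degrees/frame per component; invalid (sky) pixels receive spurious
    outlier vectors at ``sky_outlier_rate`` with exponentially distributed
    magnitudes, mimicking low-contrast estimation noise.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not 0.0 <= sky_outlier_rate <= 1.0:
        raise ValueError("sky_outlier_rate must lie in [0, 1]")
    if sigma == 0 and sky_outlier_rate == 0:
        return flow
    rng = np.random.default_rng(seed)
    u = flow.u.copy()
    v = flow.v.copy()
    if sigma > 0:
        u = np.where(flow.valid, u + rng.normal(0, sigma, u.shape), u)
        v = np.where(flow.valid, v + rng.normal(0, sigma, v.shape), v)
    sky = ~flow.valid
    if sky_outlier_rate > 0 and np.any(sky):
        hits = sky & (rng.random(u.shape) < sky_outlier_rate)
        mag = rng.exponential(outlier_scale, u.shape)
        ang = rng.uniform(0, 2 * np.pi, u.shape)
        u = np.where(hits, mag * np.cos(ang), u)
        v = np.where(hits, mag * np.sin(ang), v)
    return replace(flow, u=u, v=v)


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """Seeded camera path: per-frame poses, velocities and segment labels.

    ``poses`` holds one extra pose so that every one of the ``n_frames``
    frames has a successor for flow rendering.  ``heading_az``/``heading_el``
    give the per-frame ground-truth heading in the frame's own camera
    coordinates.
    """

    poses: list
    heading_az: np.ndarray
    heading_el: np.ndarray
    speeds_mps: np.ndarray
    segment_index: np.ndarray
    is_transition: np.ndarray
    seed: int
    start_height: float
    camera: CameraModel

    @property
    def n_frames(self) -> int:
        return len(self.poses) - 1


def _rotate_towards(rot: Rotation, target_world: np.ndarray, angle_rad: float) -> Rotation:
    """Rotate the camera so its optical axis turns toward a world direction."""
    axis_now = rot.apply([0.0, 0.0, 1.0])
    cross = np.cross(axis_now, target_world)
    n = np.linalg.norm(cross)
    if n < 1e-12 or angle_rad <= 0:
        return rot
    return Rotation.from_rotvec(cross / n * angle_rad) * rot


def _slerp_dir(a: np.ndarray, b: np.ndarray, frac: float) -> np.ndarray:
    """Spherical interpolation between two unit vectors."""
    dot = float(np.clip(np.dot(a, b), -1.0, 1.0))
    theta = math.acos(dot)
    if theta < 1e-9:
        return a
    sa = math.sin((1 - frac) * theta) / math.sin(theta)
    sb = math.sin(frac * theta) / math.sin(theta)
    d = sa * a + sb * b
    return d / np.linalg.norm(d)


def make_trajectory(
    seed: int,
    camera: CameraModel = CameraModel(),
    n_segments: int = 5,
    segment_frames: int = 30,
    transition_frames: int = 3,
    speed_range: tuple = (1.0, 20.0),
    height_range: tuple = (1.0, 5.0),
    fps: float = FPS,
    reaim_fraction: float = 0.5,
    scene: DepthScene | None = None,
    min_clearance: float = 0.5,
    max_attempts: int = 200,
) -> Trajectory:
    """Sample a seeded multi-segment trajectory following the stimulus protocol.

    Each segment translates toward a heading pixel drawn uniformly from the
    current camera image at a speed drawn uniformly from ``speed_range``;
    between segments the translation direction interpolates through three
    interim headings while the camera re-aims toward the new heading by
    ``reaim_fraction`` of the heading change (introducing rotational flow
    during the transition).  Trajectories that bring the camera within
    ``min_clearance`` of the scene are rejected and re-sampled from a
    seed offset.
    """
    if not (speed_range[0] >= 0 and speed_range[1] >= speed_range[0]):
        raise ValueError("invalid speed_range")
    if not (height_range[0] > 0 and height_range[1] >= height_range[0]):
        raise ValueError("invalid height_range")
    if n_segments < 1 or segment_frames < 1 or transition_frames < 0:
        raise ValueError("invalid protocol sizes")

    for attempt in range(max_attempts):
        rng = np.random.default_rng([int(seed), attempt])
        height = float(rng.uniform(*height_range))
        pos = np.array([0.0, height, 0.0])
        rot = Rotation.identity()
        speeds = rng.uniform(*speed_range, size=n_segments)

        poses, h_az, h_el, spd, seg_ix, trans = [], [], [], [], [], []
        prev_dir = None
        prev_speed = None
        ok = True

        for k in range(n_segments):
            row, col = rng.integers(0, camera.grid, size=2)
            new_dir = rot.apply(camera.pixel_ray(int(row), int(col)))
            if k > 0 and transition_frames > 0:
                angle = math.acos(float(np.clip(
                    np.dot(rot.apply([0, 0, 1.0]), new_dir), -1, 1)))
                step_angle = reaim_fraction * angle / transition_frames
                for j in range(1, transition_frames + 1):
                    frac = j / (transition_frames + 1)
                    d = _slerp_dir(prev_dir, new_dir, frac)
                    v = prev_speed + frac * (speeds[k] - prev_speed)
                    poses.append(CameraPose(pos.copy(), rot))
                    try:
                        a, e = heading_angles(d, rot)
                    except ValueError:
                        ok = False
                        break
                    h_az.append(a); h_el.append(e)
                    spd.append(v); seg_ix.append(k + 1); trans.append(True)
                    pos = pos + (v / fps) * d
                    rot = _rotate_towards(rot, new_dir, step_angle)
                if not ok:
                    break
            for _ in range(segment_frames):
                poses.append(CameraPose(pos.copy(), rot))
                try:
                    a, e = heading_angles(new_dir, rot)
                except ValueError:
                    ok = False
                    break
                h_az.append(a); h_el.append(e)
                spd.append(speeds[k]); seg_ix.append(k + 1); trans.append(False)
                pos = pos + (speeds[k] / fps) * new_dir
            if not ok:
                break
            prev_dir, prev_speed = new_dir, speeds[k]

        if not ok:
            continue
        poses.append(CameraPose(pos.copy(), rot))  # terminal pose
        if scene is not None and any(
            scene.clearance(p.position) < min_clearance for p in poses
        ):
            continue
        return Trajectory(
            poses,
            np.asarray(h_az), np.asarray(h_el), np.asarray(spd),
            np.asarray(seg_ix, dtype=int), np.asarray(trans, dtype=bool),
            int(seed), height, camera,
        )
    raise RuntimeError(f"could not sample a collision-free trajectory for seed {seed}")


def render_trajectory(scene: DepthScene, traj: Trajectory,
                      noise_sigma: float = 0.0,
                      sky_outlier_rate: float = 0.0,
                      seed: int = 0) -> list:
    """Render the full flow sequence (one field per frame) for a trajectory."""
    fields = []
    for i in range(traj.n_frames):
        f = render_flow(scene, traj.poses[i], traj.poses[i + 1], traj.camera, frame=i)
        # ground truth from the trajectory (identical to the rendered value,
        # but kept authoritative so noise cannot touch it)
        f.heading_az = float(traj.heading_az[i])
        f.heading_el = float(traj.heading_el[i])
        if noise_sigma > 0 or sky_outlier_rate > 0:
            f = add_estimation_noise(f, noise_sigma, sky_outlier_rate,
                                     seed=np.random.SeedSequence([seed, i]).generate_state(1)[0])
        fields.append(f)
    return fields
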