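"""Synthetic operating-room scene generator.

Emulates the ground-truth acquisition setup: a five-level lumbar specimen,
one four-sphere optical marker rigidly attached per vertebra, an optical
tracker streaming marker poses at ~335 Hz, two stereo RGB-D rigs recording
at 30 Hz from twelve standardized viewpoints (0, +/-15, +/-30 degrees in two
planes, 600 mm stand-off), a dual-domain calibration phantom, and fifteen
push-pin fiducials.  Every stage is driven by one seeded generator, so a
given configuration reproduces all streams, observations and depth maps
bit-identically.

The vertebra meshes are parametric stand-ins (ellipsoidal body with
posterior and transverse protrusions), not anatomical models; the pipeline
under test is geometry-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy import ndimage

from .calibration import (
    CalibrationPhantom,
    board_object_points,
    default_phantom,
    measure_phantom_pose,
    solve_extrinsic,
    truncate_rows,
)
from .geometry import (
    OTS_FRAME,
    WORLD_FRAME,
    FrameId,
    PointSet3D,
    RigidTransform,
    TimedPose,
    registration_rms,
)
from .labels import (
    DepthMap,
    MarkerAttachment,
    PoseStream,
    VertebraModel,
    merge_depth,
    render_depth,
)
from .stereo import CameraIntrinsics, PixelPoint, StereoRig, project_points

__all__ = [
    "SceneConfig",
    "ViewpointSpec",
    "SyntheticSpecimen",
    "StereoObservations",
    "SyntheticScene",
    "make_vertebra_mesh",
    "make_specimen",
    "standard_viewpoints",
    "simulate_ots_stream",
    "simulate_stereo_observations",
    "rasterize_blobs",
    "detect_blob_centroids",
    "build_scene",
]


@dataclass(frozen=True)
class SceneConfig:
    """Full synthetic-world description; identical config + seed reproduce
    every stream, image and map bit-identically.

    Rates, resolution, stand-off and viewpoint angles follow the recording
    protocol; rig intrinsics/baseline are plausible stand-ins (the protocol
    does not fix them numerically).  Noise sigmas default to a
    sub-millimetre optical tracker and noiseless pixels.
    """

    seed: int = 0
    # acquisition rates
    ots_rate_hz: float = 335.0
    rgbd_rate_hz: float = 30.0
    # stereo rig
    image_width: int = 1920
    image_height: int = 1080
    fx_px: float = 1400.0
    baseline_mm: float = 63.0
    # viewpoint geometry
    viewpoint_distance_mm: float = 600.0
    # noise model
    ots_rot_deg_sigma: float = 0.05
    ots_trans_mm_sigma: float = 0.05
    sphere_jitter_mm_sigma: float = 0.02
    pixel_sigma_px: float = 0.0
    depth_scale_bias: float = 1.0
    timestamp_jitter_frac: float = 0.0  # uniform +/- frac/2 of a sample interval
    clock_offset_s: float = 0.0
    breathing_amp_mm: float = 0.0
    breathing_hz: float = 0.25
    # specimen
    level_count: int = 5
    level_spacing_mm: float = 35.0
    mesh_subdivisions: int = 2

    def __post_init__(self) -> None:
        if self.ots_rate_hz <= 0 or self.rgbd_rate_hz <= 0:
            raise ValueError("rates must be positive")
        for name in ("ots_rot_deg_sigma", "ots_trans_mm_sigma", "sphere_jitter_mm_sigma", "pixel_sigma_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.depth_scale_bias <= 0:
            raise ValueError("depth_scale_bias must be positive")

    def intrinsics(self) -> CameraIntrinsics:
        return CameraIntrinsics(
            fx=self.fx_px,
            fy=self.fx_px,
            cx=(self.image_width - 1) / 2.0,
            cy=(self.image_height - 1) / 2.0,
            width=self.image_width,
            height=self.image_height,
        )

    def rig(self, sensor_frame: FrameId = "S1") -> StereoRig:
        return StereoRig.rectified(self.intrinsics(), self.baseline_mm, sensor_frame)


@dataclass(frozen=True)
class ViewpointSpec:
    """One standardized rig placement: stereo baseline aligned with the
    axial-coronal or sagittal-coronal plane intersection, inclined by the
    given angle, facing ``target`` from ``distance_mm`` away."""

    plane: str  # "axial-coronal" | "sagittal-coronal"
    angle_deg: float
    sensor: FrameId
    target: np.ndarray = field(default_factory=lambda: np.zeros(3))
    distance_mm: float = 600.0

    def __post_init__(self) -> None:
        if self.plane not in ("axial-coronal", "sagittal-coronal"):
            raise ValueError(f"unknown plane {self.plane!r}")
        object.__setattr__(self, "target", np.asarray(self.target, dtype=float).reshape(3))

    @property
    def position(self) -> np.ndarray:
        up = np.array([0.0, 0.0, 1.0])
        tilt = np.array([0.0, 1.0, 0.0]) if self.plane == "axial-coronal" else np.array([1.0, 0.0, 0.0])
        a = np.deg2rad(self.angle_deg)
        return self.target + self.distance_mm * (np.cos(a) * up + np.sin(a) * tilt)

    def world_from_sensor(self) -> RigidTransform:
        """Rig pose: +z optical axis toward the target, +x along the
        stereo baseline (the plane-intersection axis), +y completing a
        right-handed, y-down camera frame."""
        pos = self.position
        z_cam = self.target - pos
        z_cam = z_cam / np.linalg.norm(z_cam)
        x_cam = (
            np.array([1.0, 0.0, 0.0])
            if self.plane == "axial-coronal"
            else np.array([0.0, 1.0, 0.0])
        )
        y_cam = np.cross(z_cam, x_cam)
        R = np.stack([x_cam, y_cam, z_cam], axis=1)
        return RigidTransform(R, pos, source=self.sensor, target=WORLD_FRAME)


def standard_viewpoints(
    center: np.ndarray | None = None, distance_mm: float = 600.0
) -> list[ViewpointSpec]:
    """The twelve standardized static-scene viewpoints, six per sensor:
    for each of the two plane alignments, both sensors at 0 degrees, then
    +15/-15 and +30/-30 split between sensor 1 (positive) and sensor 2
    (negative) inclination."""
    center = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    out: list[ViewpointSpec] = []
    for plane in ("axial-coronal", "sagittal-coronal"):
        for angle, sensor in (
            (0.0, "S1"),
            (0.0, "S2"),
            (15.0, "S1"),
            (-15.0, "S2"),
            (30.0, "S1"),
            (-30.0, "S2"),
        ):
            out.append(
                ViewpointSpec(
                    plane=plane,
                    angle_deg=angle,
                    sensor=sensor,
                    target=center,
                    distance_mm=distance_mm,
                )
            )
    return out


# ---------------------------------------------------------------------------
# specimen


def make_vertebra_mesh(level_index: int, resolution: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Closed parametric vertebra stand-in: an ellipsoidal body with a
    posterior (spinous) and two lateral (transverse) radial bumps.

    Built by radially displacing an icosphere, so the mesh stays watertight
    and genus zero.  Deterministic for fixed inputs; size varies slightly
    with ``level_index`` (1-based, caudal levels larger).
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    base = trimesh.creation.icosphere(subdivisions=resolution, radius=1.0)
    dirs = np.asarray(base.vertices, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

    a = 20.0 + 0.8 * level_index  # lateral
    b = 14.0 + 0.5 * level_index  # cranio-caudal
    c = 12.0 + 0.4 * level_index  # antero-posterior
    r_ell = 1.0 / np.sqrt(
        (dirs[:, 0] / a) ** 2 + (dirs[:, 1] / b) ** 2 + (dirs[:, 2] / c) ** 2
    )

    def bump(direction: np.ndarray, amp: float, width: float) -> np.ndarray:
        cosang = dirs @ direction
        ang = np.arccos(np.clip(cosang, -1, 1))
        return amp * np.exp(-((ang / width) ** 2))

    r = (
        r_ell
        + bump(np.array([0.0, 0.0, 1.0]), 12.0, 0.45)  # spinous process (posterior, +z)
        + bump(np.array([1.0, 0.0, 0.0]), 8.0, 0.40)  # right transverse process
        + bump(np.array([-1.0, 0.0, 0.0]), 8.0, 0.40)  # left transverse process
    )
    vertices = dirs * r[:, None]
    return vertices, np.asarray(base.faces, dtype=int)


def _surface_point(vertices: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """The mesh vertex farthest along ``direction`` — guaranteed to lie on
    the surface (used for push-pin placement)."""
    d = np.asarray(direction, dtype=float)
    return vertices[int(np.argmax(vertices @ d))].copy()


def _marker_sphere_layout(level_index: int) -> np.ndarray:
    """Four co-planar sphere centres in the marker frame, centroid at the
    origin.  The layout varies with the level so the inter-sphere distance
    multisets are pairwise distinct (unambiguous marker identification)."""
    j = level_index
    raw = np.array(
        [
            [0.0, 0.0, 0.0],
            [52.0 + 5.0 * j, 6.0, 0.0],
            [26.0, 42.0 + 4.0 * j, 0.0],
            [-18.0 - 3.0 * j, 30.0, 0.0],
        ]
    )
    return raw - raw.mean(axis=0)


@dataclass(frozen=True)
class SyntheticSpecimen:
    """Five instrumented levels with ground-truth world poses of every frame."""

    models: dict[FrameId, VertebraModel]
    attachments: dict[FrameId, MarkerAttachment]
    level_world: dict[FrameId, RigidTransform]  # world <- Lj
    marker_world: dict[FrameId, RigidTransform]  # world <- Mj
    marker_spheres: dict[FrameId, PointSet3D]  # in marker frame
    pushpins_level: dict[FrameId, PointSet3D]  # 3 pins per level, level frame
    marker_for_level: dict[FrameId, FrameId]

    @property
    def levels(self) -> tuple[FrameId, ...]:
        return tuple(self.models)

    def pushpins_world(self) -> tuple[np.ndarray, tuple[FrameId, ...]]:
        pts, levels = [], []
        for level, pins in self.pushpins_level.items():
            pts.append(self.level_world[level].apply(pins.points))
            levels.extend([level] * len(pins))
        return np.vstack(pts), tuple(levels)

    def marker_spheres_world(self, marker: FrameId) -> np.ndarray:
        return self.marker_world[marker].apply(self.marker_spheres[marker].points)


def make_specimen(config: SceneConfig) -> SyntheticSpecimen:
    """Stack the configured number of levels along the cranio-caudal (y)
    axis, attach one distinct four-sphere marker per level protruding
    anteriorly (toward the tracker side, -x/-z), and plant three push-pins
    per level on the mesh surface (both transverse processes + spinous
    process)."""
    n = config.level_count
    models: dict[FrameId, VertebraModel] = {}
    attachments: dict[FrameId, MarkerAttachment] = {}
    level_world: dict[FrameId, RigidTransform] = {}
    marker_world: dict[FrameId, RigidTransform] = {}
    marker_spheres: dict[FrameId, PointSet3D] = {}
    pushpins_level: dict[FrameId, PointSet3D] = {}
    marker_for_level: dict[FrameId, FrameId] = {}

    for j in range(1, n + 1):
        level, marker = f"L{j}", f"M{j}"
        vertices, faces = make_vertebra_mesh(j, config.mesh_subdivisions)
        models[level] = VertebraModel(level=level, vertices=vertices, faces=faces)

        # gentle lordotic curvature: small rotation about the lateral axis
        tilt = np.deg2rad(2.0 * (j - (n + 1) / 2.0))
        ty = (j - (n + 1) / 2.0) * config.level_spacing_mm
        level_world[level] = RigidTransform.from_axis_angle(
            np.array([1.0, 0.0, 0.0]), tilt, np.array([0.0, ty, 0.0]),
            source=level, target=WORLD_FRAME,
        )

        spheres = _marker_sphere_layout(j)
        marker_spheres[marker] = PointSet3D(spheres, frame=marker)
        # marker branch protrudes anteriorly, plane facing the tracker (-x)
        face_ots = RigidTransform.from_axis_angle(
            np.array([0.0, 1.0, 0.0]), np.deg2rad(-75.0 + 4.0 * j), np.zeros(3),
            source=marker, target=marker,
        )
        offset = np.array([-55.0, 0.0, -70.0])
        w_from_m = RigidTransform(
            face_ots.rotation,
            level_world[level].apply(offset),
            source=marker,
            target=WORLD_FRAME,
        )
        marker_world[marker] = w_from_m
        attachments[level] = MarkerAttachment(
            level=level, transform=w_from_m.inverse() @ level_world[level]
        )
        marker_for_level[level] = marker

        pins = np.stack(
            [
                _surface_point(vertices, np.array([1.0, 0.0, 0.3])),   # right transverse
                _surface_point(vertices, np.array([-1.0, 0.0, 0.3])),  # left transverse
                _surface_point(vertices, np.array([0.0, 0.0, 1.0])),   # spinous
            ]
        )
        pushpins_level[level] = PointSet3D(
            pins, frame=level, labels=(f"{level}-TR", f"{level}-TL", f"{level}-SP")
        )

    return SyntheticSpecimen(
        models=models,
        attachments=attachments,
        level_world=level_world,
        marker_world=marker_world,
        marker_spheres=marker_spheres,
        pushpins_level=pushpins_level,
        marker_for_level=marker_for_level,
    )


# ---------------------------------------------------------------------------
# tracker stream


def _noise_transform(rng: np.random.Generator, rot_deg_sigma: float, trans_mm_sigma: float, frame: FrameId) -> RigidTransform:
    axis = rng.normal(size=3)
    nrm = np.linalg.norm(axis)
    axis = axis / nrm if nrm > 0 else np.array([1.0, 0.0, 0.0])
    angle = np.deg2rad(rng.normal(0.0, rot_deg_sigma)) if rot_deg_sigma > 0 else 0.0
    trans = rng.normal(0.0, trans_mm_sigma, size=3) if trans_mm_sigma > 0 else np.zeros(3)
    return RigidTransform.from_axis_angle(axis, angle, trans, source=frame, target=frame)


def simulate_ots_stream(
    specimen: SyntheticSpecimen,
    duration_s: float,
    config: SceneConfig,
    ots_from_world: RigidTransform,
    rng: np.random.Generator | None = None,
    t0: float = 0.0,
) -> dict[FrameId, PoseStream]:
    """Tracked marker pose streams, keyed by level.

    Each sample is the ground-truth tracker-from-marker pose composed with a
    small rigid perturbation applied in the marker frame (rotation about the
    sphere centroid), so lever-arm error propagation to the distant anatomy
    is reproduced faithfully.  The reported registration error is the RMS of
    a best-fit of the marker geometry to sphere centres jittered with the
    configured sphere-level noise, mirroring how a tracker derives it.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_samples = int(round(duration_s * config.ots_rate_hz))
    dt = 1.0 / config.ots_rate_hz
    base_ts = t0 + config.clock_offset_s + np.arange(n_samples) * dt
    if config.timestamp_jitter_frac > 0:
        jitter = rng.uniform(-0.5, 0.5, size=n_samples) * dt * min(config.timestamp_jitter_frac, 0.999)
        base_ts = base_ts + jitter

    streams: dict[FrameId, PoseStream] = {}
    for level in specimen.levels:
        marker = specimen.marker_for_level[level]
        samples = []
        for k in range(n_samples):
            w_from_m = specimen.marker_world[marker]
            if config.breathing_amp_mm > 0:
                shift = config.breathing_amp_mm * np.sin(
                    2 * np.pi * config.breathing_hz * base_ts[k]
                ) * np.array([0.0, 0.0, 1.0])
                w_from_m = RigidTransform(
                    w_from_m.rotation, w_from_m.translation + shift,
                    source=w_from_m.source, target=w_from_m.target,
                )
            true_pose = ots_from_world @ w_from_m
            noisy = true_pose @ _noise_transform(
                rng, config.ots_rot_deg_sigma, config.ots_trans_mm_sigma, marker
            )
            if config.sphere_jitter_mm_sigma > 0:
                geom = specimen.marker_spheres[marker]
                jittered = PointSet3D(
                    geom.points + rng.normal(0, config.sphere_jitter_mm_sigma, geom.points.shape),
                    frame=marker,
                )
                reg_err = registration_rms(geom, jittered)
            else:
                reg_err = 0.0
            samples.append(TimedPose(float(base_ts[k]), noisy, registration_error=reg_err))
        streams[level] = PoseStream(marker=marker, samples=tuple(samples))
    return streams


# ---------------------------------------------------------------------------
# stereo observations


@dataclass(frozen=True)
class StereoObservations:
    """One synthetic stereo capture.  Observation lists are index-aligned
    with their source points; entries for objects outside either frustum are
    None and their indices are flagged in ``missing_*`` (never silently
    dropped)."""

    corners_left: tuple[PixelPoint | None, ...]
    corners_right: tuple[PixelPoint | None, ...]
    missing_corners: tuple[int, ...]
    blobs_left: tuple[PixelPoint | None, ...]
    blobs_right: tuple[PixelPoint | None, ...]
    blob_levels: tuple[FrameId, ...]
    missing_blobs: tuple[int, ...]
    measured_depth: DepthMap | None


def _observe_points(
    rig: StereoRig,
    sensor_pts: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator,
) -> tuple[list[PixelPoint | None], list[PixelPoint | None], list[int]]:
    r_from_l = rig.right_from_left
    right_pts = r_from_l.apply(sensor_pts)
    left_list: list[PixelPoint | None] = []
    right_list: list[PixelPoint | None] = []
    missing: list[int] = []
    for i, (pl, pr) in enumerate(zip(sensor_pts, right_pts)):
        ok = pl[2] > 1.0 and pr[2] > 1.0
        if ok:
            uv_l = project_points(rig.left, pl[None])[0]
            uv_r = project_points(rig.right, pr[None])[0]
            if config.pixel_sigma_px > 0:
                uv_l = uv_l + rng.normal(0, config.pixel_sigma_px, 2)
                uv_r = uv_r + rng.normal(0, config.pixel_sigma_px, 2)
            in_l = -0.5 <= uv_l[0] < rig.left.width - 0.5 and -0.5 <= uv_l[1] < rig.left.height - 0.5
            in_r = -0.5 <= uv_r[0] < rig.right.width - 0.5 and -0.5 <= uv_r[1] < rig.right.height - 0.5
            ok = in_l and in_r
        if ok:
            left_list.append(PixelPoint(*uv_l))
            right_list.append(PixelPoint(*uv_r))
        else:
            left_list.append(None)
            right_list.append(None)
            missing.append(i)
    return left_list, right_list, missing


def simulate_stereo_observations(
    world_from_sensor: RigidTransform,
    specimen: SyntheticSpecimen,
    config: SceneConfig,
    phantom: CalibrationPhantom | None = None,
    world_from_board: RigidTransform | None = None,
    rng: np.random.Generator | None = None,
    render: bool = True,
) -> StereoObservations:
    """Project phantom corners and push-pin heads into both cameras (with
    optional Gaussian pixel noise) and reconstruct the sensor's measured
    depth map as a render of the true scene, optionally scaled by the
    configured systematic depth bias."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    rig = config.rig(world_from_sensor.source)
    sensor_from_world = world_from_sensor.inverse()

    corners_l: tuple[PixelPoint | None, ...] = ()
    corners_r: tuple[PixelPoint | None, ...] = ()
    missing_c: tuple[int, ...] = ()
    if phantom is not None:
        if world_from_board is None:
            raise ValueError("phantom placement (world_from_board) required with a phantom")
        board_pts = truncate_rows(board_object_points(phantom.board), phantom.board)
        world_pts = world_from_board.apply(board_pts.points)
        cl, cr, mc = _observe_points(rig, sensor_from_world.apply(world_pts), config, rng)
        corners_l, corners_r, missing_c = tuple(cl), tuple(cr), tuple(mc)

    pin_world, pin_levels = specimen.pushpins_world()
    bl, br, mb = _observe_points(rig, sensor_from_world.apply(pin_world), config, rng)

    depth = None
    if render:
        per_level = []
        for level, model in specimen.models.items():
            pose = sensor_from_world @ specimen.level_world[level]
            per_level.append(render_depth(rig.left, (model.vertices, model.faces), pose))
        merged = merge_depth(per_level)
        if config.depth_scale_bias != 1.0:
            depth = DepthMap(merged.values * config.depth_scale_bias)
        else:
            depth = merged

    return StereoObservations(
        corners_left=corners_l,
        corners_right=corners_r,
        missing_corners=missing_c,
        blobs_left=tuple(bl),
        blobs_right=tuple(br),
        blob_levels=pin_levels,
        missing_blobs=tuple(mb),
        measured_depth=depth,
    )


# ---------------------------------------------------------------------------
# blob imaging


def rasterize_blobs(
    blobs: list[PixelPoint],
    radius_px: float,
    width: int,
    height: int,
) -> np.ndarray:
    """Anti-aliased disks on a black float image (intensity 0..1).

    Blobs must be inside the image bounds and pairwise non-overlapping at
    the given radius.
    """
    centers = np.array([[b.u, b.v] for b in blobs], dtype=float).reshape(-1, 2)
    for i, (u, v) in enumerate(centers):
        if not (radius_px <= u <= width - 1 - radius_px and radius_px <= v <= height - 1 - radius_px):
            raise ValueError(f"blob {i} at ({u:.1f}, {v:.1f}) exceeds image bounds")
    if len(centers) > 1:
        from scipy.spatial.distance import pdist

        if np.min(pdist(centers)) < 2 * radius_px + 2:
            raise ValueError("blobs overlap at the given radius")
    img = np.zeros((height, width))
    for u, v in centers:
        x0, x1 = int(np.floor(u - radius_px - 1)), int(np.ceil(u + radius_px + 1))
        y0, y1 = int(np.floor(v - radius_px - 1)), int(np.ceil(v + radius_px + 1))
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        d = np.hypot(xs - u, ys - v)
        cover = np.clip(radius_px + 0.5 - d, 0.0, 1.0)  # linear edge anti-aliasing
        img[y0 : y1 + 1, x0 : x1 + 1] = np.maximum(img[y0 : y1 + 1, x0 : x1 + 1], cover)
    return img


def detect_blob_centroids(image: np.ndarray, threshold: float = 0.5) -> list[PixelPoint]:
    """Threshold -> connected components -> intensity-weighted centroids.

    Components are ordered by the (row, column) of their first pixel in scan
    order, matching a deterministic detector.
    """
    mask = image > threshold
    labelled, n = ndimage.label(mask)
    if n == 0:
        return []
    order = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labelled == lab)
        first = np.lexsort((cols, rows))[0]
        order.append((rows[first], cols[first], lab))
    order.sort()
    out = []
    for _, _, lab in order:
        rows, cols = np.nonzero(labelled == lab)
        w = image[rows, cols]
        out.append(PixelPoint(u=float(np.sum(cols * w) / np.sum(w)), v=float(np.sum(rows * w) / np.sum(w))))
    return out


# ---------------------------------------------------------------------------
# whole-scene convenience wrapper


@dataclass(frozen=True)
class SyntheticScene:
    """A fully specified virtual OR: specimen, tracker pose, phantom and the
    twelve standardized viewpoints, with helpers for each pipeline stage."""

    config: SceneConfig
    specimen: SyntheticSpecimen
    world_from_ots: RigidTransform
    phantom: CalibrationPhantom
    world_from_board: RigidTransform
    viewpoints: tuple[ViewpointSpec, ...]

    @property
    def ots_from_world(self) -> RigidTransform:
        return self.world_from_ots.inverse()

    def true_sensor_from_ots(self, viewpoint: ViewpointSpec) -> RigidTransform:
        t = viewpoint.world_from_sensor().inverse() @ self.world_from_ots
        return t.with_frames(source=OTS_FRAME, target=viewpoint.sensor)

    def tracked_phantom_pose(
        self, rng: np.random.Generator, timestamp: float = 0.0, max_attempts: int = 50
    ) -> TimedPose:
        """Observe the phantom spheres with the tracker (with sphere-level
        jitter) and fit its pose; like the physical protocol, re-observe
        until the registration error passes the 0.1 mm gate."""
        geom = self.phantom.marker_geometry
        world_spheres = self.world_from_board.apply(geom.points)
        ots_spheres_true = self.ots_from_world.apply(world_spheres)
        sigma = self.config.sphere_jitter_mm_sigma
        for _ in range(max_attempts):
            observed = PointSet3D(
                ots_spheres_true + rng.normal(0, sigma, ots_spheres_true.shape)
                if sigma > 0
                else ots_spheres_true,
                frame=OTS_FRAME,
            )
            pose = measure_phantom_pose(self.phantom, observed, timestamp)
            if pose.registration_error < 0.1:
                # stored pose maps board frame -> tracker frame
                return TimedPose(
                    pose.timestamp,
                    pose.transform.with_frames(self.phantom.board_frame, OTS_FRAME),
                    pose.registration_error,
                )
        raise RuntimeError("phantom pose gate not passed; sphere jitter too large")

    def calibrate(
        self, viewpoint: ViewpointSpec, rng: np.random.Generator | None = None
    ) -> RigidTransform:
        """Run the full extrinsic calibration at one viewpoint and return
        the estimated sensor-from-tracker transform."""
        rng = np.random.default_rng(self.config.seed) if rng is None else rng
        obs = simulate_stereo_observations(
            viewpoint.world_from_sensor(),
            self.specimen,
            self.config,
            phantom=self.phantom,
            world_from_board=self.world_from_board,
            rng=rng,
            render=False,
        )
        if obs.missing_corners:
            raise RuntimeError(f"corners {obs.missing_corners} outside the stereo frusta")
        pose = self.tracked_phantom_pose(rng)
        return solve_extrinsic(
            self.config.rig(viewpoint.sensor),
            list(obs.corners_left),
            list(obs.corners_right),
            self.phantom,
            pose,
        )


def build_scene(config: SceneConfig) -> SyntheticScene:
    """Assemble the default virtual OR for a configuration.

    The specimen sits at the world origin (spine along y, posterior +z up);
    the tracker views it from the -x side; the calibration phantom lies
    centred on top of the anatomy; the twelve standardized viewpoints face
    the scene centre from the configured stand-off.
    """
    specimen = make_specimen(config)

    ots_pos = np.array([-1200.0, 0.0, 400.0])
    z_axis = -ots_pos / np.linalg.norm(ots_pos)  # optical axis toward the scene
    x_axis = np.cross(np.array([0.0, 0.0, 1.0]), z_axis)
    x_axis /= np.linalg.norm(x_axis)
    y_axis = np.cross(z_axis, x_axis)
    world_from_ots = RigidTransform(
        np.stack([x_axis, y_axis, z_axis], axis=1), ots_pos, source=OTS_FRAME, target=WORLD_FRAME
    )

    phantom = default_phantom()
    world_from_board = RigidTransform(
        np.eye(3), np.array([-60.0, -75.0, 120.0]), source=phantom.board_frame, target=WORLD_FRAME
    )

    viewpoints = tuple(standard_viewpoints(np.zeros(3), config.viewpoint_distance_mm))
    return SyntheticScene(
        config=config,
        specimen=specimen,
        world_from_ots=world_from_ots,
        phantom=phantom,
        world_from_board=world_from_board,
        viewpoints=viewpoints,
    )
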