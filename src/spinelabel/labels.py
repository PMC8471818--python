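"""Per-frame ground-truth label assembly.

For every RGB-D frame, the tracked marker pose with the nearest timestamp is
looked up in each marker's pose stream and chained with the extrinsic
calibration and the marker-to-vertebra attachment:

    sensor <- level  =  (sensor <- tracker) o (tracker <- marker at t) o (marker <- level)

The posed vertebra meshes are then rasterised into a z-buffer depth map,
giving a dense per-pixel label to compare against the sensor's own
reconstructed depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    FrameId,
    FrameMismatchError,
    RigidTransform,
    TimedPose,
)
from .stereo import CameraIntrinsics

__all__ = [
    "PoseStream",
    "VertebraModel",
    "MarkerAttachment",
    "DepthMap",
    "FrameLabel",
    "nearest_pose",
    "pose_chain",
    "render_depth",
    "merge_depth",
    "generate_labels",
]


@dataclass(frozen=True)
class PoseStream:
    """Time-ordered tracked poses of one marker (timestamps strictly
    increasing, seconds)."""

    marker: FrameId
    samples: tuple[TimedPose, ...]

    def __post_init__(self) -> None:
        samples = tuple(self.samples)
        object.__setattr__(self, "samples", samples)
        ts = np.array([s.timestamp for s in samples])
        if len(ts) > 1 and not np.all(np.diff(ts) > 0):
            raise ValueError("pose stream timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def timestamps(self) -> np.ndarray:
        return np.array([s.timestamp for s in self.samples])


@dataclass(frozen=True)
class VertebraModel:
    """A vertebra's triangle mesh in its own level frame (vertices mm)."""

    level: FrameId
    vertices: np.ndarray
    faces: np.ndarray
    visible_surface: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        f = np.asarray(self.faces, dtype=int).reshape(-1, 3)
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        if len(v) == 0 or len(f) == 0:
            raise ValueError("mesh must be non-empty")
        if f.min() < 0 or f.max() >= len(v):
            raise ValueError("faces index vertices out of range")


@dataclass(frozen=True)
class MarkerAttachment:
    """The rigid marker-from-level transform measured from postoperative CT."""

    level: FrameId
    transform: RigidTransform


@dataclass(frozen=True)
class DepthMap:
    """Per-pixel depth along the camera z axis, millimetres.

    Float encoding: invalid pixels are NaN.  Integer (PNG16) exports use 0 as
    the invalid marker at 0.1 mm per unit.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("depth map must be 2D")
        if np.any(v[np.isfinite(v)] <= 0):
            raise ValueError("valid depth values must be positive")
        object.__setattr__(self, "values", v)

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass(frozen=True)
class FrameLabel:
    """Ground truth for one RGB-D frame: the pose of every tracked level in
    the sensor frame plus (optionally) the rendered depth map."""

    sensor: FrameId
    timestamp: float
    per_level_pose: dict[FrameId, RigidTransform]
    depth: DepthMap | None = None


def nearest_pose(stream: PoseStream, t: float) -> TimedPose:
    """Sample minimising |timestamp - t|; ties go to the earlier sample."""
    if len(stream) == 0:
        raise ValueError(f"pose stream for {stream.marker!r} is empty")
    ts = stream.timestamps
    i = int(np.searchsorted(ts, t))
    if i == 0:
        return stream.samples[0]
    if i == len(ts):
        return stream.samples[-1]
    before, after = ts[i - 1], ts[i]
    # strict '<' sends exact midpoints to the earlier sample
    return stream.samples[i] if (after - t) < (t - before) else stream.samples[i - 1]


def pose_chain(
    s_from_o: RigidTransform,
    o_from_m: TimedPose,
    m_from_l: MarkerAttachment,
) -> TimedPose:
    """Sensor-from-level pose at the tracked sample's timestamp."""
    chained = s_from_o @ o_from_m.transform @ m_from_l.transform
    return TimedPose(timestamp=o_from_m.timestamp, transform=chained)


# ---------------------------------------------------------------------------
# z-buffer rasterisation


def _is_top_left(ax: float, ay: float, bx: float, by: float) -> bool:
    # Edge a->b of a triangle oriented so the interior has positive edge
    # weights, y increasing downward: top edge is horizontal going +x,
    # left edge goes -y.
    dx, dy = bx - ax, by - ay
    return (dy == 0 and dx > 0) or dy < 0


def render_depth(
    cam: CameraIntrinsics,
    mesh: tuple[np.ndarray, np.ndarray],
    pose: RigidTransform,
    near_mm: float = 1.0,
) -> DepthMap:
    """Rasterise a posed triangle mesh into a z-buffer depth map.

    A pixel is covered by a triangle iff the triangle's 2D projection
    contains the pixel centre (top-left fill rule on edge ties); its value is
    the smallest z over covering triangles, interpolated
    perspective-correctly (1/z is affine in the image plane for a planar
    triangle).  Back-face culling is off.  Pixels covered by no triangle are
    NaN.  Triangles with any vertex closer than ``near_mm`` are skipped
    (no clipping; synthetic scenes keep geometry well in front).
    """
    vertices, faces = mesh
    vertices = np.asarray(vertices, dtype=float).reshape(-1, 3)
    faces = np.asarray(faces, dtype=int).reshape(-1, 3)
    if len(vertices) == 0 or len(faces) == 0:
        raise ValueError("mesh must be non-empty")

    cam_pts = pose.apply(vertices)
    z = cam_pts[:, 2]
    u = cam.cx + cam.fx * np.divide(cam_pts[:, 0], z, out=np.zeros_like(z), where=z > 0)
    v = cam.cy + cam.fy * np.divide(cam_pts[:, 1], z, out=np.zeros_like(z), where=z > 0)
    inv_z = np.divide(1.0, z, out=np.zeros_like(z), where=z > 0)

    W, H = cam.width, cam.height
    buf = np.full((H, W), np.inf)

    for f in faces:
        if np.any(z[f] < near_mm):
            continue
        xs, ys, ws = u[f], v[f], inv_z[f]
        area = (xs[1] - xs[0]) * (ys[2] - ys[0]) - (ys[1] - ys[0]) * (xs[2] - xs[0])
        if area == 0:
            continue
        if area < 0:  # normalise winding so interior weights are positive
            xs, ys, ws = xs[::-1], ys[::-1], ws[::-1]
            area = -area

        x0 = max(int(np.ceil(xs.min())), 0)
        x1 = min(int(np.floor(xs.max())), W - 1)
        y0 = max(int(np.ceil(ys.min())), 0)
        y1 = min(int(np.floor(ys.max())), H - 1)
        if x0 > x1 or y0 > y1:
            continue

        px, py = np.meshgrid(
            np.arange(x0, x1 + 1, dtype=float),
            np.arange(y0, y1 + 1, dtype=float),
        )
        inside = np.ones(px.shape, dtype=bool)
        bary = []
        for k in range(3):
            ax, ay = xs[k], ys[k]
            bx, by = xs[(k + 1) % 3], ys[(k + 1) % 3]
            w = (bx - ax) * (py - ay) - (by - ay) * (px - ax)
            if _is_top_left(ax, ay, bx, by):
                inside &= w >= 0
            else:
                inside &= w > 0
            bary.append(w)
        if not inside.any():
            continue
        # edge weight opposite vertex k is bary[(k+1)%3]
        l0, l1, l2 = bary[1] / area, bary[2] / area, bary[0] / area
        interp_inv_z = l0 * ws[0] + l1 * ws[1] + l2 * ws[2]
        with np.errstate(divide="ignore"):
            depth = 1.0 / interp_inv_z
        depth = np.where(inside & (interp_inv_z > 0), depth, np.inf)
        region = buf[y0 : y1 + 1, x0 : x1 + 1]
        np.minimum(region, depth, out=region)

    buf[~np.isfinite(buf)] = np.nan
    return DepthMap(buf)


def merge_depth(maps: list[DepthMap]) -> DepthMap:
    """Z-buffer union of several depth maps (per-pixel minimum over the
    valid values) — one sensor image of the whole exposed spine."""
    if not maps:
        raise ValueError("no depth maps to merge")
    stack = np.stack([m.values for m in maps])
    filled = np.where(np.isnan(stack), np.inf, stack)
    merged = filled.min(axis=0)
    merged[~np.isfinite(merged)] = np.nan
    return DepthMap(merged)


def generate_labels(
    frame_timestamps: np.ndarray,
    streams: dict[FrameId, PoseStream],
    s_from_o: RigidTransform,
    attachments: dict[FrameId, MarkerAttachment],
    models: dict[FrameId, VertebraModel],
    cam: CameraIntrinsics,
    render: bool = True,
) -> list[FrameLabel]:
    """Build one :class:`FrameLabel` per recorded frame timestamp.

    ``streams`` maps each level to its marker's tracked pose stream; the
    depth maps of all levels are merged by z-buffer minimum.
    """
    for level, stream in streams.items():
        if len(stream) == 0:
            raise ValueError(f"pose stream for level {level!r} is empty")
        if level not in attachments:
            raise ValueError(f"no marker attachment for level {level!r}")

    labels: list[FrameLabel] = []
    for t in np.asarray(frame_timestamps, dtype=float):
        poses: dict[FrameId, RigidTransform] = {}
        for level, stream in streams.items():
            sample = nearest_pose(stream, float(t))
            poses[level] = pose_chain(s_from_o, sample, attachments[level]).transform
        depth = None
        if render:
            per_level = [
                render_depth(cam, (models[level].vertices, models[level].faces), poses[level])
                for level in streams
                if level in models
            ]
            if per_level:
                depth = merge_depth(per_level)
        labels.append(
            FrameLabel(sensor=s_from_o.target, timestamp=float(t), per_level_pose=poses, depth=depth)
        )
    return labels
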