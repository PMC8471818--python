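"""Pinhole stereo camera model.

Camera frame convention: +z along the optical axis, +x right, +y down.
Image origin top-left; continuous pixel coordinates use the pixel-centre
convention (pixel (0, 0) has centre u=0.0, v=0.0).  The sensor frame of a
stereo rig is defined as its left camera frame.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .geometry import FrameId, RigidTransform

__all__ = [
    "CameraIntrinsics",
    "StereoRig",
    "PixelPoint",
    "BehindCameraError",
    "ParallelRaysError",
    "project",
    "triangulate_pair",
    "triangulate_pair_midpoint",
    "depth_from_disparity",
    "apply_focal_correction",
]


class BehindCameraError(ValueError):
    """Projection requested for a point at or behind the camera plane."""


class ParallelRaysError(ValueError):
    """Triangulation requested for (near-)parallel viewing rays."""


@dataclass(frozen=True)
class PixelPoint:
    u: float
    v: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.u) and np.isfinite(self.v)):
            raise ValueError("pixel coordinates must be finite")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.u, self.v], dtype=float)


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole intrinsics; focal lengths and principal point in pixels.

    Radial distortion is modelled as zero throughout (see
    ``distortion_coeffs`` hook); the synthetic world is distortion-free.
    """

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    distortion_coeffs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the image")

    @property
    def K(self) -> np.ndarray:
        return np.array(
            [[self.fx, 0.0, self.cx], [0.0, self.fy, self.cy], [0.0, 0.0, 1.0]]
        )

    def scaled(self, factor: float) -> "CameraIntrinsics":
        """Intrinsics for an image resized by ``factor`` (same field of view)."""
        return CameraIntrinsics(
            fx=self.fx * factor,
            fy=self.fy * factor,
            cx=(self.cx + 0.5) * factor - 0.5,
            cy=(self.cy + 0.5) * factor - 0.5,
            width=int(round(self.width * factor)),
            height=int(round(self.height * factor)),
        )


@dataclass(frozen=True)
class StereoRig:
    """Two pinhole cameras plus the left-to-right extrinsic.

    ``right_from_left`` maps left-camera coordinates into the right-camera
    frame.  The rig's sensor frame is, by definition, the left camera frame.
    """

    left: CameraIntrinsics
    right: CameraIntrinsics
    right_from_left: RigidTransform
    sensor_frame: FrameId = "S1"

    def __post_init__(self) -> None:
        if self.baseline_mm <= 0:
            raise ValueError("stereo baseline must be positive")

    @property
    def baseline_mm(self) -> float:
        return float(np.linalg.norm(self.right_from_left.translation))

    @classmethod
    def rectified(
        cls,
        intrinsics: CameraIntrinsics,
        baseline_mm: float,
        sensor_frame: FrameId = "S1",
    ) -> "StereoRig":
        """Fronto-parallel rig: identical intrinsics, right camera displaced
        by ``baseline_mm`` along the left camera's +x axis."""
        r_from_l = RigidTransform(
            np.eye(3),
            np.array([-baseline_mm, 0.0, 0.0]),
            source=f"{sensor_frame}:left",
            target=f"{sensor_frame}:right",
        )
        return cls(intrinsics, intrinsics, r_from_l, sensor_frame=sensor_frame)

    def projection_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        """3x4 projection matrices of both cameras in the sensor (= left) frame."""
        P_left = self.left.K @ np.hstack([np.eye(3), np.zeros((3, 1))])
        rl = self.right_from_left
        P_right = self.right.K @ np.hstack([rl.rotation, rl.translation.reshape(3, 1)])
        return P_left, P_right


def project(cam: CameraIntrinsics, p: np.ndarray) -> PixelPoint:
    """Project one camera-frame point (mm) to continuous pixel coordinates.

    u = cx + fx * x / z, v = cy + fy * y / z; requires z > 0.
    """
    x, y, z = np.asarray(p, dtype=float).reshape(3)
    if z <= 0:
        raise BehindCameraError(f"point has non-positive depth z={z}")
    return PixelPoint(cam.cx + cam.fx * x / z, cam.cy + cam.fy * y / z)


def project_points(cam: CameraIntrinsics, pts: np.ndarray) -> np.ndarray:
    """Vectorised projection of an (n, 3) array; returns (n, 2) pixel coords."""
    pts = np.asarray(pts, dtype=float).reshape(-1, 3)
    z = pts[:, 2]
    if np.any(z <= 0):
        raise BehindCameraError("some points have non-positive depth")
    uv = np.empty((len(pts), 2))
    uv[:, 0] = cam.cx + cam.fx * pts[:, 0] / z
    uv[:, 1] = cam.cy + cam.fy * pts[:, 1] / z
    return uv


def _ray_in_left_frame(rig: StereoRig, which: str, uv: PixelPoint) -> tuple[np.ndarray, np.ndarray]:
    if which == "left":
        cam = rig.left
        d = np.array([(uv.u - cam.cx) / cam.fx, (uv.v - cam.cy) / cam.fy, 1.0])
        return np.zeros(3), d
    cam = rig.right
    d_right = np.array([(uv.u - cam.cx) / cam.fx, (uv.v - cam.cy) / cam.fy, 1.0])
    l_from_r = rig.right_from_left.inverse()
    return l_from_r.translation.copy(), l_from_r.rotation @ d_right


def triangulate_pair(rig: StereoRig, left_uv: PixelPoint, right_uv: PixelPoint) -> np.ndarray:
    """Two-view linear (DLT) triangulation, result in the sensor frame (mm).

    Solves the homogeneous system stacking, for each view, the two
    cross-product rows of ``uv x (P X) = 0`` and taking the smallest
    right singular vector.  Exact inverse of :func:`project` for
    noise-free, consistent observations.
    """
    o1, d1 = _ray_in_left_frame(rig, "left", left_uv)
    o2, d2 = _ray_in_left_frame(rig, "right", right_uv)
    cross = np.cross(d1 / np.linalg.norm(d1), d2 / np.linalg.norm(d2))
    if np.linalg.norm(cross) < 1e-12:
        raise ParallelRaysError("viewing rays are parallel; no intersection")

    P1, P2 = rig.projection_matrices()
    A = np.empty((4, 4))
    A[0] = left_uv.u * P1[2] - P1[0]
    A[1] = left_uv.v * P1[2] - P1[1]
    A[2] = right_uv.u * P2[2] - P2[0]
    A[3] = right_uv.v * P2[2] - P2[1]
    _, _, vt = np.linalg.svd(A)
    X = vt[-1]
    if abs(X[3]) < 1e-15:
        raise ParallelRaysError("triangulated point at infinity")
    return X[:3] / X[3]


def triangulate_pair_midpoint(rig: StereoRig, left_uv: PixelPoint, right_uv: PixelPoint) -> np.ndarray:
    """Midpoint of the common perpendicular of the two back-projected rays.

    Kept as an independent cross-check of the DLT solution.
    """
    o1, d1 = _ray_in_left_frame(rig, "left", left_uv)
    o2, d2 = _ray_in_left_frame(rig, "right", right_uv)
    # Solve [d1 -d2] [s; t] = o2 - o1 in least squares.
    A = np.stack([d1, -d2], axis=1)
    rhs = o2 - o1
    st, *_ = np.linalg.lstsq(A, rhs, rcond=None)
    if not np.all(np.isfinite(st)):
        raise ParallelRaysError("viewing rays are parallel; no intersection")
    p1 = o1 + st[0] * d1
    p2 = o2 + st[1] * d2
    return (p1 + p2) / 2.0


def depth_from_disparity(rig: StereoRig, disparity_px: float) -> float:
    """Depth (mm) from horizontal disparity for a rectified fronto-parallel
    rig: z = fx * baseline / disparity."""
    if disparity_px <= 0:
        raise ValueError(f"disparity must be positive, got {disparity_px}")
    return rig.left.fx * rig.baseline_mm / disparity_px


def apply_focal_correction(rig: StereoRig, scale: float) -> StereoRig:
    """Return a rig with both cameras' focal lengths multiplied by ``scale``.

    This is the depth-correction mechanism: reconstructed depth at a fixed
    disparity scales by exactly ``scale`` (principal points untouched), so a
    single scalar zeroes a systematic median z-deviation.
    """
    if scale <= 0:
        raise ValueError(f"focal scale must be positive, got {scale}")

    def bump(cam: CameraIntrinsics) -> CameraIntrinsics:
        return replace(cam, fx=cam.fx * scale, fy=cam.fy * scale)

    return replace(rig, left=bump(rig.left), right=bump(rig.right))
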