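"""Rigid-transform algebra and point-set registration.

Every quantity in the pipeline is expressed through frame-labelled rigid
transforms: the optical tracking system (OTS) frame ``O``, the two stereo
sensor frames ``S1``/``S2``, per-vertebra marker frames ``M1``..``M5`` and
vertebra (level) frames ``L1``..``L5``.  A transform named *B from A* maps
coordinates expressed in frame A into frame B.  All lengths are millimetres,
all timestamps seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "FrameId",
    "FrameMismatchError",
    "DegenerateInputError",
    "RigidTransform",
    "PointSet3D",
    "TimedPose",
    "compose",
    "invert",
    "horn_fit",
    "registration_rms",
    "icp_point_to_point",
]

# Symbolic frame labels are plain strings; these are the canonical ones.
FrameId = str

OTS_FRAME: FrameId = "O"
SENSOR_FRAMES: tuple[FrameId, FrameId] = ("S1", "S2")
MARKER_FRAMES: tuple[FrameId, ...] = tuple(f"M{j}" for j in range(1, 6))
LEVEL_FRAMES: tuple[FrameId, ...] = tuple(f"L{j}" for j in range(1, 6))
WORLD_FRAME: FrameId = "world"
BOARD_FRAME: FrameId = "board"

_ORTHO_TOL = 1e-9


class FrameMismatchError(ValueError):
    """Raised when a transform chain's inner frames do not match."""


class DegenerateInputError(ValueError):
    """Raised for point configurations that do not determine a rigid fit."""


@dataclass(frozen=True)
class RigidTransform:
    """An SE(3) map from ``source`` frame coordinates to ``target`` frame.

    Parameters
    ----------
    rotation
        3x3 orthonormal matrix with determinant +1 (checked to 1e-9).
    translation
        3-vector in millimetres.
    source, target
        Symbolic frame labels; composition requires matching inner frames.
    """

    rotation: np.ndarray
    translation: np.ndarray
    source: FrameId = WORLD_FRAME
    target: FrameId = WORLD_FRAME

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation determinant is not +1 (reflection?)")
        if not np.all(np.isfinite(t)):
            raise ValueError("translation must be finite")

    # -- constructors ------------------------------------------------------
    @classmethod
    def identity(cls, frame: FrameId = WORLD_FRAME, target: FrameId | None = None) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), source=frame, target=frame if target is None else target)

    @classmethod
    def from_matrix(cls, m: np.ndarray, source: FrameId = WORLD_FRAME, target: FrameId = WORLD_FRAME) -> "RigidTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3], source=source, target=target)

    @classmethod
    def from_axis_angle(
        cls,
        axis: np.ndarray,
        angle_rad: float,
        translation: np.ndarray | None = None,
        source: FrameId = WORLD_FRAME,
        target: FrameId = WORLD_FRAME,
    ) -> "RigidTransform":
        axis = np.asarray(axis, dtype=float)
        n = np.linalg.norm(axis)
        if n == 0:
            R = np.eye(3)
        else:
            k = axis / n
            K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
            R = np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
        t = np.zeros(3) if translation is None else translation
        return cls(R, t, source=source, target=target)

    # -- views -------------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """4x4 row-major homogeneous matrix."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map one (3,) point or an (n, 3) array from source to target frame."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation

    def with_frames(self, source: FrameId, target: FrameId) -> "RigidTransform":
        return replace(self, source=source, target=target)

    # -- algebra -----------------------------------------------------------
    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)

    def inverse(self) -> "RigidTransform":
        return invert(self)

    def rotation_angle_rad(self) -> float:
        """Magnitude of the rotation, radians."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.arccos(np.clip(c, -1.0, 1.0)))


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """Chain two transforms: the result maps ``b.source`` to ``a.target``.

    Frame labels must match at the junction (``a.source == b.target``); this
    is what keeps a chain like sensor<-OTS, OTS<-marker, marker<-level honest.
    """
    if a.source != b.target:
        raise FrameMismatchError(
            f"cannot compose: left transform expects source frame {a.source!r} "
            f"but right transform produces {b.target!r}"
        )
    return RigidTransform(
        a.rotation @ b.rotation,
        a.rotation @ b.translation + a.translation,
        source=b.source,
        target=a.target,
    )


def invert(a: RigidTransform) -> RigidTransform:
    """Inverse map, with source/target swapped."""
    Rt = a.rotation.T
    return RigidTransform(Rt, -Rt @ a.translation, source=a.target, target=a.source)


@dataclass(frozen=True)
class PointSet3D:
    """An ordered set of 3D points (mm) expressed in a named frame.

    Order is significant: correspondence between two sets is by index.
    """

    points: np.ndarray
    frame: FrameId = WORLD_FRAME
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "points", p)
        if not np.all(np.isfinite(p)):
            raise ValueError("point coordinates must be finite")
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != len(p):
                raise ValueError("labels must match point count")
            object.__setattr__(self, "labels", labels)

    def __len__(self) -> int:
        return len(self.points)

    def transformed(self, t: RigidTransform) -> "PointSet3D":
        if t.source != self.frame:
            raise FrameMismatchError(
                f"transform expects source frame {t.source!r}, points are in {self.frame!r}"
            )
        return PointSet3D(t.apply(self.points), frame=t.target, labels=self.labels)


@dataclass(frozen=True)
class TimedPose:
    """A timestamped rigid transform, optionally carrying the tracking
    system's marker-geometry registration error (RMS, mm)."""

    timestamp: float
    transform: RigidTransform
    registration_error: float | None = None

    def __post_init__(self) -> None:
        if self.registration_error is not None and self.registration_error < 0:
            raise ValueError("registration_error must be >= 0")


def _check_corresponded(src: PointSet3D, dst: PointSet3D) -> tuple[np.ndarray, np.ndarray]:
    a, b = src.points, dst.points
    if len(a) != len(b):
        raise DegenerateInputError(f"point counts differ: {len(a)} vs {len(b)}")
    if len(a) < 3:
        raise DegenerateInputError(f"need at least 3 corresponded points, got {len(a)}")
    return a, b


def _check_noncollinear(pts: np.ndarray) -> None:
    c = pts - pts.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    scale = max(s[0], 1.0)
    if s[1] / scale < 1e-9:
        raise DegenerateInputError("points are collinear; rotation is not determined")


def horn_fit(src: PointSet3D, dst: PointSet3D) -> RigidTransform:
    """Closed-form absolute orientation (Horn's unit-quaternion method).

    Returns the rigid transform minimising ``sum_j ||R src_j + T - dst_j||^2``
    over rotations R and translations T — no scale component.  This is the
    solver behind both the extrinsic calibration (OTS corner set to
    triangulated sensor corner set) and marker-pose estimation from observed
    sphere centres.

    The rotation is recovered as the eigenvector of the 4x4 quaternion
    profile matrix with the largest eigenvalue.
    """
    a, b = _check_corresponded(src, dst)
    _check_noncollinear(a)

    ca = a - a.mean(axis=0)
    cb = b - b.mean(axis=0)
    M = ca.T @ cb  # cross-covariance, src x dst

    sxx, sxy, sxz = M[0]
    syx, syy, syz = M[1]
    szx, szy, szz = M[2]
    N = np.array(
        [
            [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
            [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
            [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
            [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
        ]
    )
    w, v = np.linalg.eigh(N)
    q = v[:, -1]  # unit quaternion (w, x, y, z) for the largest eigenvalue
    qw, qx, qy, qz = q
    R = np.array(
        [
            [1 - 2 * (qy * qy + qz * qz), 2 * (qx * qy - qw * qz), 2 * (qx * qz + qw * qy)],
            [2 * (qx * qy + qw * qz), 1 - 2 * (qx * qx + qz * qz), 2 * (qy * qz - qw * qx)],
            [2 * (qx * qz - qw * qy), 2 * (qy * qz + qw * qx), 1 - 2 * (qx * qx + qy * qy)],
        ]
    )
    # Re-orthonormalise against accumulated rounding in the quaternion.
    u, _, vt = np.linalg.svd(R)
    R = u @ vt
    t = b.mean(axis=0) - R @ a.mean(axis=0)
    return RigidTransform(R, t, source=src.frame, target=dst.frame)


def registration_rms(geometry: PointSet3D, observed: PointSet3D) -> float:
    """RMS residual (mm) after best rigid alignment of ``geometry`` onto
    ``observed`` — the quantity a tracking system reports as its marker
    geometry registration error."""
    fit = horn_fit(geometry, observed)
    resid = fit.apply(geometry.points) - observed.points
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def icp_point_to_point(
    src: PointSet3D,
    dst: PointSet3D,
    init: RigidTransform | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[RigidTransform, float]:
    """Point-to-point iterative closest point.

    Alternates nearest-neighbour correspondence (ties broken by lowest
    destination index) with a full Horn re-fit until the RMS improvement per
    iteration drops below ``tol`` or ``max_iter`` is reached.  Returns the
    src-frame -> dst-frame transform and the final RMS (mm).
    """
    if len(src.points) == 0 or len(dst.points) == 0:
        raise DegenerateInputError("ICP requires non-empty point sets")
    current = RigidTransform.identity(src.frame, dst.frame) if init is None else init
    if current.source != src.frame or current.target != dst.frame:
        raise FrameMismatchError(
            f"init must map {src.frame!r} to {dst.frame!r}, got "
            f"{current.source!r} -> {current.target!r}"
        )
    prev_rms = np.inf
    rms = np.inf
    for _ in range(max_iter):
        moved = current.apply(src.points)
        d = cdist(moved, dst.points)
        nn = np.argmin(d, axis=1)  # argmin returns the lowest index on ties
        matched = dst.points[nn]
        rms = float(np.sqrt(np.mean(np.sum((moved - matched) ** 2, axis=1))))
        current = horn_fit(src, PointSet3D(matched, frame=dst.frame))
        if prev_rms - rms < tol:
            break
        prev_rms = rms
    moved = current.apply(src.points)
    d = cdist(moved, dst.points)
    nn = np.argmin(d, axis=1)
    rms = float(np.sqrt(np.mean(np.sum((moved - dst.points[nn]) ** 2, axis=1))))
    return current, rms
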