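"""Extrinsic calibration of the optical tracking system to a stereo sensor.

A dual-domain phantom — a chessboard observed by the stereo cameras, rigidly
joined to a four-sphere retro-reflective marker observed by the tracker —
provides 3D correspondences in both device frames.  The inner chessboard
corners are triangulated from the two camera views (``SiCC``) and, on the
tracker side, obtained by mapping the known board geometry through the
tracked phantom pose (``OCC'``).  The sensor-from-tracker transform is the
closed-form least-squares alignment of the two corresponded sets.

Two empirical details of the procedure are modelled explicitly: the
tracked phantom pose is only accepted when the marker geometry registration
error is strictly below 0.1 mm, and the three chessboard rows farthest from
the marker branch are dropped before the solve (pose error grows with each
row's lever arm), leaving 25 of the 40 inner corners.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (
    BOARD_FRAME,
    OTS_FRAME,
    FrameId,
    FrameMismatchError,
    PointSet3D,
    RigidTransform,
    TimedPose,
    horn_fit,
)
from .stereo import PixelPoint, StereoRig, triangulate_pair

__all__ = [
    "ChessboardSpec",
    "CalibrationPhantom",
    "CorrespondenceSet",
    "PoseRejectedError",
    "board_object_points",
    "truncate_rows",
    "phantom_world_corners",
    "gate_phantom_pose",
    "measure_phantom_pose",
    "solve_extrinsic",
    "default_phantom",
]

POSE_GATE_MM = 0.1
DEFAULT_DROPPED_ROWS = 3


class PoseRejectedError(ValueError):
    """Tracked phantom pose failed the registration-error gate."""

    def __init__(self, registration_error: float, threshold: float):
        self.registration_error = registration_error
        self.threshold = threshold
        super().__init__(
            f"phantom pose rejected: registration error {registration_error:.4f} mm "
            f">= gate {threshold:.4f} mm"
        )


@dataclass(frozen=True)
class ChessboardSpec:
    """Chessboard geometry in squares; the detectable grid is the inner
    corners, (columns-1) x (rows-1)."""

    columns: int = 6
    rows: int = 9
    square_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.columns < 2 or self.rows < 2:
            raise ValueError("board needs at least 2 columns and 2 rows")
        if self.square_mm <= 0:
            raise ValueError("square side must be positive")

    @property
    def inner_corner_count(self) -> int:
        return (self.columns - 1) * (self.rows - 1)


@dataclass(frozen=True)
class CalibrationPhantom:
    """Board spec plus the four co-planar marker-sphere centres, both
    expressed in the board frame (origin at the marker-proximal inner
    corner, x across columns, y along rows, z out of the board plane)."""

    board: ChessboardSpec = field(default_factory=ChessboardSpec)
    marker_geometry: PointSet3D = None  # type: ignore[assignment]
    board_frame: FrameId = BOARD_FRAME
    coplanarity_tol_mm: float = 0.05

    def __post_init__(self) -> None:
        if self.marker_geometry is None:
            raise ValueError("marker_geometry is required")
        pts = self.marker_geometry.points
        if len(pts) != 4:
            raise ValueError(f"marker geometry must have exactly 4 spheres, got {len(pts)}")
        centred = pts - pts.mean(axis=0)
        s = np.linalg.svd(centred, compute_uv=False)
        if s[2] > self.coplanarity_tol_mm:
            raise ValueError(
                f"marker spheres deviate from a common plane by {s[2]:.3f} mm "
                f"(tolerance {self.coplanarity_tol_mm} mm)"
            )


@dataclass(frozen=True)
class CorrespondenceSet:
    """Corresponded corner sets: tracker-side OCC' and sensor-side SiCC."""

    ots_points: PointSet3D
    sensor_points: PointSet3D
    retained_rows: int

    def __post_init__(self) -> None:
        if len(self.ots_points) != len(self.sensor_points):
            raise ValueError("corresponded sets must have equal cardinality")


def board_object_points(spec: ChessboardSpec) -> PointSet3D:
    """Inner-corner grid in the board frame: z=0, x = i*square (i along
    columns), y = j*square (j along rows), ordered row-major (j, then i)."""
    ni = spec.columns - 1
    nj = spec.rows - 1
    jj, ii = np.meshgrid(np.arange(nj), np.arange(ni), indexing="ij")
    pts = np.zeros((ni * nj, 3))
    pts[:, 0] = ii.ravel() * spec.square_mm
    pts[:, 1] = jj.ravel() * spec.square_mm
    return PointSet3D(pts, frame=BOARD_FRAME)


def truncate_rows(points: PointSet3D, spec: ChessboardSpec, drop_last: int = DEFAULT_DROPPED_ROWS) -> PointSet3D:
    """Remove the ``drop_last`` rows with the largest j index (farthest from
    the board origin / marker branch) from a full canonical-order grid."""
    ni = spec.columns - 1
    nj = spec.rows - 1
    if len(points) != ni * nj:
        raise ValueError(
            f"expected a full {ni}x{nj} inner-corner grid ({ni * nj} points), got {len(points)}"
        )
    if drop_last < 0:
        raise ValueError("drop_last must be >= 0")
    if drop_last >= nj:
        raise ValueError(f"dropping {drop_last} of {nj} rows would leave no points")
    keep = (nj - drop_last) * ni
    labels = points.labels[:keep] if points.labels is not None else None
    return PointSet3D(points.points[:keep], frame=points.frame, labels=labels)


def phantom_world_corners(
    phantom: CalibrationPhantom,
    ots_pose: RigidTransform,
    drop_last: int = DEFAULT_DROPPED_ROWS,
) -> PointSet3D:
    """Truncated board corners mapped through the tracked phantom pose,
    yielding OCC' in the tracker frame."""
    if ots_pose.source != phantom.board_frame:
        raise FrameMismatchError(
            f"ots_pose must map board frame {phantom.board_frame!r}, "
            f"but its source is {ots_pose.source!r}"
        )
    corners = truncate_rows(board_object_points(phantom.board), phantom.board, drop_last)
    return corners.transformed(ots_pose)


def gate_phantom_pose(pose: TimedPose, threshold: float = POSE_GATE_MM) -> bool:
    """Accept a tracked phantom pose iff its registration error is strictly
    below ``threshold`` (mm)."""
    if pose.registration_error is None:
        raise ValueError("pose carries no registration error; cannot gate")
    return pose.registration_error < threshold


def measure_phantom_pose(
    phantom: CalibrationPhantom,
    observed_spheres: PointSet3D,
    timestamp: float = 0.0,
) -> TimedPose:
    """Estimate the tracked phantom pose (tracker frame from board frame)
    from observed sphere centres, carrying the registration RMS the way a
    tracking system reports it."""
    fit = horn_fit(phantom.marker_geometry, observed_spheres)
    resid = fit.apply(phantom.marker_geometry.points) - observed_spheres.points
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return TimedPose(timestamp=timestamp, transform=fit, registration_error=rms)


def solve_extrinsic(
    rig: StereoRig,
    left_corners: list[PixelPoint],
    right_corners: list[PixelPoint],
    phantom: CalibrationPhantom,
    ots_pose: TimedPose,
    drop_last: int = DEFAULT_DROPPED_ROWS,
    gate_mm: float = POSE_GATE_MM,
) -> RigidTransform:
    """Single-frame extrinsic calibration: sensor frame from tracker frame.

    The corner pixel lists must be in canonical (truncated) grid order.  Each
    left/right pair is triangulated into the sensor frame (SiCC); the
    tracker-side counterparts OCC' come from the gated phantom pose; the
    result is the least-squares rigid alignment OCC' -> SiCC.
    """
    if not gate_phantom_pose(ots_pose, gate_mm):
        raise PoseRejectedError(ots_pose.registration_error, gate_mm)
    occ = phantom_world_corners(phantom, ots_pose.transform, drop_last)
    n = len(occ)
    if len(left_corners) != n or len(right_corners) != n:
        raise ValueError(
            f"corner count mismatch: expected {n} per camera, got "
            f"{len(left_corners)} left / {len(right_corners)} right"
        )
    sensor_pts = np.array(
        [triangulate_pair(rig, l, r) for l, r in zip(left_corners, right_corners)]
    )
    scc = PointSet3D(sensor_pts, frame=rig.sensor_frame)
    fit = horn_fit(occ, scc)
    return fit.with_frames(source=OTS_FRAME, target=rig.sensor_frame)


def default_phantom() -> CalibrationPhantom:
    """The dual-domain phantom of the standard setup: a 6x9 / 30 mm board
    and four co-planar spheres on a branch orthogonal to the board plane,
    proximal to the board origin.  Sphere coordinates are a plausible layout,
    asymmetric so the marker pose is unambiguous."""
    spheres = PointSet3D(
        np.array(
            [
                [-20.0, -35.0, 40.0],
                [35.0, -50.0, 40.0],
                [80.0, -20.0, 40.0],
                [20.0, -80.0, 40.0],
            ]
        ),
        frame=BOARD_FRAME,
    )
    return CalibrationPhantom(board=ChessboardSpec(), marker_geometry=spheres)
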