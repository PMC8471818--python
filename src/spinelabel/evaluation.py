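"""Quantitative accuracy measures of the labelling setup.

* **TRE** (target registration error): Euclidean distance between a push-pin
  fiducial's CT-measured position mapped through the calibrated
  transformation chain and its independently triangulated position in the
  sensor frame.
* **VBSE** (visible bone surface error): median absolute per-pixel
  difference between the rendered ground-truth depth map and the sensor's
  reconstructed depth map, over pixels valid in both.
* **Depth correction**: a single focal-length scale per sensor chosen so the
  median z-deviation between chained CT fiducials and triangulated
  fiducials is zero.
* **Experiment-plan enumeration**: the deterministic bookkeeping of the
  recording protocol (recordings, viewpoints, TRE/VBSE datapoint counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .geometry import FrameId, PointSet3D, RigidTransform
from .labels import DepthMap
from .stereo import PixelPoint, StereoRig, triangulate_pair

__all__ = [
    "FiducialSet",
    "TREResult",
    "VBSEResult",
    "DepthCorrection",
    "ExperimentPlan",
    "PlanCounts",
    "compute_tre",
    "triangulate_fiducials",
    "compute_vbse",
    "estimate_depth_correction",
    "enumerate_plan",
]


@dataclass(frozen=True)
class FiducialSet:
    """Push-pin head centres with per-point level tags.

    ``space`` is ``"level"`` when each point is expressed in its own
    vertebra's frame (the CT-side measurement) or ``"sensor"`` when all
    points live in one sensor frame (the triangulated measurement).
    A complete set has 3 pins per level over 5 levels = 15 points.
    """

    points: PointSet3D
    levels: tuple[FrameId, ...]
    space: str = "level"

    def __post_init__(self) -> None:
        levels = tuple(self.levels)
        object.__setattr__(self, "levels", levels)
        if len(levels) != len(self.points):
            raise ValueError("one level tag per point required")
        if self.space not in ("level", "sensor"):
            raise ValueError("space must be 'level' or 'sensor'")

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class TREResult:
    per_point_mm: np.ndarray
    mean_mm: float
    sd_mm: float

    def __post_init__(self) -> None:
        d = np.asarray(self.per_point_mm, dtype=float)
        object.__setattr__(self, "per_point_mm", d)
        if np.any(d < 0):
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class VBSEResult:
    median_abs_mm: float
    evaluated_pixels: int

    def __post_init__(self) -> None:
        if self.median_abs_mm < 0 or self.evaluated_pixels < 0:
            raise ValueError("VBSE fields must be non-negative")


@dataclass(frozen=True)
class DepthCorrection:
    """Focal scale zeroing the median z-deviation, and the equivalent
    per-camera focal adjustment in pixels."""

    scale: float
    delta_f_px: float
    residual_median_mm: float

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def compute_tre(
    ct_fiducials: FiducialSet,
    chains: dict[FrameId, RigidTransform],
    sensor_fiducials: FiducialSet,
) -> TREResult:
    """Per-fiducial 3D distance after mapping each CT point through the
    chain of the level it is inserted in.

    The CT set must be in level space and the sensor set in sensor space,
    corresponded by index.  The standard deviation is the sample SD (ddof=1)
    when more than one point is present.
    """
    if ct_fiducials.space != "level":
        raise ValueError("ct_fiducials must be expressed in level frames")
    if sensor_fiducials.space != "sensor":
        raise ValueError("sensor_fiducials must be expressed in the sensor frame")
    if len(ct_fiducials) != len(sensor_fiducials):
        raise ValueError("fiducial sets must be corresponded by index")
    missing = sorted(set(ct_fiducials.levels) - set(chains))
    if missing:
        raise ValueError(f"no transformation chain for level(s): {', '.join(missing)}")

    dists = np.empty(len(ct_fiducials))
    for i, (p, level) in enumerate(zip(ct_fiducials.points.points, ct_fiducials.levels)):
        mapped = chains[level].apply(p)
        dists[i] = np.linalg.norm(mapped - sensor_fiducials.points.points[i])
    sd = float(np.std(dists, ddof=1)) if len(dists) > 1 else 0.0
    return TREResult(per_point_mm=dists, mean_mm=float(np.mean(dists)), sd_mm=sd)


def triangulate_fiducials(
    rig: StereoRig,
    left_blobs: list[PixelPoint],
    right_blobs: list[PixelPoint],
    levels: tuple[FrameId, ...],
) -> FiducialSet:
    """Triangulate corresponded push-pin blob detections into sensor space,
    preserving the level tags."""
    if len(left_blobs) != len(right_blobs) or len(left_blobs) != len(levels):
        raise ValueError(
            f"blob/level count mismatch: {len(left_blobs)} left, "
            f"{len(right_blobs)} right, {len(levels)} levels"
        )
    pts = np.array([triangulate_pair(rig, l, r) for l, r in zip(left_blobs, right_blobs)])
    return FiducialSet(
        points=PointSet3D(pts, frame=rig.sensor_frame),
        levels=tuple(levels),
        space="sensor",
    )


def compute_vbse(rendered: DepthMap, measured: DepthMap) -> VBSEResult:
    """Median absolute depth difference over pixels valid in both maps.

    The even-count median is the mean of the two central values.  Raises if
    the valid regions do not overlap.
    """
    if rendered.values.shape != measured.values.shape:
        raise ValueError(
            f"depth map shapes differ: {rendered.values.shape} vs {measured.values.shape}"
        )
    mask = rendered.valid_mask & measured.valid_mask
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no pixel is valid in both depth maps")
    diff = np.abs(rendered.values[mask] - measured.values[mask])
    return VBSEResult(median_abs_mm=float(np.median(diff)), evaluated_pixels=n)


def estimate_depth_correction(
    true_z: np.ndarray,
    measured_z: np.ndarray,
    fx_px: float = 1400.0,
) -> DepthCorrection:
    """Find the focal scale s with median(s * measured - true) = 0.

    For positive depths the median deviation is monotone increasing in s, so
    the zero is bracketed and found by Brent's method.  ``delta_f_px`` is
    the implied focal-length adjustment (s - 1) * fx.
    """
    true_z = np.asarray(true_z, dtype=float).ravel()
    measured_z = np.asarray(measured_z, dtype=float).ravel()
    if len(true_z) == 0 or len(true_z) != len(measured_z):
        raise ValueError("need equal-length, non-empty depth lists")
    if np.any(true_z <= 0) or np.any(measured_z <= 0):
        raise ValueError("depths must be positive")

    def median_dev(s: float) -> float:
        return float(np.median(s * measured_z - true_z))

    lo, hi = 0.5, 2.0
    while median_dev(lo) > 0 and lo > 1e-3:
        lo /= 2
    while median_dev(hi) < 0 and hi < 1e3:
        hi *= 2
    scale = float(brentq(median_dev, lo, hi, xtol=1e-12))
    return DepthCorrection(
        scale=scale,
        delta_f_px=(scale - 1.0) * fx_px,
        residual_median_mm=median_dev(scale),
    )


@dataclass(frozen=True)
class ExperimentPlan:
    """The recording protocol's bookkeeping parameters.

    Defaults reproduce the full cadaveric study plan: 10 specimens with
    pedicle screws in both pedicles of L1-L5 (10 screws), 4 surgical steps
    per screw, 2 sensors; push-pins in both transverse processes and the
    spinous process of each of 5 levels (15 pins); 6 standardized viewpoints
    per sensor for the static TRE scene; the first 40 surgical recordings
    per evaluated specimen enter the VBSE analysis.  One specimen is
    excluded from quantitative evaluation (intact soft tissue), leaving 9.
    """

    specimens: int = 10
    evaluated_specimens: int = 9
    levels: int = 5
    screws_per_level: int = 2
    steps_per_screw: int = 4
    sensors: int = 2
    pushpins_per_level: int = 3
    viewpoints_per_sensor: int = 6
    vbse_recordings_per_specimen: int = 40


@dataclass(frozen=True)
class PlanCounts:
    recordings_per_specimen: int
    tre_datapoints_per_specimen: int
    tre_datapoints_total: int
    viewpoints_total: int
    vbse_recordings_total: int
    pushpins_per_specimen: int
    tre_viewpoints_per_specimen: int


def enumerate_plan(plan: ExperimentPlan = ExperimentPlan()) -> PlanCounts:
    """Deterministically enumerate every record implied by the protocol."""
    screws = plan.levels * plan.screws_per_level
    pins = plan.levels * plan.pushpins_per_level
    tre_viewpoints = plan.viewpoints_per_sensor * plan.sensors
    return PlanCounts(
        recordings_per_specimen=screws * plan.steps_per_screw * plan.sensors,
        tre_datapoints_per_specimen=pins * plan.viewpoints_per_sensor * plan.sensors,
        tre_datapoints_total=plan.evaluated_specimens * pins * tre_viewpoints,
        viewpoints_total=plan.specimens * screws * plan.sensors,
        vbse_recordings_total=plan.evaluated_specimens
        * plan.vbse_recordings_per_specimen
        * plan.sensors,
        pushpins_per_specimen=pins,
        tre_viewpoints_per_specimen=tre_viewpoints,
    )
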