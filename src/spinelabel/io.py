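"""Readers and writers for the pipeline's on-disk formats.

* rigid transforms: YAML/JSON, 4x4 row-major homogeneous matrix with
  explicit source/target frame labels
* stereo camera parameters: YAML/JSON schema (per-camera intrinsics plus a
  4x4 right-from-left matrix)
* tracked pose streams: CSV with a row-major 3x4 pose per sample
* depth maps: PFM (32-bit float, mm, NaN = invalid) and 16-bit PNG at
  0.1 mm per unit with 0 = invalid
* meshes: PLY / STL through trimesh
* frame-label archives: one directory per recording with per-frame pose
  JSON and depth PFM files
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

from .geometry import RigidTransform, TimedPose
from .labels import DepthMap, FrameLabel, PoseStream
from .stereo import CameraIntrinsics, StereoRig

__all__ = [
    "transform_to_dict",
    "transform_from_dict",
    "save_transform",
    "load_transform",
    "save_rig",
    "load_rig",
    "save_pose_streams_csv",
    "load_pose_streams_csv",
    "write_pfm",
    "read_pfm",
    "write_depth_png16",
    "read_depth_png16",
    "save_mesh",
    "load_mesh",
    "save_labels",
    "load_labels",
]

PNG16_MM_PER_UNIT = 0.1


# -- transforms --------------------------------------------------------------


def transform_to_dict(t: RigidTransform) -> dict:
    return {
        "source": t.source,
        "target": t.target,
        "matrix": [[float(x) for x in row] for row in t.matrix],
    }


def transform_from_dict(d: dict) -> RigidTransform:
    return RigidTransform.from_matrix(np.array(d["matrix"], dtype=float), d["source"], d["target"])


def save_transform(t: RigidTransform, path: str | Path) -> None:
    path = Path(path)
    data = transform_to_dict(t)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_transform(path: str | Path) -> RigidTransform:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return transform_from_dict(data)


# -- cameras -----------------------------------------------------------------


def _cam_to_dict(cam: CameraIntrinsics) -> dict:
    return {
        "fx": cam.fx, "fy": cam.fy, "cx": cam.cx, "cy": cam.cy,
        "width": cam.width, "height": cam.height,
    }


def save_rig(rig: StereoRig, path: str | Path) -> None:
    data = {
        "sensor_frame": rig.sensor_frame,
        "left": _cam_to_dict(rig.left),
        "right": _cam_to_dict(rig.right),
        "right_from_left": transform_to_dict(rig.right_from_left),
    }
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))


def load_rig(path: str | Path) -> StereoRig:
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
    return StereoRig(
        left=CameraIntrinsics(**data["left"]),
        right=CameraIntrinsics(**data["right"]),
        right_from_left=transform_from_dict(data["right_from_left"]),
        sensor_frame=data["sensor_frame"],
    )


# -- pose streams ------------------------------------------------------------

_POSE_COLS = [f"r{i}{j}" for i in range(3) for j in range(3)] + ["tx", "ty", "tz"]


def save_pose_streams_csv(streams: dict[str, PoseStream], path: str | Path) -> None:
    """CSV schema: timestamp_s, marker_id, 12 row-major 3x4 pose floats,
    registration_error_mm.  All markers interleaved, sorted by timestamp."""
    rows = []
    for stream in streams.values():
        for s in stream.samples:
            m = s.transform.matrix
            row = {"timestamp_s": s.timestamp, "marker_id": stream.marker}
            for i in range(3):
                for j in range(3):
                    row[f"r{i}{j}"] = m[i, j]
            row["tx"], row["ty"], row["tz"] = m[:3, 3]
            row["registration_error_mm"] = (
                np.nan if s.registration_error is None else s.registration_error
            )
            rows.append(row)
    df = pd.DataFrame(rows, columns=["timestamp_s", "marker_id", *_POSE_COLS, "registration_error_mm"])
    df = df.sort_values(["timestamp_s", "marker_id"], kind="stable")
    df.to_csv(path, index=False)


def load_pose_streams_csv(path: str | Path) -> dict[str, PoseStream]:
    df = pd.read_csv(path)
    streams: dict[str, PoseStream] = {}
    for marker, group in df.groupby("marker_id", sort=True):
        group = group.sort_values("timestamp_s", kind="stable")
        samples = []
        for _, row in group.iterrows():
            R = np.array([[row[f"r{i}{j}"] for j in range(3)] for i in range(3)])
            t = np.array([row["tx"], row["ty"], row["tz"]])
            err = row["registration_error_mm"]
            samples.append(
                TimedPose(
                    float(row["timestamp_s"]),
                    RigidTransform(R, t, source=str(marker), target="O"),
                    registration_error=None if np.isnan(err) else float(err),
                )
            )
        streams[str(marker)] = PoseStream(marker=str(marker), samples=tuple(samples))
    return streams


# -- depth maps --------------------------------------------------------------


def write_pfm(depth: DepthMap, path: str | Path) -> None:
    """Little-endian single-channel PFM; rows stored bottom-up per the spec
    of the format; invalid pixels stay NaN."""
    values = depth.values.astype(np.float32)
    with open(path, "wb") as f:
        f.write(b"Pf\n")
        f.write(f"{values.shape[1]} {values.shape[0]}\n".encode())
        f.write(b"-1.0\n")  # negative scale => little endian
        f.write(values[::-1].tobytes())


def read_pfm(path: str | Path) -> DepthMap:
    with open(path, "rb") as f:
        header = f.readline().strip()
        if header != b"Pf":
            raise ValueError(f"not a single-channel PFM file: header {header!r}")
        dims = f.readline().decode()
        m = re.match(r"^\s*(\d+)\s+(\d+)\s*$", dims)
        if not m:
            raise ValueError(f"bad PFM dimensions line: {dims!r}")
        w, h = int(m.group(1)), int(m.group(2))
        scale = float(f.readline().decode().strip())
        dtype = "<f4" if scale < 0 else ">f4"
        data = np.frombuffer(f.read(w * h * 4), dtype=dtype).reshape(h, w)
    return DepthMap(np.ascontiguousarray(data[::-1]).astype(float))


def write_depth_png16(depth: DepthMap, path: str | Path) -> None:
    """16-bit PNG at 0.1 mm per unit; 0 marks invalid pixels.  Valid depths
    above 6553.5 mm are not representable and raise."""
    import imageio.v3 as iio

    v = depth.values
    scaled = np.where(np.isfinite(v), np.round(v / PNG16_MM_PER_UNIT), 0.0)
    if scaled.max() > np.iinfo(np.uint16).max:
        raise ValueError("depth exceeds the 16-bit PNG encoding range (6553.5 mm)")
    iio.imwrite(Path(path), scaled.astype(np.uint16))


def read_depth_png16(path: str | Path) -> DepthMap:
    import imageio.v3 as iio

    raw = np.asarray(iio.imread(Path(path))).astype(float)
    values = np.where(raw > 0, raw * PNG16_MM_PER_UNIT, np.nan)
    return DepthMap(values)


# -- meshes ------------------------------------------------------------------


def save_mesh(vertices: np.ndarray, faces: np.ndarray, path: str | Path) -> None:
    """PLY or STL export, by file extension."""
    trimesh.Trimesh(vertices=vertices, faces=faces, process=False).export(str(path))


def load_mesh(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    mesh = trimesh.load(str(path), process=False, force="mesh")
    return np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces, dtype=int)


# -- frame-label archives ----------------------------------------------------


def save_labels(labels: list[FrameLabel], directory: str | Path) -> None:
    """Archive layout: ``frame_NNNNNN.json`` (sensor, timestamp, per-level
    pose matrices) plus ``frame_NNNNNN.pfm`` when a depth map is present."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, label in enumerate(labels):
        stem = f"frame_{i:06d}"
        data = {
            "sensor": label.sensor,
            "timestamp_s": label.timestamp,
            "per_level_pose": {
                level: transform_to_dict(t) for level, t in label.per_level_pose.items()
            },
            "depth_file": f"{stem}.pfm" if label.depth is not None else None,
        }
        (directory / f"{stem}.json").write_text(json.dumps(data, indent=2))
        if label.depth is not None:
            write_pfm(label.depth, directory / f"{stem}.pfm")


def load_labels(directory: str | Path) -> list[FrameLabel]:
    directory = Path(directory)
    labels = []
    for jf in sorted(directory.glob("frame_*.json")):
        data = json.loads(jf.read_text())
        depth = None
        if data.get("depth_file"):
            depth = read_pfm(directory / data["depth_file"])
        labels.append(
            FrameLabel(
                sensor=data["sensor"],
                timestamp=float(data["timestamp_s"]),
                per_level_pose={
                    level: transform_from_dict(d) for level, d in data["per_level_pose"].items()
                },
                depth=depth,
            )
        )
    return labels
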