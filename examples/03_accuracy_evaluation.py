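"""Setup accuracy: target registration error and visible bone surface error.

Under realistic tracker noise (0.05 deg / 0.05 mm), compares the fifteen
push-pin fiducials mapped through the calibrated chain against their
independently triangulated stereo positions (TRE), and the rendered
ground-truth depth label against the sensor's measured depth map (VBSE,
median over the first 10 frames as in the recording protocol).
"""

import numpy as np

from spinelabel.evaluation import FiducialSet, compute_tre, compute_vbse, triangulate_fiducials
from spinelabel.geometry import PointSet3D
from spinelabel.labels import generate_labels
from spinelabel.scene import SceneConfig, build_scene, simulate_ots_stream, simulate_stereo_observations

config = SceneConfig(seed=3, image_width=480, image_height=270, fx_px=350.0,
                     ots_rot_deg_sigma=0.05, ots_trans_mm_sigma=0.05,
                     sphere_jitter_mm_sigma=0.02, pixel_sigma_px=0.1)
scene = build_scene(config)
viewpoint = scene.viewpoints[0]
rig = config.rig(viewpoint.sensor)
rng = np.random.default_rng(config.seed)

s_from_o = scene.calibrate(viewpoint, rng)
streams = simulate_ots_stream(scene.specimen, 0.5, config, scene.ots_from_world, rng)
obs = simulate_stereo_observations(viewpoint.world_from_sensor(), scene.specimen,
                                   config, rng=rng, render=True)

# CT-side fiducials live in their own vertebra frames
pts, levels = [], []
for level, pins in scene.specimen.pushpins_level.items():
    pts.append(pins.points)
    levels.extend([level] * len(pins))
ct = FiducialSet(PointSet3D(np.vstack(pts), "level"), tuple(levels), "level")
sensor = triangulate_fiducials(rig, list(obs.blobs_left), list(obs.blobs_right), obs.blob_levels)

frame_times = np.arange(10) / config.rgbd_rate_hz
labels = generate_labels(frame_times, streams, s_from_o, scene.specimen.attachments,
                         scene.specimen.models, rig.left, render=True)

tre = compute_tre(ct, labels[0].per_level_pose, sensor)
print(f"TRE: {tre.mean_mm:.3f} +/- {tre.sd_mm:.3f} mm over {len(tre.per_point_mm)} push-pins")

per_frame = [compute_vbse(label.depth, obs.measured_depth).median_abs_mm for label in labels]
print(f"VBSE: {np.median(per_frame):.3f} mm (median of {len(per_frame)} per-frame medians)")
# TRE lands in the low-millimetre regime (dominated by the noisy
# single-frame calibration); VBSE stays sub-millimetre because the depth
# comparison is insensitive to in-plane pose error.
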