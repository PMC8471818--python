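"""Extrinsic calibration of the optical tracker to a stereo sensor.

Builds the synthetic OR scene, observes the dual-domain phantom (chessboard
for the cameras, four-sphere marker for the tracker) at one standardized
viewpoint, solves for the sensor-from-tracker transform and compares it
with the scene's ground truth.
"""

import numpy as np

from spinelabel.scene import SceneConfig, build_scene

config = SceneConfig(seed=1, image_width=480, image_height=270, fx_px=350.0,
                     pixel_sigma_px=0.1, sphere_jitter_mm_sigma=0.02)
scene = build_scene(config)
viewpoint = scene.viewpoints[0]  # 0 deg, axial-coronal plane, 600 mm stand-off

estimated = scene.calibrate(viewpoint, np.random.default_rng(config.seed))
true = scene.true_sensor_from_ots(viewpoint)
delta = estimated.inverse() @ true

print(f"viewpoint: {viewpoint.plane} {viewpoint.angle_deg:+.0f} deg, sensor {viewpoint.sensor}")
print(f"estimated sensor<-tracker translation [mm]: {np.round(estimated.translation, 2)}")
print(f"rotation error:    {np.degrees(delta.rotation_angle_rad()) * 3600:.2f} arcsec")
print(f"translation error: {np.linalg.norm(delta.translation):.4f} mm")
# With 0.1 px corner noise on the 25 triangulated chessboard corners the
# single-frame solve lands within roughly a millimetre of the true
# extrinsic; with zero noise the recovery is exact to numerical precision.
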