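# Methods

## Model and procedure

The package treats ground-truth labelling as a chain of rigid (SE(3))
transforms between named coordinate frames: tracker `O`, stereo sensors
`S1`/`S2` (each defined as its rig's left-camera frame), markers `M1..M5`
and vertebral levels `L1..L5`. All lengths are millimetres and all
timestamps seconds, everywhere; a transform stores its source and target
frame and composition refuses mismatched chains, which removes the most
common class of silent frame errors.

**Absolute orientation.** Point-set registration uses Horn's closed-form
unit-quaternion method: the rotation is the eigenvector of the 4×4
quaternion profile matrix with the largest eigenvalue, re-orthonormalised
by SVD against rounding, and the translation aligns the centroids. The
SVD-based Kabsch solution serves as an independent oracle in the tests,
never as the implementation. Degenerate inputs (fewer than three points,
collinear configurations detected by a relative second-singular-value
threshold of 1e-9) raise rather than return garbage.

**Stereo model.** Cameras are ideal pinholes (+z forward, +x right, +y
down, pixel-centre convention, origin top-left). Distortion is zero by
construction in the synthetic world; a coefficient hook exists but is
outside the tested surface. Triangulation is the linear DLT: the
homogeneous 4×4 system stacking both views' cross-product rows, solved by
SVD; the two-ray midpoint solution is retained as a cross-check. Depth for
a rectified rig follows z = f·b/d, which makes the focal correction exact:
scaling both cameras' focal lengths by s scales reconstructed depth at
fixed disparity by exactly s.

**Extrinsic calibration.** The dual-domain phantom is a 6×9 chessboard
with 30 mm squares (40 inner corners) rigidly joined to four co-planar
tracker spheres whose coordinates are stored in the board frame. A tracked
phantom pose is accepted only if the marker geometry registration error is
strictly below 0.1 mm. The last three chessboard rows — the rows with the
largest row index, i.e. farthest from the board origin — are dropped from
all point sets before the solve, leaving 25 correspondences per frame: the
tracked pose's rotational error grows with each row's lever arm, so the
far rows carry the least reliable tracker-side coordinates. The board
origin is placed at the marker-proximal corner precisely so that this
truncation removes the marker-distal rows. The calibration itself is a
single-frame Horn fit of the pose-mapped board corners onto the
stereo-triangulated corners.

**Labels.** For each camera frame the tracked sample with the nearest
timestamp is selected (exact midpoints resolve to the earlier sample); the
chain sensor←tracker ∘ tracker←marker(t) ∘ marker←level gives each level's
pose. Depth labels come from a hand-rolled z-buffer rasteriser: a pixel is
covered iff the projected triangle contains the pixel centre, with the
top-left rule deciding edge ties so adjacent triangles cover a shared edge
exactly once; 1/z is interpolated linearly in screen space
(perspective-correct for planar triangles); back-face culling is off;
per-level renders are merged by pixel-wise minimum into one map per frame,
matching a sensor's single view of the exposed spine. Triangles closer
than 1 mm to the camera are skipped instead of clipped — synthetic scenes
keep geometry far in front of the camera.

**Accuracy measures.** TRE is the Euclidean distance between a CT-measured
push-pin head mapped through its level's chain and the same pin
triangulated from the stereo pair; it is reported as mean ± sample SD plus
the full distribution. VBSE is the median absolute per-pixel difference
over pixels valid in both the rendered and the measured depth map; a
recording-level VBSE is the median of the per-frame medians over the first
10 frames (the per-recording aggregation is a declared choice; the
protocol fixes only the 10-frame window). Medians of even counts are the
mean of the central pair — pinned for bit-reproducibility. The depth
correction finds the focal scale s with median(s·measured − true) = 0 by
Brent root-finding (the median deviation is monotone in s for positive
depths, with automatic bracket expansion) and reports the equivalent
per-camera focal adjustment (s−1)·fx.

## The synthetic scene

The generator emulates the acquisition conditions: a five-level specimen
(levels 35 mm apart along the cranio-caudal axis with a gentle lordotic
tilt), one four-sphere marker per level protruding anteriorly toward the
tracker, three push-pins per level (both transverse processes and the
spinous process — 15 in total) placed exactly on mesh vertices, a tracker
at ~335 Hz, stereo rigs at 30 Hz / 1920×1080 (fx 1400 px, baseline 63 mm —
plausible stand-ins, since the protocol does not fix them numerically), and
the twelve standardized viewpoints: for each of the two plane alignments
(baseline along the axial-coronal or sagittal-coronal plane intersection)
both sensors at 0° plus +15°/+30° for sensor 1 and −15°/−30° for sensor 2,
all at 600 mm facing the scene centre.

Vertebra meshes are parametric stand-ins — an icosphere displaced radially
into an ellipsoidal body with spinous and transverse bumps — which keeps
them watertight, deterministic and anatomy-free; the pipeline itself is
geometry-agnostic. Marker sphere layouts vary per level so the
inter-sphere distance multisets differ pairwise by more than 1 mm,
making markers unambiguously identifiable.

Noise model and defaults: tracker pose noise is applied **in the marker
frame** (axis-angle rotation about the sphere centroid, σ 0.05°;
translation σ 0.05 mm per axis) so that lever-arm amplification toward the
distant anatomy — the dominant physical error source of marker-based
tracking — is reproduced. The reported registration error is synthesised
consistently: sphere centres are jittered (σ 0.02 mm, comfortably below
the 0.1 mm phantom gate, as for a healthy physical marker) and the RMS of
a best-fit realignment is attached to the sample. Pixel noise is Gaussian
on projected corners/blobs; a scalar `depth_scale_bias` emulates the
systematic depth error of imperfect intrinsics. One seeded generator
drives everything: identical config + seed reproduce every stream, image
and map bit-identically.

What the generator does **not** emulate: real corner/blob detection on
images (observations are projected points plus noise; a simple
anti-aliased disk rasteriser and centroid detector stand in for blob
detection), photorealistic RGB, soft tissue, occlusion by hands or
instruments, rolling shutter, lens distortion, and the domain mismatch
between preoperative models and the intraoperative scene. Passing tests
therefore validate the geometry and estimation pipeline, not the
performance of any physical sensor.

## Problem sizes and numerical choices

Tests and the acceptance script run renders at 480×270 with fx 350 px
(intrinsics scaled with the image, so the field of view matches the
full-resolution default) and meshes at icosphere subdivision 2 (~320
faces/level) — the package's choice of problem size for its own test
suite; `SceneConfig` defaults stay at the full study conditions. ICP uses
brute-force nearest neighbours (`cdist` + `argmin`, lowest index on ties)
for determinism at test scale, with a full Horn re-fit per iteration and a
1e-8 mm RMS-improvement stop. Rotation validity is enforced at 1e-8 on
construction and holds to 1e-9 through composition chains in tests.

## Design choices that were genuinely open

* The protocol does not state whether label depth maps are rendered per
  level or merged — merged (z-buffer minimum) is declared here.
* TRE pooling across sensors/viewpoints: pooled over all datapoints.
* The depth correction applies one scalar to fx and fy of both cameras;
  depth depends on focal length and baseline jointly, and a common scale
  is the minimal model that zeroes the median z-deviation.
* The board origin corner and row-indexing direction are conventions
  declared above; anyone comparing against externally calibrated phantom
  files must account for them.
* The ICP variant and its iteration/tolerance settings are declared
  defaults, not inferred from any reference implementation.

## Known limitations

The z-buffer rasteriser is pure NumPy and processes triangles in a Python
loop — adequate for the test-scale images, not for real-time use. The
depth-correction estimator assumes a multiplicative depth error; additive
or distance-dependent biases would need a richer model. The synthetic
scene's clock model is a shared time base with optional constant offset
and bounded jitter; independent clock drift is out of scope.
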