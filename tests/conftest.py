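import numpy as np
import pytest

from spinelabel.scene import SceneConfig, build_scene
from spinelabel.stereo import CameraIntrinsics, StereoRig


def small_config(**overrides) -> SceneConfig:
    """Study-condition scene at reduced image resolution (intrinsics scaled
    with the image so the field of view is unchanged); noise off unless a
    test turns it on."""
    base = dict(
        seed=0,
        image_width=480,
        image_height=270,
        fx_px=350.0,
        ots_rot_deg_sigma=0.0,
        ots_trans_mm_sigma=0.0,
        sphere_jitter_mm_sigma=0.0,
        pixel_sigma_px=0.0,
    )
    base.update(overrides)
    return SceneConfig(**base)


@pytest.fixture(scope="session")
def noiseless_scene():
    return build_scene(small_config())


@pytest.fixture
def default_rig() -> StereoRig:
    cam = CameraIntrinsics(fx=1400.0, fy=1400.0, cx=960.0, cy=540.0, width=1920, height=1080)
    return StereoRig.rectified(cam, 63.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# independent reference implementations (oracles) shared across test modules


def kabsch_fit(src: np.ndarray, dst: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """SVD-based least-squares rigid fit (Kabsch), independent of the
    quaternion solver under test.  Returns (R, t)."""
    sc, dc = src.mean(axis=0), dst.mean(axis=0)
    H = (src - sc).T @ (dst - dc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, dc - R @ sc


def dlt_triangulate(P1: np.ndarray, P2: np.ndarray, uv1: np.ndarray, uv2: np.ndarray) -> np.ndarray:
    """Reference two-view DLT: same homogeneous formulation as the code
    under test but solved independently, via the eigenvector of A^T A with
    the smallest eigenvalue rather than an SVD of A."""
    A = np.vstack(
        [
            uv1[0] * P1[2] - P1[0],
            uv1[1] * P1[2] - P1[1],
            uv2[0] * P2[2] - P2[0],
            uv2[1] * P2[2] - P2[1],
        ]
    )
    w, v = np.linalg.eigh(A.T @ A)
    X = v[:, 0]
    return X[:3] / X[3]
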