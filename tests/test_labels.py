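"""Timestamp matching, the transformation chain, and depth rendering."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from spinelabel.geometry import RigidTransform, TimedPose
from spinelabel.labels import (
    DepthMap,
    MarkerAttachment,
    PoseStream,
    generate_labels,
    merge_depth,
    nearest_pose,
    pose_chain,
    render_depth,
)
from spinelabel.scene import simulate_ots_stream, simulate_stereo_observations
from spinelabel.stereo import CameraIntrinsics

from conftest import small_config


def _stream(ts, marker="M1"):
    return PoseStream(
        marker=marker,
        samples=tuple(TimedPose(t, RigidTransform.identity(marker, "O")) for t in ts),
    )


class TestNearestPose:
    def test_picks_minimum_distance_sample(self):
        s = _stream([0.0, 2.985e-3, 5.970e-3, 8.955e-3, 11.940e-3])
        assert nearest_pose(s, 10e-3).timestamp == pytest.approx(8.955e-3)

    def test_exact_timestamp_returns_that_sample(self):
        s = _stream([0.0, 1.0, 2.0])
        assert nearest_pose(s, 1.0).timestamp == 1.0

    def test_tie_breaks_to_earlier_sample(self):
        s = _stream([0.0, 2.0])
        assert nearest_pose(s, 1.0).timestamp == 0.0

    def test_query_outside_range_clamps(self):
        s = _stream([1.0, 2.0])
        assert nearest_pose(s, 0.0).timestamp == 1.0
        assert nearest_pose(s, 9.0).timestamp == 2.0

    def test_monotone_queries_yield_monotone_samples(self):
        """Label poses stay time-ordered for monotone frame timestamps."""
        s = _stream(np.arange(100) * (1 / 335))
        picked = [nearest_pose(s, t).timestamp for t in np.linspace(0, 0.29, 40)]
        assert np.all(np.diff(picked) >= 0)

    def test_empty_stream_raises(self):
        with pytest.raises(ValueError):
            nearest_pose(PoseStream(marker="M1", samples=()), 0.0)

    def test_non_monotone_stream_rejected(self):
        with pytest.raises(ValueError):
            _stream([0.0, 2.0, 1.0])


class TestPoseChain:
    def test_all_identity(self):
        out = pose_chain(
            RigidTransform.identity("O", "S1"),
            TimedPose(3.5, RigidTransform.identity("M1", "O")),
            MarkerAttachment("L1", RigidTransform.identity("L1", "M1")),
        )
        assert np.allclose(out.transform.matrix, np.eye(4))
        assert out.timestamp == 3.5
        assert out.transform.source == "L1" and out.transform.target == "S1"

    def test_translations_add(self):
        a = RigidTransform(np.eye(3), [1, 0, 0], source="O", target="S1")
        b = TimedPose(0.0, RigidTransform(np.eye(3), [0, 2, 0], source="M1", target="O"))
        c = MarkerAttachment("L1", RigidTransform(np.eye(3), [0, 0, 3], source="L1", target="M1"))
        assert np.allclose(pose_chain(a, b, c).transform.translation, [1, 2, 3])

    def test_matches_homogeneous_product(self, rng):
        def rand(s, t):
            return RigidTransform(
                special_ortho_group.rvs(3, random_state=rng), rng.normal(size=3) * 50,
                source=s, target=t,
            )

        a = rand("O", "S1")
        b = rand("M1", "O")
        c = rand("L1", "M1")
        out = pose_chain(a, TimedPose(0.0, b), MarkerAttachment("L1", c))
        assert np.allclose(out.transform.matrix, a.matrix @ b.matrix @ c.matrix, atol=1e-12)


def _square(z, half=500.0):
    """Two triangles spanning a fronto-parallel square at depth z."""
    v = np.array(
        [[-half, -half, z], [half, -half, z], [half, half, z], [-half, half, z]]
    )
    f = np.array([[0, 1, 2], [0, 2, 3]])
    return v, f


@pytest.fixture
def small_cam():
    return CameraIntrinsics(fx=50.0, fy=50.0, cx=31.5, cy=23.5, width=64, height=48)


class TestRenderDepth:
    def test_full_frustum_square_fills_every_pixel(self, small_cam):
        depth = render_depth(small_cam, _square(600.0), RigidTransform.identity("m", "cam"))
        assert depth.valid_mask.all()
        assert np.allclose(depth.values, 600.0, atol=1e-9)

    def test_zbuffer_keeps_nearer_surface(self, small_cam):
        v1, f1 = _square(600.0)
        v2, f2 = _square(500.0)
        v = np.vstack([v1, v2])
        f = np.vstack([f1, f2 + 4])
        depth = render_depth(small_cam, (v, f), RigidTransform.identity("m", "cam"))
        assert np.allclose(depth.values, 500.0, atol=1e-9)

    def test_no_coverage_gives_all_invalid(self, small_cam):
        v, f = _square(600.0, half=1.0)
        pose = RigidTransform(np.eye(3), [5000.0, 0, 0], source="m", target="cam")
        depth = render_depth(small_cam, (v, f), pose)
        assert not depth.valid_mask.any()

    def test_sphere_depth_matches_analytic_ray_intersection(self):
        """z-buffer depth of an icosphere equals the first analytic
        ray-sphere intersection (rasterisation-limited)."""
        import trimesh

        cam = CameraIntrinsics(fx=300.0, fy=300.0, cx=63.5, cy=47.5, width=128, height=96)
        sphere = trimesh.creation.icosphere(subdivisions=3, radius=50.0)
        center = np.array([0.0, 0.0, 600.0])
        pose = RigidTransform(np.eye(3), center, source="m", target="cam")
        depth = render_depth(cam, (np.asarray(sphere.vertices), np.asarray(sphere.faces)), pose)

        # principal-point pixel
        u, v = 64, 48
        assert depth.valid_mask[v, u]

        def analytic(u, v):
            d = np.array([(u - cam.cx) / cam.fx, (v - cam.cy) / cam.fy, 1.0])
            # smallest positive t with |t*d - center| = r
            a = d @ d
            b = -2 * d @ center
            c = center @ center - 50.0**2
            disc = b * b - 4 * a * c
            if disc < 0:
                return np.nan
            t = (-b - np.sqrt(disc)) / (2 * a)
            return t * d[2]

        assert abs(depth.values[v, u] - analytic(u, v)) < 0.5
        assert abs(depth.values[v, u] - 550.0) < 0.5

        # convexity property: all valid pixels near the disc centre agree
        # with the analytic first intersection
        proj_r = cam.fx * 50.0 / 600.0
        for du in (-10, -5, 0, 5, 10):
            for dv in (-8, 0, 8):
                uu, vv = u + du, v + dv
                if np.hypot(du, dv) < 0.6 * proj_r and depth.valid_mask[vv, uu]:
                    assert abs(depth.values[vv, uu] - analytic(uu, vv)) < 0.5

    def test_invariant_to_face_and_vertex_permutation(self, small_cam, rng):
        v, f = _square(600.0)
        base = render_depth(small_cam, (v, f), RigidTransform.identity("m", "cam"))
        perm = rng.permutation(len(v))
        inv = np.argsort(perm)
        v2 = v[perm]
        f2 = inv[f][::-1]  # re-labelled vertices, reversed face order
        out = render_depth(small_cam, (v2, f2), RigidTransform.identity("m", "cam"))
        assert np.array_equal(base.valid_mask, out.valid_mask)
        assert np.allclose(base.values, out.values, atol=1e-12, equal_nan=True)

    def test_adjacent_triangles_cover_shared_edge_once(self, small_cam):
        """Top-left fill rule: a shared edge belongs to exactly one triangle
        (no holes, and the two single-triangle renders do not overlap)."""
        v, f = _square(600.0, half=200.0)
        both = render_depth(small_cam, (v, f), RigidTransform.identity("m", "cam"))
        first = render_depth(small_cam, (v, f[:1]), RigidTransform.identity("m", "cam"))
        second = render_depth(small_cam, (v, f[1:]), RigidTransform.identity("m", "cam"))
        union = first.valid_mask | second.valid_mask
        overlap = first.valid_mask & second.valid_mask
        assert np.array_equal(both.valid_mask, union)
        assert not overlap.any()


class TestDepthMap:
    def test_rejects_non_positive_valid_values(self):
        with pytest.raises(ValueError):
            DepthMap(np.array([[1.0, -2.0]]))

    def test_merge_is_pixelwise_minimum(self):
        a = DepthMap(np.array([[500.0, np.nan], [600.0, np.nan]]))
        b = DepthMap(np.array([[550.0, 400.0], [np.nan, np.nan]]))
        m = merge_depth([a, b]).values
        assert m[0, 0] == 500.0 and m[0, 1] == 400.0 and m[1, 0] == 600.0
        assert np.isnan(m[1, 1])


class TestGenerateLabels:
    def test_one_second_at_30hz_gives_30_labels(self, noiseless_scene):
        cfg = noiseless_scene.config
        streams = simulate_ots_stream(
            noiseless_scene.specimen, 1.0, cfg, noiseless_scene.ots_from_world
        )
        vp = noiseless_scene.viewpoints[0]
        ts = np.arange(int(round(cfg.rgbd_rate_hz))) / cfg.rgbd_rate_hz
        labels = generate_labels(
            ts, streams, noiseless_scene.true_sensor_from_ots(vp),
            noiseless_scene.specimen.attachments, noiseless_scene.specimen.models,
            cfg.rig(vp.sensor).left, render=False,
        )
        assert len(labels) == 30
        assert all(set(l.per_level_pose) == set(noiseless_scene.specimen.levels) for l in labels)

    def test_static_scene_label_matches_measured_depth(self, noiseless_scene):
        """Noiseless static scene: the rendered label equals the simulated
        sensor depth map pixel for pixel (same geometry, both paths)."""
        cfg = noiseless_scene.config
        vp = noiseless_scene.viewpoints[0]
        streams = simulate_ots_stream(
            noiseless_scene.specimen, 0.1, cfg, noiseless_scene.ots_from_world
        )
        labels = generate_labels(
            np.array([0.0]), streams, noiseless_scene.true_sensor_from_ots(vp),
            noiseless_scene.specimen.attachments, noiseless_scene.specimen.models,
            cfg.rig(vp.sensor).left, render=True,
        )
        obs = simulate_stereo_observations(
            vp.world_from_sensor(), noiseless_scene.specimen, cfg, render=True
        )
        a, b = labels[0].depth, obs.measured_depth
        assert np.array_equal(a.valid_mask, b.valid_mask)
        assert np.allclose(a.values[a.valid_mask], b.values[b.valid_mask], atol=1e-6)

    def test_z_shifted_chain_shifts_median_depth(self, noiseless_scene):
        """A 2 mm camera-z perturbation of the extrinsic appears as a
        ~2 mm median difference against the measured map."""
        from spinelabel.evaluation import compute_vbse

        cfg = noiseless_scene.config
        vp = noiseless_scene.viewpoints[0]
        streams = simulate_ots_stream(
            noiseless_scene.specimen, 0.1, cfg, noiseless_scene.ots_from_world
        )
        shift = RigidTransform(np.eye(3), [0, 0, 2.0], source=vp.sensor, target=vp.sensor)
        perturbed = shift @ noiseless_scene.true_sensor_from_ots(vp)
        labels = generate_labels(
            np.array([0.0]), streams, perturbed,
            noiseless_scene.specimen.attachments, noiseless_scene.specimen.models,
            cfg.rig(vp.sensor).left, render=True,
        )
        obs = simulate_stereo_observations(
            vp.world_from_sensor(), noiseless_scene.specimen, cfg, render=True
        )
        res = compute_vbse(labels[0].depth, obs.measured_depth)
        assert 1.7 < res.median_abs_mm < 2.3

    def test_empty_stream_names_level(self, noiseless_scene):
        cfg = noiseless_scene.config
        streams = simulate_ots_stream(
            noiseless_scene.specimen, 0.1, cfg, noiseless_scene.ots_from_world
        )
        streams = dict(streams)
        streams["L3"] = PoseStream(marker="M3", samples=())
        with pytest.raises(ValueError, match="L3"):
            generate_labels(
                np.array([0.0]), streams,
                noiseless_scene.true_sensor_from_ots(noiseless_scene.viewpoints[0]),
                noiseless_scene.specimen.attachments, noiseless_scene.specimen.models,
                cfg.rig("S1").left, render=False,
            )
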