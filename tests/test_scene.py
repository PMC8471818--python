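"""The synthetic operating-room scene: specimen, viewpoints, streams,
stereo observations and blob imaging."""

import itertools

import numpy as np
import pytest
import trimesh

from spinelabel.evaluation import estimate_depth_correction
from spinelabel.scene import (
    SceneConfig,
    build_scene,
    detect_blob_centroids,
    make_specimen,
    make_vertebra_mesh,
    rasterize_blobs,
    simulate_ots_stream,
    simulate_stereo_observations,
    standard_viewpoints,
)
from spinelabel.stereo import PixelPoint, triangulate_pair

from conftest import small_config


class TestVertebraMesh:
    def test_watertight_genus_zero(self):
        v, f = make_vertebra_mesh(3, 2)
        m = trimesh.Trimesh(v, f, process=False)
        assert m.is_watertight
        assert m.euler_number == 2

    def test_deterministic(self):
        v1, f1 = make_vertebra_mesh(2, 2)
        v2, f2 = make_vertebra_mesh(2, 2)
        assert np.array_equal(v1, v2) and np.array_equal(f1, f2)

    def test_vertex_count_grows_with_resolution(self):
        n = [len(make_vertebra_mesh(1, r)[0]) for r in (1, 2, 3)]
        assert n[0] < n[1] < n[2]


class TestSpecimen:
    def test_fifteen_pushpins(self, noiseless_scene):
        pts, levels = noiseless_scene.specimen.pushpins_world()
        assert len(pts) == 15
        assert all(levels.count(l) == 3 for l in noiseless_scene.specimen.levels)

    def test_five_markers_of_four_spheres(self, noiseless_scene):
        spheres = noiseless_scene.specimen.marker_spheres
        assert len(spheres) == 5
        assert all(len(s) == 4 for s in spheres.values())

    def test_marker_attachment_roundtrip(self, noiseless_scene):
        """Marker-frame sphere positions mapped level -> marker -> world
        equal the stored world positions."""
        sp = noiseless_scene.specimen
        for level in sp.levels:
            marker = sp.marker_for_level[level]
            via_chain = (sp.level_world[level] @ sp.attachments[level].transform.inverse()).apply(
                sp.marker_spheres[marker].points
            )
            assert np.allclose(via_chain, sp.marker_spheres_world(marker), atol=1e-12)

    def test_marker_geometries_pairwise_distinct(self, noiseless_scene):
        """Inter-sphere distance multisets differ by > 1 mm between any two
        markers, so markers are unambiguously identifiable."""
        sp = noiseless_scene.specimen
        multisets = [
            np.sort(
                np.linalg.norm(p.points[:, None] - p.points[None], axis=-1)[
                    np.triu_indices(4, 1)
                ]
            )
            for p in sp.marker_spheres.values()
        ]
        for a, b in itertools.combinations(multisets, 2):
            assert np.max(np.abs(a - b)) > 1.0

    def test_pushpins_lie_on_mesh_vertices(self, noiseless_scene):
        sp = noiseless_scene.specimen
        for level, pins in sp.pushpins_level.items():
            verts = sp.models[level].vertices
            for p in pins.points:
                assert np.min(np.linalg.norm(verts - p, axis=1)) < 1e-12


class TestStandardViewpoints:
    def test_twelve_viewpoints_six_per_sensor(self):
        vps = standard_viewpoints()
        assert len(vps) == 12
        assert sum(v.sensor == "S1" for v in vps) == 6
        assert sum(v.sensor == "S2" for v in vps) == 6

    def test_distance_is_600mm(self):
        for vp in standard_viewpoints():
            assert np.isclose(np.linalg.norm(vp.position - vp.target), 600.0, atol=1e-9)

    def test_optical_axis_faces_target(self):
        for vp in standard_viewpoints():
            w_from_s = vp.world_from_sensor()
            z_axis = w_from_s.rotation[:, 2]
            to_target = (vp.target - w_from_s.translation) / 600.0
            assert np.allclose(z_axis, to_target, atol=1e-9)

    def test_zero_degree_axial_view_is_antiparallel_to_up(self):
        vp = next(
            v for v in standard_viewpoints() if v.plane == "axial-coronal" and v.angle_deg == 0
        )
        z_axis = vp.world_from_sensor().rotation[:, 2]
        assert np.allclose(z_axis, [0, 0, -1], atol=1e-12)

    def test_plus_minus_15_axes_subtend_30_degrees(self):
        vps = [v for v in standard_viewpoints() if v.plane == "axial-coronal" and abs(v.angle_deg) == 15]
        z1 = vps[0].world_from_sensor().rotation[:, 2]
        z2 = vps[1].world_from_sensor().rotation[:, 2]
        ang = np.degrees(np.arccos(np.clip(z1 @ z2, -1, 1)))
        assert np.isclose(ang, 30.0, atol=1e-9)


class TestOtsStream:
    def test_one_second_gives_335_samples(self, noiseless_scene):
        streams = simulate_ots_stream(
            noiseless_scene.specimen, 1.0, noiseless_scene.config, noiseless_scene.ots_from_world
        )
        assert all(len(s) == 335 for s in streams.values())

    def test_zero_sigma_equals_ground_truth(self, noiseless_scene):
        sp = noiseless_scene.specimen
        streams = simulate_ots_stream(sp, 0.05, noiseless_scene.config, noiseless_scene.ots_from_world)
        for level, stream in streams.items():
            marker = sp.marker_for_level[level]
            true = noiseless_scene.ots_from_world @ sp.marker_world[marker]
            for s in stream.samples:
                assert np.allclose(s.transform.matrix, true.matrix, atol=1e-12)
                assert s.registration_error == 0.0

    def test_translation_noise_sd_matches_config(self):
        cfg = small_config(ots_trans_mm_sigma=0.1)
        scene = build_scene(cfg)
        streams = simulate_ots_stream(scene.specimen, 3.0, cfg, scene.ots_from_world)
        trans = np.array([s.transform.translation for s in streams["L1"].samples])
        sd = trans.std(axis=0)
        assert np.all(np.abs(sd - 0.1) < 0.01)  # within 10% of 0.1 mm

    def test_registration_error_tracks_sphere_jitter(self):
        cfg = small_config(sphere_jitter_mm_sigma=0.02)
        scene = build_scene(cfg)
        streams = simulate_ots_stream(scene.specimen, 0.3, cfg, scene.ots_from_world)
        errs = [s.registration_error for s in streams["L2"].samples]
        assert all(e > 0 for e in errs)
        assert np.mean(errs) < 0.1  # healthy markers pass the phantom gate scale


class TestStereoObservations:
    def test_noiseless_triangulation_closes_loop(self, noiseless_scene):
        """Triangulating any noiseless observation reproduces the
        ground-truth 3D point to < 1e-9 mm."""
        vp = noiseless_scene.viewpoints[0]
        obs = simulate_stereo_observations(
            vp.world_from_sensor(), noiseless_scene.specimen, noiseless_scene.config, render=False
        )
        assert obs.missing_blobs == ()
        rig = noiseless_scene.config.rig(vp.sensor)
        pin_world, _ = noiseless_scene.specimen.pushpins_world()
        sensor_true = vp.world_from_sensor().inverse().apply(pin_world)
        for l, r, t in zip(obs.blobs_left, obs.blobs_right, sensor_true):
            assert np.max(np.abs(triangulate_pair(rig, l, r) - t)) < 1e-9

    def test_depth_bias_recovered_by_correction_estimator(self, noiseless_scene):
        """A 2% systematic depth bias in the measured map is exactly undone
        by the estimated focal scale 1/1.02."""
        cfg = small_config(depth_scale_bias=1.02)
        scene = build_scene(cfg)
        vp = scene.viewpoints[0]
        obs = simulate_stereo_observations(vp.world_from_sensor(), scene.specimen, cfg, render=True)
        truth = simulate_stereo_observations(
            vp.world_from_sensor(), scene.specimen, small_config(), render=True
        )
        mask = obs.measured_depth.valid_mask
        res = estimate_depth_correction(
            truth.measured_depth.values[mask][:90], obs.measured_depth.values[mask][:90]
        )
        assert res.scale == pytest.approx(1 / 1.02, abs=1e-6)

    def test_out_of_frustum_flagged_not_dropped(self, noiseless_scene):
        """Observations outside the frustum are flagged missing and keep
        their index slot."""
        vp = noiseless_scene.viewpoints[0]
        narrow = small_config(image_width=40, image_height=30, fx_px=350.0)
        obs = simulate_stereo_observations(
            vp.world_from_sensor(), noiseless_scene.specimen, narrow, render=False
        )
        assert len(obs.blobs_left) == 15
        assert len(obs.missing_blobs) > 0
        for i in obs.missing_blobs:
            assert obs.blobs_left[i] is None and obs.blobs_right[i] is None


class TestBlobImaging:
    def test_single_disk_centroid_accuracy(self):
        img = rasterize_blobs([PixelPoint(100.5, 200.5)], 4.0, 300, 300)
        (c,) = detect_blob_centroids(img)
        assert abs(c.u - 100.5) < 0.1 and abs(c.v - 200.5) < 0.1

    def test_blank_image_detects_nothing(self):
        assert detect_blob_centroids(np.zeros((50, 50))) == []

    def test_fifteen_disks_in_fifteen_centroids_out(self, rng):
        pts = []
        for gy in range(3):
            for gx in range(5):
                pts.append(PixelPoint(40 + 50 * gx + rng.uniform(-3, 3), 40 + 50 * gy + rng.uniform(-3, 3)))
        img = rasterize_blobs(pts, 4.0, 300, 200)
        cents = detect_blob_centroids(img)
        assert len(cents) == 15
        got = np.array([[c.u, c.v] for c in cents])
        want = np.array([[p.u, p.v] for p in pts])
        for w in want:
            assert np.min(np.linalg.norm(got - w, axis=1)) < 0.1

    def test_overlapping_blobs_raise(self):
        with pytest.raises(ValueError, match="overlap"):
            rasterize_blobs([PixelPoint(50, 50), PixelPoint(54, 50)], 4.0, 100, 100)

    def test_out_of_bounds_blob_raises(self):
        with pytest.raises(ValueError, match="bounds"):
            rasterize_blobs([PixelPoint(2, 2)], 4.0, 100, 100)


class TestDeterminism:
    def test_identical_config_and_seed_reproduce_everything(self):
        """Bit-identical streams, observations and depth maps for the same
        configuration and seed."""
        outs = []
        for _ in range(2):
            cfg = SceneConfig(
                seed=7, image_width=160, image_height=90, fx_px=116.0,
                ots_rot_deg_sigma=0.05, ots_trans_mm_sigma=0.05,
                sphere_jitter_mm_sigma=0.02, pixel_sigma_px=0.25,
            )
            scene = build_scene(cfg)
            rng = np.random.default_rng(cfg.seed)
            streams = simulate_ots_stream(scene.specimen, 0.05, cfg, scene.ots_from_world, rng)
            vp = scene.viewpoints[3]
            obs = simulate_stereo_observations(
                vp.world_from_sensor(), scene.specimen, cfg, rng=rng, render=True
            )
            outs.append((streams, obs))
        s1, s2 = outs[0][0], outs[1][0]
        for level in s1:
            for a, b in zip(s1[level].samples, s2[level].samples):
                assert a.timestamp == b.timestamp
                assert np.array_equal(a.transform.matrix, b.transform.matrix)
                assert a.registration_error == b.registration_error
        o1, o2 = outs[0][1], outs[1][1]
        for a, b in zip(o1.blobs_left, o2.blobs_left):
            assert (a is None) == (b is None)
            if a is not None:
                assert a.u == b.u and a.v == b.v
        assert np.array_equal(
            o1.measured_depth.values, o2.measured_depth.values, equal_nan=True
        )
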