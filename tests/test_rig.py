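import numpy as np
import pytest

from markerless.models import center_of_mass
from markerless.multiview import synchronize, triangulate
from markerless.pipeline import reconstruct
from markerless.rig import (RigConfig, FIVE_CAMERA_ANGLES, generate_augmenter_corpus,
                            generate_cohort, generate_motion, make_default_rig,
                            mirror_trial, render_observations, standing_pelvis_height)


class TestRigCameras:
    def test_optical_axes_meet_near_target(self):
        cams = make_default_rig(RigConfig())
        for cam in cams:
            R, t = cam.extrinsics.R, cam.extrinsics.translation
            pos = -R.T @ t
            fwd = R[2]  # camera z axis in world coords
            # distance from the aim point (0, 1, 0) to the optical ray
            v = np.array([0, 1.0, 0]) - pos
            d = np.linalg.norm(v - (v @ fwd) * fwd)
            assert d < 0.01

    def test_five_camera_layout(self):
        cfg = RigConfig(n_cameras=5, camera_angles_deg=FIVE_CAMERA_ANGLES,
                        frame_offsets=(0,) * 5)
        cams = make_default_rig(cfg)
        assert len(cams) == 5
        angles = sorted(np.rad2deg(np.arctan2(-(c.extrinsics.R.T @ c.extrinsics.translation)[2],
                                              (-(c.extrinsics.R.T @ c.extrinsics.translation))[0]))
                        for c in cams)
        np.testing.assert_allclose(angles, sorted(FIVE_CAMERA_ANGLES), atol=1e-6)

    def test_test_cube_visible_in_all_cameras(self):
        from markerless.cameras import project_points

        cams = make_default_rig(RigConfig())
        corners = np.array([[x, y, z] for x in (-1, 1) for y in (0.05, 1.95)
                            for z in (-1, 1)], dtype=float)
        for cam in cams:
            px, valid = project_points(corners, cam.intrinsics, cam.extrinsics)
            assert valid.all()
            w, h = cam.intrinsics.image_size
            assert np.all(px[:, 0] > 0) and np.all(px[:, 0] < w)
            assert np.all(px[:, 1] > 0) and np.all(px[:, 1] < h)


class TestMotionGeneration:
    def test_static_task_constant(self, model2d):
        traj = generate_motion("static", model2d, duration=0.5, seed=0)
        assert np.ptp(traj.q, axis=0).max() == 0.0

    def test_same_seed_identical(self, model3d):
        a = generate_motion("walk", model3d, duration=1.0, seed=9)
        b = generate_motion("walk", model3d, duration=1.0, seed=9)
        np.testing.assert_array_equal(a.q, b.q)

    def test_squat_pelvis_single_minimum(self, model2d):
        traj = generate_motion("squat", model2d, duration=2.0, seed=3)
        y = traj.column("pelvis_ty")
        k = int(np.argmin(y))
        assert 0 < k < len(y) - 1
        # descend then rise, allowing micrometer ripple from the balance pass
        assert np.all(np.diff(y[:k + 1]) <= 1e-4)
        assert np.all(np.diff(y[k:]) >= -1e-4)

    def test_squat_com_stays_over_feet(self, model2d):
        traj = generate_motion("squat", model2d, duration=2.0, seed=3)
        com_x = center_of_mass(model2d, traj.q)[:, 0]
        assert np.ptp(com_x) < 0.02  # balanced throughout

    def test_unknown_task_rejected(self, model2d):
        with pytest.raises(ValueError):
            generate_motion("backflip", model2d)

    def test_bounds_respected(self, model3d):
        for task in ("walk", "squat", "sit_to_stand"):
            traj = generate_motion(task, model3d, duration=1.5, seed=11)
            lo, hi = model3d.bounds.T
            assert np.all(traj.q >= lo - 1e-9) and np.all(traj.q <= hi + 1e-9)


class TestRendering:
    def test_noiseless_closed_loop_triangulation(self, model3d):
        cfg = RigConfig(keypoint_noise_sd=0.0, dropout_rate=0.0,
                        confidence_base=(0.9, 0.95), frame_offsets=(0, 0), seed=5)
        cams = make_default_rig(cfg)
        traj = generate_motion("squat", model3d, duration=1.0, seed=5)
        rendered = render_observations(model3d, traj, cams, cfg)
        kp3d = triangulate(rendered.series, cams)
        assert kp3d.validity.all()
        err = np.linalg.norm(kp3d.positions - rendered.gt_keypoints3d.positions,
                             axis=2)
        assert err.max() < 1e-6

    def test_configured_offset_recovered(self, model3d):
        cfg = RigConfig(keypoint_noise_sd=0.004, dropout_rate=0.0,
                        frame_offsets=(0, 17), seed=6)
        cams = make_default_rig(cfg)
        traj = generate_motion("walk", model3d, duration=3.0, seed=6)
        rendered = render_observations(model3d, traj, cams, cfg)
        _, lags = synchronize(rendered.series, max_lag=40)
        assert lags == [0, 17]

    def test_occlusion_forces_low_confidence(self, model3d):
        cfg = RigConfig(occlusion_rate=3.0, frame_offsets=(0, 0), seed=7)
        cams = make_default_rig(cfg)
        traj = generate_motion("walk", model3d, duration=2.0, seed=7)
        rendered = render_observations(model3d, traj, cams, cfg)
        assert (rendered.series[0].confidence < 0.05).any()

    def test_determinism(self, model2d):
        cfg = RigConfig(seed=8, frame_offsets=(0, 3))
        cams = make_default_rig(cfg)
        traj = generate_motion("squat", model2d, duration=1.0, seed=8)
        r1 = render_observations(model2d, traj, cams, cfg)
        r2 = render_observations(model2d, traj, cams, cfg)
        for a, b in zip(r1.series, r2.series):
            np.testing.assert_array_equal(a.positions, b.positions)
            np.testing.assert_array_equal(a.confidence, b.confidence)


class TestCorpus:
    def test_subject_count_and_split_partition(self, corpus3d):
        subjects = {t.subject_id.rstrip("m") for t in corpus3d}
        assert len(subjects) == 15
        by_subject = {}
        for t in corpus3d:
            by_subject.setdefault(t.subject_id.rstrip("m"), set()).add(t.split)
        for splits in by_subject.values():
            assert len(splits) == 1  # no subject straddles splits
        assert {t.split for t in corpus3d} == {"train", "val", "test"}

    def test_distinct_anthropometry(self, corpus3d):
        hw = {(round(t.height, 6), round(t.mass, 6)) for t in corpus3d}
        assert len(hw) == 15

    def test_regeneration_identical(self):
        a = generate_augmenter_corpus(n_subjects=3, duration=1.0, seed=42)
        b = generate_augmenter_corpus(n_subjects=3, duration=1.0, seed=42)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.keypoints3d, tb.keypoints3d)
            np.testing.assert_array_equal(ta.markers, tb.markers)

    def test_mirroring_swaps_sides(self, corpus3d):
        t = corpus3d[0]
        m = mirror_trial(t)
        ir = t.keypoint_names.index("r_knee")
        il = t.keypoint_names.index("l_knee")
        np.testing.assert_allclose(m.keypoints3d[:, ir, :2], t.keypoints3d[:, il, :2])
        np.testing.assert_allclose(m.keypoints3d[:, ir, 2], -t.keypoints3d[:, il, 2])


class TestCohort:
    def test_paired_structure_and_effect_recording(self):
        cohort = generate_cohort("squat_symmetry", n=4, effect=0.6, seed=2,
                                 duration=1.0)
        assert len(cohort) == 8
        by_subject = {}
        for t in cohort:
            by_subject.setdefault(t.subject_id, []).append(t)
        for trials in by_subject.values():
            assert {t.condition for t in trials} == {"natural", "asymmetric"}
            assert trials[0].height == trials[1].height
            assert trials[0].mass == trials[1].mass

    def test_null_effect_conditions_identical_kinematics(self):
        cohort = generate_cohort("squat_symmetry", n=2, effect=1.0, seed=3,
                                 duration=1.0)
        nat = [t for t in cohort if t.condition == "natural"]
        asym = [t for t in cohort if t.condition == "asymmetric"]
        for a, b in zip(nat, asym):
            np.testing.assert_allclose(a.reference.q, b.reference.q, atol=1e-12)

    def test_asymmetric_condition_flexes_left_knee_more(self):
        cohort = generate_cohort("squat_symmetry", n=1, effect=0.6, seed=4,
                                 duration=1.0)
        nat = next(t for t in cohort if t.condition == "natural")
        asym = next(t for t in cohort if t.condition == "asymmetric")
        assert asym.reference.column("knee_angle_l").min() < \
            nat.reference.column("knee_angle_l").min() - 0.2

    def test_unknown_study_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort("marathon", n=2)
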