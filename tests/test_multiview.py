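import numpy as np
import pytest

from markerless.cameras import CameraExtrinsics, CameraIntrinsics, CameraParameters
from markerless.models import KEYPOINT_CANON
from markerless.multiview import (KeypointSeries2D, SyncError, estimate_lag, fill_gaps,
                                  synchronize, triangulate, triangulate_frame,
                                  velocity_signal)

K = len(KEYPOINT_CANON)


def _series(positions, confidence, rate=60.0, camera_id="cam0"):
    T = positions.shape[0]
    return KeypointSeries2D(camera_id, rate, np.arange(T) / rate, positions, confidence)


def _cubic_series(T=60, rate=60.0):
    t = np.arange(T) / rate
    pos = np.zeros((T, K, 2))
    for k in range(K):
        pos[:, k, 0] = 100 + 3 * k + 40 * t ** 3 - 25 * t ** 2 + 10 * t
        pos[:, k, 1] = 200 + 2 * k + 15 * t ** 3 + 5 * t
    return _series(pos, np.full((T, K), 0.9))


class TestFillGaps:
    def test_identity_without_gaps(self):
        s = _cubic_series()
        out = fill_gaps(s)
        np.testing.assert_array_equal(out.positions, s.positions)
        np.testing.assert_array_equal(out.confidence, s.confidence)

    def test_short_gap_recovers_cubic_exactly(self):
        s = _cubic_series()
        s.confidence[20:23, 4] = 0.1
        truth = s.positions[20:23, 4].copy()
        s.positions[20:23, 4] = -999.0
        out = fill_gaps(s, max_gap=0.5, conf_floor=0.4)
        np.testing.assert_allclose(out.positions[20:23, 4], truth, atol=1e-9)
        expected_conf = 0.5 * (s.confidence[19, 4] + s.confidence[23, 4])
        np.testing.assert_allclose(out.confidence[20:23, 4], expected_conf)

    def test_long_gap_left_untouched(self):
        s = _cubic_series(T=240)
        s.confidence[40:160, 2] = 0.0  # 2 s dropout
        corrupted = s.positions[40:160, 2].copy()
        out = fill_gaps(s, max_gap=0.5, conf_floor=0.4)
        np.testing.assert_array_equal(out.positions[40:160, 2], corrupted)
        assert np.all(out.confidence[40:160, 2] == 0.0)


class TestVelocitySignal:
    def test_static_pose_zero(self):
        pos = np.tile(np.arange(K)[None, :, None] * 5.0, (30, 1, 2))
        s = _series(pos, np.full((30, K), 0.8))
        np.testing.assert_allclose(velocity_signal(s), 0.0, atol=1e-12)

    def test_confidence_weighting_isolates_moving_keypoint(self):
        T = 30
        pos = np.zeros((T, K, 2))
        pos[:, 3, 0] = np.arange(T)  # 1 px/frame = 60 px/s
        conf = np.zeros((T, K))
        conf[:, 3] = 0.7
        s = _series(pos, conf)
        sig = velocity_signal(s)
        np.testing.assert_allclose(sig[1:-1], 60.0, atol=1e-9)

    def test_matches_longhand_weighted_mean(self, rng):
        T = 40
        pos = rng.normal(0, 30, (T, K, 2)).cumsum(axis=0)
        conf = rng.uniform(0.1, 1.0, (T, K))
        s = _series(pos, conf)
        sig = velocity_signal(s)
        t = s.times
        speeds = np.linalg.norm(np.gradient(pos, t, axis=0), axis=2)
        expected = (speeds * conf).sum(axis=1) / conf.sum(axis=1)
        np.testing.assert_allclose(sig, expected, atol=1e-10)

    def test_too_few_frames(self):
        s = _cubic_series(T=2)
        with pytest.raises(SyncError):
            velocity_signal(s)


class TestLag:
    def test_identical_signals_zero_lag(self, rng):
        x = rng.normal(0, 1, 600)
        assert estimate_lag(x, x, max_lag=120) == 0

    @pytest.mark.parametrize("k", [-120, -37, -1, 0, 1, 17, 120])
    def test_recovers_integer_shift(self, k, rng):
        t = np.arange(1200) / 60.0
        base = np.sin(2 * np.pi * 1.1 * t) + 0.5 * np.sin(2 * np.pi * 2.7 * t)
        base = base + rng.normal(0, 0.2, base.shape)  # about SNR 5
        b = np.roll(base, -k)  # b shows later content -> positive lag
        assert estimate_lag(base, b, max_lag=120) == k

    def test_constant_signal_errors(self):
        with pytest.raises(SyncError, match="static"):
            estimate_lag(np.ones(600), np.ones(600), max_lag=120)


class TestSynchronize:
    def _moving_series(self, T=400, shift=0, camera_id="c"):
        t = np.arange(T + 200) / 60.0
        pos = np.zeros((T + 200, K, 2))
        for k in range(K):
            pos[:, k, 0] = 50 * np.sin(2 * np.pi * 0.8 * t + 0.2 * k) + 10 * k
            pos[:, k, 1] = 30 * np.cos(2 * np.pi * 1.3 * t + 0.1 * k)
        sl = pos[shift:shift + T]
        return _series(sl, np.full((T, K), 0.9), camera_id=camera_id)

    def test_two_copies_full_window(self):
        a = self._moving_series()
        aligned, lags = synchronize([a, a.copy()], max_lag=60)
        assert lags == [0, 0]
        assert aligned[0].n_frames == a.n_frames

    def test_known_offset_pair(self):
        a = self._moving_series(shift=0)
        b = self._moving_series(shift=17, camera_id="c2")
        aligned, lags = synchronize([a, b], max_lag=60)
        # camera whose first frame shows later scene content started later
        assert lags[1] == 17
        assert aligned[0].n_frames == a.n_frames - 17
        np.testing.assert_array_equal(aligned[0].times, aligned[1].times)

    def test_three_cameras_mixed_offsets(self):
        base = 30
        series = [self._moving_series(shift=base + s, camera_id=f"c{i}")
                  for i, s in enumerate([0, 5, -8])]
        aligned, lags = synchronize(series, max_lag=60)
        assert lags == [0, 5, -8]
        assert aligned[0].n_frames == series[0].n_frames - 13


def _two_cameras():
    intr = CameraIntrinsics(950.0, 955.0, 360.0, 640.0,
                            np.array([0.05, -0.08, 1e-3, -1e-3, 0.01]), (720, 1280))
    cams = []
    for i, ang in enumerate((-np.pi / 4, np.pi / 4)):
        from scipy.spatial.transform import Rotation

        pos = np.array([3 * np.cos(ang), 1.5, 3 * np.sin(ang)])
        fwd = np.array([0, 1.0, 0]) - pos
        fwd /= np.linalg.norm(fwd)
        right = np.cross(fwd, [0, 1, 0]); right /= np.linalg.norm(right)
        down = np.cross(fwd, right)
        R = np.stack([right, down, fwd])
        cams.append(CameraParameters(
            intr, CameraExtrinsics(Rotation.from_matrix(R).as_rotvec(), -R @ pos),
            f"cam{i}"))
    return cams


class TestTriangulation:
    cams = _two_cameras()

    def _observe(self, pt, rng=None, noise=0.0):
        from markerless.cameras import project_points

        obs = []
        for cam in self.cams:
            px, valid = project_points(pt[None], cam.intrinsics, cam.extrinsics)
            p = px[0]
            if noise and rng is not None:
                p = p + rng.normal(0, noise, 2)
            obs.append((p, 0.9))
        return obs

    def test_noiseless_two_camera_reconstruction(self, rng):
        for _ in range(200):
            pt = rng.uniform([-1, 0, -1], [1, 2, 1])
            xyz, valid = triangulate_frame(self._observe(pt), self.cams)
            assert valid
            np.testing.assert_allclose(xyz, pt, atol=1e-6)

    def test_common_confidence_scaling_invariance(self, rng):
        pt = rng.uniform([-1, 0, -1], [1, 2, 1])
        obs = self._observe(pt, rng, noise=2.0)
        x1, _ = triangulate_frame([(p, c) for p, c in obs], self.cams)
        x2, _ = triangulate_frame([(p, 0.5 * c) for p, c in obs], self.cams)
        np.testing.assert_allclose(x1, x2, atol=1e-9)

    def test_equal_confidence_matches_unweighted_dlt(self, rng):
        """Longhand unweighted homogeneous DLT as the oracle."""
        from markerless.cameras import undistort_points

        pt = rng.uniform([-1, 0, -1], [1, 2, 1])
        obs = self._observe(pt, rng, noise=3.0)
        rows = []
        for (px, _), cam in zip(obs, self.cams):
            xn, _ = undistort_points(px[None], cam.intrinsics)
            P = np.hstack([cam.extrinsics.R, cam.extrinsics.translation[:, None]])
            rows.append(xn[0, 0] * P[2] - P[0])
            rows.append(xn[0, 1] * P[2] - P[1])
        _, _, Vt = np.linalg.svd(np.asarray(rows))
        oracle = Vt[-1][:3] / Vt[-1][3]
        ours, _ = triangulate_frame([(p, 0.7) for p, _ in obs], self.cams)
        np.testing.assert_allclose(ours, oracle, atol=1e-9)

    def test_zero_confidence_camera_excluded(self, rng):
        cams3 = self.cams + [self.cams[0]]
        pt = rng.uniform([-1, 0, -1], [1, 2, 1])
        obs2 = self._observe(pt, rng, noise=2.0)
        obs3 = obs2 + [(obs2[0][0] + 100.0, 0.0)]  # garbage, zero confidence
        x2, _ = triangulate_frame(obs2, self.cams)
        x3, _ = triangulate_frame(obs3, cams3)
        np.testing.assert_allclose(x2, x3, atol=1e-9)

    def test_below_min_confidence_invalid(self):
        pt = np.array([0.0, 1.0, 0.0])
        obs = [(p, 0.1) for p, _ in self._observe(pt)]
        _, valid = triangulate_frame(obs, self.cams)
        assert not valid

    def test_series_triangulation_consistency_and_validity(self, rng):
        from markerless.cameras import project_points

        T = 20
        pts = rng.uniform([-0.5, 0.5, -0.5], [0.5, 1.5, 0.5], (T, K, 3))
        series = []
        for cam in self.cams:
            px, _ = project_points(pts.reshape(-1, 3), cam.intrinsics, cam.extrinsics)
            conf = np.full((T, K), 0.9)
            series.append(_series(px.reshape(T, K, 2), conf,
                                  camera_id=cam.camera_id))
        series[0].confidence[5:9, 2] = 0.0  # occluded in one of two cameras
        kp3d = triangulate(series, self.cams)
        assert not kp3d.validity[5:9, 2].any()
        ok = kp3d.validity
        err = np.linalg.norm(kp3d.positions[ok] - pts[ok], axis=-1)
        assert err.max() < 1e-6
        # frame-wise agreement with triangulate_frame
        obs = [(series[c].positions[3, 7], series[c].confidence[3, 7])
               for c in range(2)]
        single, _ = triangulate_frame(obs, self.cams)
        np.testing.assert_allclose(single, kp3d.positions[3, 7], atol=1e-12)

    def test_unsynchronized_inputs_rejected(self):
        a = _cubic_series(T=10)
        b = _cubic_series(T=12)
        with pytest.raises(SyncError):
            triangulate([a, b], self.cams)

    def test_reprojection_rmse_bounded_by_noise(self, rng):
        """Monte-Carlo: with 1 px observation noise the triangulated points
        reproject within about the injected noise level."""
        from markerless.cameras import project_points

        errs = []
        for _ in range(300):
            pt = rng.uniform([-0.5, 0.5, -0.5], [0.5, 1.5, 0.5])
            obs = self._observe(pt, rng, noise=1.0)
            xyz, valid = triangulate_frame(obs, self.cams)
            assert valid
            for (px_obs, _), cam in zip(obs, self.cams):
                px_hat, _ = project_points(xyz[None], cam.intrinsics, cam.extrinsics)
                errs.append(np.linalg.norm(px_hat[0] - px_obs))
        rmse = np.sqrt(np.mean(np.square(errs)))
        assert rmse <= 1.5  # <= injected noise within Monte-Carlo slack
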