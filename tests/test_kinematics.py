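import numpy as np
import pytest

from markerless.io import MarkerTrajectorySet
from markerless.kinematics import (CoordinateTrajectory, differentiate,
                                   inverse_kinematics, lowpass_filter)
from markerless.models import (ModelError, Segment, Dof, SkeletalModel, demo2d,
                               inverse_dynamics, load_model, mechanical_energy,
                               save_model, scale_model)


def _markers_from(model, q):
    fk = model.forward_kinematics(np.atleast_2d(q))
    pos = fk.marker_positions()
    T = np.atleast_2d(q).shape[0]
    return MarkerTrajectorySet(model.marker_names, np.arange(T) / 60.0, pos)


class TestModelDefinition:
    def test_demo3d_has_21_coordinates(self, model3d):
        assert model3d.nq == 21
        assert len(model3d.marker_names) == 43
        assert len(model3d.keypoint_names) == 20

    def test_cyclic_graph_rejected(self):
        segs = [Segment("a", "b", [0, 0, 0]), Segment("b", "a", [0, 0, 0]),
                Segment("root", None, [0, 0, 0])]
        with pytest.raises(ModelError, match="cycle"):
            SkeletalModel("bad", segs)

    def test_orphan_parent_rejected(self):
        segs = [Segment("root", None, [0, 0, 0]), Segment("a", "ghost", [0, 0, 0])]
        with pytest.raises(ModelError, match="unknown parent"):
            SkeletalModel("bad", segs)

    def test_serialization_roundtrip(self, model2d, rng):
        back = load_model(save_model(model2d))
        assert back.coordinate_names == model2d.coordinate_names
        assert back.marker_names == model2d.marker_names
        q = rng.normal(0, 0.2, model2d.nq)
        q = np.clip(q, model2d.bounds[:, 0], model2d.bounds[:, 1])
        a = model2d.forward_kinematics(q).marker_positions()
        b = back.forward_kinematics(q).marker_positions()
        for name in model2d.marker_names:
            np.testing.assert_allclose(a[name], b[name], atol=1e-12)


class TestScaling:
    def test_identity_scaling(self, model3d):
        neutral = _markers_from(model3d, np.tile(model3d.default_pose(), (5, 1)))
        scaled, factors = scale_model(model3d, neutral, height=1.75,
                                      mass=model3d.total_mass)
        for name, f in factors.items():
            assert f == pytest.approx(1.0, abs=1e-6)

    def test_detects_longer_thigh(self, model3d):
        donor = model3d.copy()
        for s in donor.segments:
            if s.name.startswith("thigh"):
                s.markers = {k: v * 1.1 for k, v in s.markers.items()}
            if s.name.startswith("shank"):
                s.origin = s.origin * 1.1
        neutral = _markers_from(donor, donor.default_pose())
        _, factors = scale_model(model3d, neutral, 1.80, 80.0)
        assert factors["thigh_r"] == pytest.approx(1.1, abs=0.01)
        assert factors["thigh_l"] == pytest.approx(1.1, abs=0.01)
        assert factors["pelvis"] == pytest.approx(1.0, abs=0.01)

    def test_mass_conservation(self, model3d):
        neutral = _markers_from(model3d, model3d.default_pose())
        scaled, _ = scale_model(model3d, neutral, 1.80, 80.0)
        assert scaled.total_mass == pytest.approx(80.0, abs=1e-9)

    def test_scaling_idempotent(self, model3d):
        neutral = _markers_from(model3d, model3d.default_pose())
        scaled, _ = scale_model(model3d, neutral, 1.85, 85.0)
        re_neutral = _markers_from(scaled, scaled.default_pose())
        _, factors2 = scale_model(scaled, re_neutral, 1.85, 85.0)
        for f in factors2.values():
            assert f == pytest.approx(1.0, abs=1e-9)

    def test_missing_markers_listed(self, model3d):
        neutral = _markers_from(model3d, model3d.default_pose())
        del neutral.positions["r_asis"]
        neutral.marker_names.remove("r_asis")
        with pytest.raises(ModelError, match="r_asis"):
            scale_model(model3d, neutral, 1.75, 75.0)


class TestForwardKinematics:
    def test_planar_two_link_closed_form(self):
        l1, l2 = 0.4, 0.3
        segs = [
            Segment("link1", None, [0, 0, 0],
                    dofs=[Dof("q1", "rotation", [0, 0, 1], (-7, 7))]),
            Segment("link2", "link1", [0, -l1, 0],
                    dofs=[Dof("q2", "rotation", [0, 0, 1], (-7, 7))],
                    markers={"tip": np.array([0.0, -l2, 0.0])}),
        ]
        m = SkeletalModel("2link", segs)
        fk = m.forward_kinematics(np.array([np.pi / 2, 0.0]))
        # rotating +90 deg about z sends (0,-l,0) to (l,0,0)
        np.testing.assert_allclose(fk.point("link2", [0, -l2, 0]),
                                   [l1 + l2, 0, 0], atol=1e-12)

    def test_rigidity_of_intra_segment_distances(self, model3d, rng):
        lo, hi = model3d.bounds.T
        d_ref = None
        for _ in range(10):
            q = rng.uniform(lo, hi)
            fk = model3d.forward_kinematics(q)
            pos = fk.marker_positions()
            d = np.linalg.norm(pos["r_knee_lat"] - pos["r_thigh_cluster1"])
            if d_ref is None:
                d_ref = d
            assert d == pytest.approx(d_ref, abs=1e-12)


class TestInverseKinematics:
    def test_roundtrip_identity_default_pose(self, model2d):
        markers = _markers_from(model2d, model2d.default_pose())
        traj, rmse = inverse_kinematics(model2d, markers)
        np.testing.assert_allclose(traj.q[0], model2d.default_pose(), atol=1e-6)
        assert rmse[0] < 1e-9

    @pytest.mark.parametrize("fixture", ["model2d", "model3d"])
    def test_roundtrip_random_poses(self, fixture, request, rng):
        model = request.getfixturevalue(fixture)
        lo, hi = model.bounds.T
        rot = np.array([d.kind == "rotation" for d in model.coordinates])
        for _ in range(10):
            q_true = model.default_pose() + rng.uniform(-0.25, 0.25, model.nq)
            q_true = np.clip(q_true, lo, hi)
            markers = _markers_from(model, q_true)
            traj, _ = inverse_kinematics(model, markers, q0=model.default_pose())
            err = np.abs(traj.q[0] - q_true)
            assert err[rot].max() < np.deg2rad(0.1)
            assert err[~rot].max() < 5e-4

    def test_noisy_markers_small_angle_error(self, model3d, rng):
        from markerless.rig import generate_motion

        traj_true = generate_motion("walk", model3d, duration=1.0, seed=4)
        fk = model3d.forward_kinematics(traj_true.q)
        pos = {k: v + rng.normal(0, 0.018, v.shape)
               for k, v in fk.marker_positions().items()}
        markers = MarkerTrajectorySet(model3d.marker_names, traj_true.times, pos)
        traj, _ = inverse_kinematics(model3d, markers, q0=traj_true.q[0])
        traj = lowpass_filter(traj, 6.0)  # standard gait processing
        rot = np.array([d.kind == "rotation" for d in model3d.coordinates])
        mae = np.abs(traj.q - traj_true.q)[:, rot].mean()
        assert np.rad2deg(mae) < 2.0


class TestFiltering:
    def test_zero_lag_and_passband(self):
        fs = 100.0
        t = np.arange(0, 4, 1 / fs)
        x = np.sin(2 * np.pi * 2.0 * t)
        traj = CoordinateTrajectory(["a"], t, x[:, None])
        y = lowpass_filter(traj, 12.0).q[:, 0]
        xc = np.correlate(x - x.mean(), y - y.mean(), mode="full")
        assert abs(np.argmax(xc) - (len(x) - 1)) < 1  # peak at zero lag
        assert np.ptp(y[50:-50]) == pytest.approx(np.ptp(x[50:-50]), rel=0.01)

    def test_minus_six_db_at_cutoff(self):
        """Two passes of a 4th-order Butterworth give |H|^2 = 1/2 at cutoff."""
        fs, fc = 1000.0, 12.0
        t = np.arange(0, 30, 1 / fs)
        x = np.sin(2 * np.pi * fc * t)
        y = lowpass_filter((x, fs), fc)
        ratio = np.ptp(y[5000:-5000]) / np.ptp(x[5000:-5000])
        assert ratio == pytest.approx(0.5, abs=0.01)

    def test_dc_preserved(self):
        fs = 60.0
        traj = CoordinateTrajectory(["a"], np.arange(60) / fs, np.full((60, 1), 3.7))
        np.testing.assert_allclose(lowpass_filter(traj, 10.0).q, 3.7, atol=1e-9)

    def test_cutoff_above_nyquist_rejected(self):
        traj = CoordinateTrajectory(["a"], np.arange(60) / 60.0, np.zeros((60, 1)))
        with pytest.raises(ValueError, match="Nyquist"):
            lowpass_filter(traj, 40.0)


class TestDifferentiate:
    def test_linear_ramp(self):
        t = np.arange(100) / 100.0
        traj = differentiate(CoordinateTrajectory(["a"], t, (2.5 * t)[:, None]))
        np.testing.assert_allclose(traj.qd, 2.5, atol=1e-9)
        np.testing.assert_allclose(traj.qdd, 0.0, atol=1e-6)

    def test_sinusoid_amplitude(self):
        fs, f = 200.0, 2.0
        t = np.arange(0, 3, 1 / fs)
        traj = differentiate(CoordinateTrajectory(["a"], t,
                                                  np.sin(2 * np.pi * f * t)[:, None]))
        amp = np.abs(traj.qd[20:-20]).max()
        assert amp == pytest.approx(2 * np.pi * f, rel=1e-3)

    def test_too_short(self):
        traj = CoordinateTrajectory(["a"], np.arange(3) / 60.0, np.zeros((3, 1)))
        with pytest.raises(ValueError):
            differentiate(traj)


class TestInverseDynamics:
    def _pendulum(self):
        seg = Segment("rod", None, [0, 0, 0],
                      dofs=[Dof("theta", "rotation", [0, 0, 1], (-10, 10))],
                      mass=2.0, com=[0, -0.5, 0], inertia=[2.0 / 12] * 3)
        return SkeletalModel("pend", [seg])

    def test_pendulum_closed_form(self):
        pend = self._pendulum()
        w = 2 * np.pi * 1.3
        t = np.linspace(0, 2, 200)
        q = (0.5 * np.sin(w * t))[:, None]
        qd = (0.5 * w * np.cos(w * t))[:, None]
        qdd = (-0.5 * w ** 2 * np.sin(w * t))[:, None]
        tau = inverse_dynamics(pend, q, qd, qdd)
        I_o = 2.0 / 12 + 2.0 * 0.25  # parallel axis
        tau_cf = I_o * qdd[:, 0] + 2.0 * 9.81 * 0.5 * np.sin(q[:, 0])
        np.testing.assert_allclose(tau[:, 0], tau_cf, atol=1e-12)

    def test_zero_motion_zero_gravity_zero_forces(self, model2d):
        q = np.zeros((3, model2d.nq))
        tau = inverse_dynamics(model2d, q, np.zeros_like(q), np.zeros_like(q),
                               gravity=np.zeros(3))
        np.testing.assert_allclose(tau, 0.0, atol=1e-12)

    def test_energy_consistency_passive_swing(self):
        """Sum(tau * qd) equals d/dt(KE + PE) on any trajectory."""
        pend = self._pendulum()
        dt = 1e-4
        t = np.arange(0, 1, dt)
        w = 2 * np.pi * 0.9
        q = (0.7 * np.sin(w * t))[:, None]
        qd = (0.7 * w * np.cos(w * t))[:, None]
        qdd = (-0.7 * w ** 2 * np.sin(w * t))[:, None]
        tau = inverse_dynamics(pend, q, qd, qdd)
        ke, pe = mechanical_energy(pend, q, qd)
        power = tau[:, 0] * qd[:, 0]
        # integral form: E(t1) - E(t0) = int power dt (trapezoid)
        lhs = (ke + pe)[-1] - (ke + pe)[0]
        rhs = np.trapezoid(power, t)
        assert lhs == pytest.approx(rhs, abs=1e-6)

    def test_external_force_lever_arm_oracle(self, model2d):
        """Without gravity or motion, the joint moment from a vertical force
        under the foot equals the closed-form lever arm about each z joint."""
        from markerless.rig import standing_pelvis_height

        F = 300.0
        q = np.zeros((1, model2d.nq))
        q[0, model2d.coordinate_index("pelvis_ty")] = standing_pelvis_height(model2d)
        fk = model2d.forward_kinematics(q)
        cop_local = np.array([0.05, -0.077, 0.0])
        ext = [("foot_r", cop_local, np.array([[0, F, 0]]))]
        tau = inverse_dynamics(model2d, q, np.zeros_like(q), np.zeros_like(q), ext,
                               gravity=np.zeros(3))
        cop = np.atleast_2d(fk.point("foot_r", cop_local))[0]
        for joint, seg in (("ankle_angle_r", "foot_r"), ("knee_angle_r", "shank_r"),
                           ("hip_flexion_r", "thigh_r")):
            origin = np.atleast_2d(fk.point(seg, np.zeros(3)))[0]
            expected = -F * (cop[0] - origin[0])
            assert tau[0, model2d.coordinate_index(joint)] == pytest.approx(
                expected, rel=1e-9), joint
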