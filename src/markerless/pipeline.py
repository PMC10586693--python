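"""End-to-end processing: from per-camera 2D keypoints to dynamics and
cohort-level statistics.

``reconstruct`` covers the vision half (gap filling, synchronization,
triangulation); ``estimate_kinematics`` the augmentation + inverse
kinematics half; ``run_symmetry_cohort`` executes the full chain on a
synthetic squat cohort and classifies natural vs asymmetric squats from the
knee-extension-moment symmetry index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .analysis import ClassificationReport, SymmetryMeasurement, roc_analysis, symmetry_index
from .augment import TrainedAugmenter, augment
from .dynamics import TrackingSettings, TrackingSolution, TrackingWeights, solve_tracking
from .io import MarkerTrajectorySet
from .kinematics import CoordinateTrajectory, differentiate, inverse_kinematics, lowpass_filter
from .models import SkeletalModel
from .multiview import (KeypointSeries2D, KeypointSeries3D, fill_gaps, synchronize,
                        triangulate)


def reconstruct(series_list: list[KeypointSeries2D], cameras, max_lag: int = 240,
                conf_floor: float = 0.4, max_gap: float = 0.5,
                min_confidence: float = 0.3
                ) -> tuple[KeypointSeries3D, list[int]]:
    """Gap-fill, synchronize, and triangulate multi-camera 2D keypoints."""
    filled = [fill_gaps(s, max_gap=max_gap, conf_floor=conf_floor) for s in series_list]
    aligned, lags = synchronize(filled, max_lag=max_lag)
    kp3d = triangulate(aligned, cameras, min_confidence=min_confidence)
    # bridge residual invalid samples (e.g. boundary dropouts) by interpolation
    # so downstream stages see complete trajectories; validity flags remain
    for k in range(kp3d.positions.shape[1]):
        ok = kp3d.validity[:, k]
        if ok.all() or not ok.any():
            continue
        for ax in range(3):
            kp3d.positions[~ok, k, ax] = np.interp(
                kp3d.times[~ok], kp3d.times[ok], kp3d.positions[ok, k, ax])
    return kp3d, lags


def estimate_kinematics(kp3d: KeypointSeries3D, height: float, mass: float,
                        augmenter: TrainedAugmenter, model: SkeletalModel,
                        cutoff: float = 6.0
                        ) -> tuple[CoordinateTrajectory, MarkerTrajectorySet, np.ndarray]:
    """Augment keypoints to anatomical markers and run inverse kinematics.

    Returns (filtered+differentiated coordinates, predicted markers,
    per-frame IK marker RMSE).
    """
    markers = augment(kp3d.positions, height, mass, augmenter, times=kp3d.times)
    traj, rmse = inverse_kinematics(model, markers)
    traj = differentiate(lowpass_filter(traj, cutoff))
    return traj, markers, rmse


def align_to_ground(model: SkeletalModel, traj: CoordinateTrajectory,
                    load_fraction: float = 0.5) -> CoordinateTrajectory:
    """Shift a reference trajectory vertically so the feet load the ground.

    Video-estimated kinematics carry centimeter-level absolute-position
    error; left unaligned, the contact spheres either float (no support for
    the pelvis equations) or dig in (huge forces).  The whole trajectory is
    shifted so the lowest contact-sphere height over the trial sits at the
    penetration that statically carries ``load_fraction`` of bodyweight per
    sphere pair.
    """
    from .contact import equilibrium_penetration

    out = traj.copy()
    fk = model.forward_kinematics(traj.q)
    lows = []
    for sphere in model.contact_spheres:
        p = fk.point(sphere.segment, sphere.position)
        lows.append(np.atleast_2d(p)[:, 1] - sphere.radius)
    low = np.min(np.stack(lows), axis=0)  # most penetrating sphere per frame
    W = model.total_mass * 9.81
    target = -equilibrium_penetration(model.contact_spheres[0],
                                      load_fraction * W / 2)
    ity = out.coordinate_names.index("pelvis_ty")
    out.q[:, ity] += target - np.quantile(low, 0.1)
    return out


def constrain_feet_to_ground(model: SkeletalModel, traj: CoordinateTrajectory,
                             cutoff: float = 4.0) -> CoordinateTrajectory:
    """Stop the feet from digging into the floor in an estimated trajectory.

    For each leg, frames where the lowest contact sphere sinks below the
    static-equilibrium penetration get a smooth knee-flexion correction that
    lifts the foot back to the surface.  Floating feet are left untouched, so
    genuine unloading (e.g. an asymmetric squat) survives the projection.
    """
    from .contact import equilibrium_penetration
    from scipy.signal import butter, sosfiltfilt

    out = traj.copy()
    W = model.total_mass * 9.81
    delta = equilibrium_penetration(model.contact_spheres[0], W / 2)
    fs = 1.0 / traj.dt
    sos = butter(2, min(cutoff, 0.45 * fs), fs=fs, output="sos")
    for side in ("r", "l"):
        ik = out.coordinate_names.index(f"knee_angle_{side}")
        spheres = [s for s in model.contact_spheres if s.segment == f"foot_{side}"]
        for _ in range(2):
            fk = model.forward_kinematics(out.q)
            h = np.min([np.atleast_2d(fk.point(s.segment, s.position))[:, 1] - s.radius
                        for s in spheres], axis=0)
            excess = np.minimum(h + delta, 0.0)  # negative where digging
            if np.all(excess > -1e-4):
                break
            qp = out.q.copy()
            qp[:, ik] -= 1e-4  # more flexion shortens the leg
            fkp = model.forward_kinematics(qp)
            hp = np.min([np.atleast_2d(fkp.point(s.segment, s.position))[:, 1] - s.radius
                         for s in spheres], axis=0)
            dh = (hp - h) / -1e-4
            dh = np.where(np.abs(dh) < 1e-3, np.sign(dh + 1e-12) * 1e-3, dh)
            corr = sosfiltfilt(sos, -excess / dh)
            out.q[:, ik] += np.minimum(corr, 0.0)
    lo, hi = model.bounds.T
    out.q = np.clip(out.q, lo, hi)
    return out


def anchor_feet_horizontal(model: SkeletalModel, traj: CoordinateTrajectory
                           ) -> CoordinateTrajectory:
    """Remove common-mode horizontal foot travel from an estimated squat-like
    trajectory.  Millimeter-scale foot sliding in video-estimated kinematics
    drives the regularized friction model to full saturation and poisons the
    force balance; the pelvis x-translation is corrected so the mean contact
    point stays put."""
    out = traj.copy()
    itx = out.coordinate_names.index("pelvis_tx")
    fk = model.forward_kinematics(out.q)
    foot_x = np.mean([np.atleast_2d(fk.point(s.segment, s.position))[:, 0]
                      for s in model.contact_spheres], axis=0)
    out.q[:, itx] += np.median(foot_x) - foot_x
    return out


def match_vertical_load(model: SkeletalModel, traj: CoordinateTrajectory,
                        cutoff: float = 4.0) -> CoordinateTrajectory:
    """Per-frame vertical registration of an estimated trajectory.

    Centimeter-level vertical error in video-based kinematics makes the
    compliant contact model imply wildly wrong ground reaction forces.  This
    solves, frame by frame, for the pelvis-height offset at which the total
    vertical contact force equals m * (g + a_com_y) implied by the
    trajectory itself, smooths the offset, and applies it.
    """
    from scipy.signal import butter, sosfiltfilt

    from .contact import contact_force
    from .models import center_of_mass

    out = traj.copy()
    fs = 1.0 / traj.dt
    sos = butter(2, min(cutoff, 0.45 * fs), fs=fs, output="sos")
    com_y = center_of_mass(model, traj.q)[:, 1]
    a_com = np.gradient(np.gradient(sosfiltfilt(sos, com_y), traj.times), traj.times)
    W = model.total_mass
    target = np.clip(W * (9.81 + a_com), 0.2 * W * 9.81, 2.5 * W * 9.81)
    ity = out.coordinate_names.index("pelvis_ty")

    def total_fy(q):
        fk = model.forward_kinematics(q)
        fy = np.zeros(q.shape[0])
        zero_v = np.zeros((q.shape[0], 3))
        for s in model.contact_spheres:
            p = np.atleast_2d(fk.point(s.segment, s.position))
            fy += contact_force(p, zero_v, s)[:, 1]
        return fy

    offset = np.zeros(len(out.times))
    q = out.q.copy()
    for _ in range(8):  # damped Newton, vectorized over frames
        f = total_fy(q)
        qp = q.copy()
        qp[:, ity] -= 1e-5
        df = (total_fy(qp) - f) / -1e-5  # dF/d(pelvis_ty), negative
        df = np.minimum(df, -1.0)
        step = np.clip((target - f) / df, -0.01, 0.01)
        offset += step
        q[:, ity] = out.q[:, ity] + offset
    out.q[:, ity] += sosfiltfilt(sos, offset)
    return out


@dataclass
class SymmetryTrialResult:
    subject_id: str
    condition: str
    peak_left: float
    peak_right: float
    symmetry: float
    solution: TrackingSolution | None


@dataclass
class CohortReport:
    trials: list[SymmetryTrialResult]
    classification: ClassificationReport


def knee_moment_symmetry(solution: TrackingSolution,
                         trim_fraction: float = 0.15) -> SymmetryTrialResult:
    """Peak knee-extension-moment symmetry of one squat solution.

    The knee coordinate counts flexion negative, so the extension moment is
    the positive moment about the knee.  Peaks are taken over the interior of
    the trial (the first and last ``trim_fraction`` are dropped, where filter
    edge effects and the initial transient of the tracking solution live).
    The left leg is the involved side.
    """
    names = solution.coordinate_names
    n = len(solution.times)
    lo, hi = int(trim_fraction * n), n - int(trim_fraction * n)
    # anchor the window to the movement itself: frames where either knee is
    # flexed beyond 30% of its excursion (the squat proper, away from the
    # quiet-standing boundaries where solver/filter transients live)
    flex = -np.minimum(solution.q[:, names.index("knee_angle_l")],
                       solution.q[:, names.index("knee_angle_r")])
    inside = np.flatnonzero(flex > 0.5 * flex.max())
    lo = max(lo, int(inside[0])) if len(inside) else lo
    hi = min(hi, int(inside[-1]) + 1) if len(inside) else hi
    mom = solution.joint_moments[lo:hi]
    pk_l = float(np.max(mom[:, names.index("knee_angle_l")]))
    pk_r = float(np.max(mom[:, names.index("knee_angle_r")]))
    sym = symmetry_index(SymmetryMeasurement(pk_l, pk_r))
    return SymmetryTrialResult("", "", pk_l, pk_r, sym, solution)


def run_symmetry_cohort(cohort, augmenter: TrainedAugmenter | None = None,
                        rig_config=None, seed: int = 0,
                        mesh_hz: float = 15.0, through_video: bool = True,
                        cutoff: float = 4.0) -> CohortReport:
    """Full squat-symmetry analysis of a rig-generated cohort.

    For each trial: render two-camera observations, synchronize,
    triangulate, augment to markers, inverse kinematics, torque-driven
    tracking simulation, then extract the knee-extension-moment symmetry
    index.  With ``through_video=False`` the vision stages are skipped and
    the generated reference feeds the simulation directly (fast screening
    variant).  Classification: symmetry index vs the instructed condition.
    """
    from .rig import RigConfig, make_default_rig, render_observations

    rng = np.random.default_rng(seed)
    results = []
    for trial in cohort:
        if through_video:
            cfg = rig_config or RigConfig()
            cfg = RigConfig(
                n_cameras=cfg.n_cameras, camera_angles_deg=cfg.camera_angles_deg,
                frame_rate=cfg.frame_rate, keypoint_noise_sd=cfg.keypoint_noise_sd,
                dropout_rate=cfg.dropout_rate, occlusion_rate=cfg.occlusion_rate,
                frame_offsets=tuple(int(o) for o in rng.integers(0, 12, cfg.n_cameras)),
                seed=int(rng.integers(2 ** 31)))
            cams = make_default_rig(cfg)
            rendered = render_observations(trial.model, trial.reference, cams, cfg)
            kp3d, _ = reconstruct(rendered.series, cams, max_lag=30)
            if augmenter is None:
                raise ValueError("through_video=True requires a trained augmenter")
            traj, _, _ = estimate_kinematics(kp3d, trial.height, trial.mass,
                                             augmenter, trial.model, cutoff=cutoff)
            traj = align_to_ground(trial.model, traj)
            traj = constrain_feet_to_ground(trial.model, traj, cutoff=cutoff)
            traj = anchor_feet_horizontal(trial.model, traj)
            traj = match_vertical_load(trial.model, traj, cutoff=cutoff)
            # drop the boundary frames where zero-lag filtering and one-sided
            # differentiation of the estimated kinematics are unreliable
            margin = int(round(0.25 / traj.dt))
            traj = CoordinateTrajectory(traj.coordinate_names,
                                        traj.times[margin:-margin],
                                        traj.q[margin:-margin])
            traj = differentiate(traj)
            # video-derived references carry cm-scale absolute error: track
            # them more loosely so the solver can restore consistency
            weights = TrackingWeights(w3=150.0, w4=5.0)
        else:
            traj = differentiate(lowpass_filter(trial.reference, cutoff))
            weights = TrackingWeights()
        sol = solve_tracking(trial.model, traj, weights,
                             TrackingSettings(mesh_hz=mesh_hz, actuation="torque",
                                              max_nfev=100))
        res = knee_moment_symmetry(sol)
        res.subject_id = trial.subject_id
        res.condition = trial.condition
        results.append(res)
    scores = np.array([r.symmetry for r in results])
    labels = np.array([r.condition == "asymmetric" for r in results])
    report = roc_analysis(scores, labels)
    return CohortReport(results, report)
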