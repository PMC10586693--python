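"""Synthetic acquisition rig: ground truth for every pipeline stage.

Emulates a two-(or more-)smartphone capture setup: cameras 1.5 m off the
ground, 3 m from the capture volume at +/-45 deg, 60 Hz, 720x1280 px;
articulated motions on the fixture models; 3D keypoint noise (default SD
18 mm) injected before projection; per-camera integer frame offsets,
confidence dropouts, and occlusion intervals.  Everything is a pure function
of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cameras import CameraExtrinsics, CameraIntrinsics, CameraParameters, project_points
from .io import MarkerTrajectorySet
from .kinematics import CoordinateTrajectory
from .models import KEYPOINT_CANON, SkeletalModel, demo2d, demo3d
from .multiview import KeypointSeries2D, KeypointSeries3D

def standing_pelvis_height(model: SkeletalModel) -> float:
    """Pelvis height at which the straight-leg standing pose statically loads
    the contact spheres with about half bodyweight per foot."""
    from .contact import equilibrium_penetration

    q0 = np.zeros(model.nq)
    fk = model.forward_kinematics(q0)
    low = min(float(np.atleast_2d(fk.point(s.segment, s.position))[0, 1]) - s.radius
              for s in model.contact_spheres)
    delta = equilibrium_penetration(model.contact_spheres[0],
                                    model.total_mass * 9.81 / 4)
    return -low - delta


@dataclass
class RigConfig:
    n_cameras: int = 2
    camera_angles_deg: tuple = (-45.0, 45.0)  # about the vertical, 0 = facing subject
    camera_height: float = 1.5  # m
    camera_distance: float = 3.0  # m
    frame_rate: float = 60.0  # Hz
    image_size: tuple[int, int] = (720, 1280)  # (width, height) px
    keypoint_noise_sd: float = 0.018  # m, 3D, per coordinate
    confidence_base: tuple[float, float] = (0.65, 0.98)  # uniform range
    dropout_rate: float = 0.01  # per frame per keypoint
    occlusion_rate: float = 0.0  # expected occlusion intervals per keypoint per trial
    occlusion_duration: float = 0.4  # s, mean (exponential)
    frame_offsets: tuple = (0, 0)  # integer frames, per camera
    seed: int = 0

    def __post_init__(self):
        if self.n_cameras < 2:
            raise ValueError("need at least 2 cameras")
        if self.keypoint_noise_sd < 0:
            raise ValueError("noise SD must be >= 0")
        if any(int(o) != o for o in self.frame_offsets):
            raise ValueError("frame offsets must be integers")


FIVE_CAMERA_ANGLES = (-70.0, -45.0, 0.0, 45.0, 70.0)


def make_default_rig(config: RigConfig) -> list[CameraParameters]:
    """Cameras on a circle at the configured distance and height, aimed at
    the capture-volume origin, with smartphone-like intrinsics."""
    angles = config.camera_angles_deg
    if len(angles) != config.n_cameras:
        raise ValueError("one angle per camera required")
    target = np.array([0.0, 1.0, 0.0])  # roughly hip height of the subject
    w, h = config.image_size
    cams = []
    for i, ang in enumerate(angles):
        a = np.deg2rad(ang)
        # subject faces +x; a camera at 0 deg sits in front (+x), others swing
        # about the vertical y axis
        pos = np.array([config.camera_distance * np.cos(a),
                        config.camera_height,
                        config.camera_distance * np.sin(a)])
        fwd = target - pos
        fwd = fwd / np.linalg.norm(fwd)
        right = np.cross(fwd, np.array([0.0, 1.0, 0.0]))
        right /= np.linalg.norm(right)
        down = np.cross(fwd, right)
        R = np.stack([right, down, fwd])  # world -> camera rows
        t = -R @ pos
        from scipy.spatial.transform import Rotation
        rv = Rotation.from_matrix(R).as_rotvec()
        intr = CameraIntrinsics(fx=700.0, fy=700.0, cx=w / 2 + 3.0, cy=h / 2 - 4.0,
                                distortion=np.array([0.06, -0.12, 1e-3, -8e-4, 0.03]),
                                image_size=(w, h))
        cams.append(CameraParameters(intr, CameraExtrinsics(rv, t), f"cam{i}"))
    return cams


# ---------------------------------------------------------------------------
# Motion generation
# ---------------------------------------------------------------------------

def _bell(t: np.ndarray, t_total: float) -> np.ndarray:
    """Single smooth rise-and-return profile in [0, 1]."""
    return 0.5 * (1 - np.cos(2 * np.pi * t / t_total))


def _leg_closure(model: SkeletalModel, q: np.ndarray) -> np.ndarray:
    """Set pelvis translation so the right ankle stays at its standing spot,
    and pelvis_ty keeps the standing load on the feet."""
    names = model.coordinate_names
    itx, ity = names.index("pelvis_tx"), names.index("pelvis_ty")
    q0 = np.zeros(model.nq)
    q0[ity] = standing_pelvis_height(model)
    anchor = model.forward_kinematics(q0).point("foot_r", np.zeros(3))
    q_work = q.copy()
    q_work[:, itx] = 0.0
    q_work[:, ity] = 0.0
    ankle = model.forward_kinematics(q_work).point("foot_r", np.zeros(3))
    ankle = np.atleast_2d(ankle)
    q_out = q.copy()
    q_out[:, itx] = anchor[0] - ankle[:, 0]
    q_out[:, ity] = anchor[1] - ankle[:, 1]
    if "pelvis_tz" in names:
        itz = names.index("pelvis_tz")
        q_out[:, itz] = anchor[2] - ankle[:, 2]
    return q_out


def _balance_com(model: SkeletalModel, q: np.ndarray, iters: int = 4) -> np.ndarray:
    """Adjust hip flexion (and keep feet flat and anchored) so the whole-body
    center of mass stays over the middle of the feet at every frame; without
    this a squat reference demands torques no actuator set can supply."""
    from .models import center_of_mass

    names = model.coordinate_names
    ih = [names.index("hip_flexion_r"), names.index("hip_flexion_l")]
    ia = [names.index("ankle_angle_r"), names.index("ankle_angle_l")]
    it_ = names.index("pelvis_tilt")
    ik = [names.index("knee_angle_r"), names.index("knee_angle_l")]
    q0 = np.zeros(model.nq)
    q0[names.index("pelvis_ty")] = standing_pelvis_height(model)
    foot_mid = model.forward_kinematics(q0).point("foot_r", np.array([0.06, 0.0, 0.0]))[0]

    def closed(qc):
        qc = qc.copy()
        for side in (0, 1):  # feet flat: ankle closes the sagittal chain
            qc[:, ia[side]] = -(qc[:, it_] + qc[:, ih[side]] + qc[:, ik[side]])
        return _leg_closure(model, qc)

    q = closed(q)
    eps = 1e-4
    for _ in range(iters):
        err = center_of_mass(model, q)[:, 0] - foot_mid
        qp = q.copy()
        qp[:, ih] += eps
        dq = (center_of_mass(model, closed(qp))[:, 0] - foot_mid - err) / eps
        dq = np.where(np.abs(dq) < 1e-6, 1e-6, dq)
        q[:, ih] -= (err / dq)[:, None]
        q = closed(q)
    return q


def generate_motion(task: str, model: SkeletalModel, duration: float = 2.0,
                    frame_rate: float = 60.0, seed: int = 0,
                    amplitude: float = 1.0, left_knee_offset: float = 0.0,
                    forward_speed: float | None = None
                    ) -> CoordinateTrajectory:
    """Smooth, bounded joint trajectories for one trial of a task.

    Tasks: ``static`` (standing), ``walk`` (periodic gait-like pattern with
    forward progression), ``squat`` and ``sit_to_stand`` (bell-profiled knee/
    hip flexion with the feet kept anchored and flat).  ``amplitude`` scales
    joint excursions; ``left_knee_offset`` adds extra left-knee flexion at
    the movement bottom (used to impose load asymmetries).  Subject-to-subject
    variation comes from ``seed``.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / frame_rate)
    names = model.coordinate_names
    q = np.zeros((len(t), model.nq))

    def col(name):
        return names.index(name)

    jit = lambda lo, hi: rng.uniform(lo, hi)
    if task == "static":
        q[:, col("pelvis_ty")] = standing_pelvis_height(model)
    elif task == "walk":
        f = 0.9 * jit(0.9, 1.1)  # stride frequency, Hz
        hip_amp = amplitude * np.deg2rad(25 * jit(0.85, 1.15))
        knee_amp = amplitude * np.deg2rad(50 * jit(0.85, 1.15))
        ankle_amp = amplitude * np.deg2rad(12 * jit(0.8, 1.2))
        # slow walk keeps the subject inside the two-camera capture volume;
        # forward_speed=0 gives a treadmill-style trial for long captures
        speed = (forward_speed if forward_speed is not None
                 else 0.5 * amplitude * jit(0.85, 1.15))
        ph = 2 * np.pi * f * t
        # slow, incommensurate amplitude modulation: stride-to-stride
        # variation that also makes the velocity signal aperiodic, which is
        # what cross-correlation synchronization relies on
        mod = (1.0 + 0.14 * np.sin(2 * np.pi * 0.21 * jit(0.8, 1.2) * t + jit(0, 6.3))
               + 0.10 * np.sin(2 * np.pi * 0.383 * jit(0.8, 1.2) * t + jit(0, 6.3)))
        for side, phase in (("r", 0.0), ("l", np.pi)):
            q[:, col(f"hip_flexion_{side}")] = hip_amp * mod * np.sin(ph + phase)
            q[:, col(f"knee_angle_{side}")] = -knee_amp * mod * 0.5 * (1 - np.cos(ph + phase - 0.6))
            q[:, col(f"ankle_angle_{side}")] = ankle_amp * np.sin(ph + phase + 1.2)
            if f"hip_adduction_{side}" in names:
                q[:, col(f"hip_adduction_{side}")] = np.deg2rad(4) * np.sin(ph + phase + 0.3)
        q[:, col("pelvis_tx")] = speed * (t - t[-1] / 2)  # centered traverse
        q[:, col("pelvis_ty")] = (standing_pelvis_height(model)
                                  - 0.012 + 0.012 * np.cos(2 * ph))
        q[:, col("pelvis_tilt")] = np.deg2rad(3) * np.sin(ph)
        if "pelvis_list" in names:
            q[:, col("pelvis_list")] = np.deg2rad(3) * np.sin(ph)
            q[:, col("pelvis_rotation")] = np.deg2rad(6) * np.sin(ph)
            q[:, col("lumbar_extension")] = np.deg2rad(4) * np.sin(ph + 0.5)
            q[:, col("lumbar_bending")] = -np.deg2rad(3) * np.sin(ph)
    elif task in ("squat", "sit_to_stand"):
        knee_max = amplitude * np.deg2rad(85 * jit(0.9, 1.1))
        prof = _bell(t, duration)
        if task == "sit_to_stand":
            prof = 1.0 - _bell(np.minimum(t, duration / 2), duration)  # flexed -> extended
        tilt_amp = np.deg2rad(12 * jit(0.8, 1.2))
        hip_ratio = -0.95 * jit(0.97, 1.03)  # shared across sides
        for side in ("r", "l"):
            knee = -knee_max * prof
            if side == "l":
                knee = knee - left_knee_offset * prof
            q[:, col(f"knee_angle_{side}")] = knee
            q[:, col(f"hip_flexion_{side}")] = hip_ratio * knee
        q[:, col("pelvis_tilt")] = tilt_amp * prof
        # keep both feet flat: the right ankle closes the sagittal chain
        q[:, col("ankle_angle_r")] = -(q[:, col("pelvis_tilt")]
                                       + q[:, col("hip_flexion_r")]
                                       + q[:, col("knee_angle_r")])
        q[:, col("ankle_angle_l")] = -(q[:, col("pelvis_tilt")]
                                      + q[:, col("hip_flexion_l")]
                                      + q[:, col("knee_angle_l")])
        if "lumbar_extension" in names:
            q[:, col("lumbar_extension")] = -0.5 * q[:, col("pelvis_tilt")]
        q = _balance_com(model, q)
    else:
        raise ValueError(f"unknown task {task!r}")
    lo, hi = model.bounds.T
    q = np.clip(q, lo + 1e-6, hi - 1e-6)
    return CoordinateTrajectory(list(names), t, q)


# ---------------------------------------------------------------------------
# Observation rendering
# ---------------------------------------------------------------------------

@dataclass
class RenderedTrial:
    """Per-camera 2D observations plus the generating ground truth."""

    series: list[KeypointSeries2D]
    cameras: list[CameraParameters]
    gt_keypoints3d: KeypointSeries3D     # full scene time base
    gt_markers: MarkerTrajectorySet      # full scene time base
    frame_offsets: list[int]
    scene_times: np.ndarray


def render_observations(model: SkeletalModel, traj: CoordinateTrajectory,
                        cameras: list[CameraParameters], config: RigConfig
                        ) -> RenderedTrial:
    """Render per-camera 2D keypoint series with noise, confidence dropouts,
    occlusions, and integer frame offsets; return ground truth alongside."""
    rng = np.random.default_rng(config.seed)
    fk = model.forward_kinematics(traj.q)
    kp = fk.keypoint_positions()
    kp3d = np.stack([kp[name] for name in KEYPOINT_CANON], axis=1)  # (T, 20, 3)
    mk = fk.marker_positions()
    T, K = kp3d.shape[:2]
    noisy = kp3d + rng.normal(0.0, config.keypoint_noise_sd, size=kp3d.shape)
    offsets = [int(o) for o in config.frame_offsets[:len(cameras)]]
    if len(offsets) < len(cameras):
        offsets += [0] * (len(cameras) - len(offsets))
    shift = [o - min(offsets) for o in offsets]
    t_out = T - max(shift)
    if t_out <= 0:
        raise ValueError("frame offsets exceed trial length")
    series = []
    for c, cam in enumerate(cameras):
        sl = slice(shift[c], shift[c] + t_out)
        pts = noisy[sl].reshape(-1, 3)
        px, valid = project_points(pts, cam.intrinsics, cam.extrinsics)
        px = px.reshape(t_out, K, 2)
        conf = rng.uniform(*config.confidence_base, size=(t_out, K))
        drop = rng.random((t_out, K)) < config.dropout_rate
        conf[drop] = rng.uniform(0.0, 0.25, size=int(drop.sum()))
        px[drop] += rng.normal(0, 40.0, size=(int(drop.sum()), 2))
        if config.occlusion_rate > 0:
            for k in range(K):
                n_occ = rng.poisson(config.occlusion_rate)
                for _ in range(n_occ):
                    start = rng.integers(0, t_out)
                    length = max(1, int(rng.exponential(config.occlusion_duration)
                                        * config.frame_rate))
                    slo = slice(start, min(start + length, t_out))
                    conf[slo, k] = rng.uniform(0.0, 0.04, size=slo.stop - slo.start)
                    px[slo, k] += rng.normal(0, 80.0, size=(slo.stop - slo.start, 2))
        conf[~valid.reshape(t_out, K)] = 0.0
        times = np.arange(t_out) / config.frame_rate
        series.append(KeypointSeries2D(cam.camera_id, config.frame_rate, times,
                                       px, np.clip(conf, 0, 1)))
    gt_kp = KeypointSeries3D(traj.times, kp3d, np.ones((T, K), dtype=bool))
    gt_mk = MarkerTrajectorySet(list(mk.keys()), traj.times, mk)
    return RenderedTrial(series, cameras, gt_kp, gt_mk, shift, traj.times)


# ---------------------------------------------------------------------------
# Corpora and cohorts
# ---------------------------------------------------------------------------

def make_subject_model(base: SkeletalModel, height: float, mass: float,
                       rng: np.random.Generator | None = None,
                       segment_jitter: float = 0.02) -> SkeletalModel:
    """Uniformly scale a fixture model to a subject's height and mass, with
    small per-segment proportions jitter."""
    f = height / base.default_height
    model = base.copy()
    rng = rng or np.random.default_rng(0)
    # jitter proportions per segment *type* so left and right stay mirrored
    jitter: dict[str, float] = {}
    for s in model.segments:
        base_name = s.name.rsplit("_", 1)[0] if s.name.endswith(("_r", "_l")) else s.name
        if base_name not in jitter:
            jitter[base_name] = 1.0 + rng.uniform(-segment_jitter, segment_jitter)
        g = f * jitter[base_name]
        s.com = s.com * g
        s.inertia = s.inertia * g ** 2
        s.markers = {k: v * g for k, v in s.markers.items()}
        s.keypoints = {k: v * g for k, v in s.keypoints.items()}
        for child in model.segments:
            if child.parent == s.name:
                child.origin = child.origin * g
    for m in model.muscles:
        m.path = [(seg, p * f) for seg, p in m.path]
        m.optimal_fiber_length *= f
        m.tendon_slack_length *= f
    for c in model.contact_spheres:
        c.position = c.position * f
    total0 = model.total_mass
    for s in model.segments:
        s.mass = s.mass * mass / total0
    model.default_height = height
    return model


@dataclass
class CorpusTrial:
    subject_id: str
    height: float
    mass: float
    task: str
    split: str  # train | val | test
    times: np.ndarray
    keypoints3d: np.ndarray  # (T, 20, 3), clean
    markers: np.ndarray  # (T, 43, 3)
    keypoint_names: list[str] = field(default_factory=lambda: list(KEYPOINT_CANON))
    marker_names: list[str] = field(default_factory=list)


def _mirror_names(names: list[str]) -> list[int]:
    """Index permutation swapping r_/l_ prefixed names."""
    idx = []
    for n in names:
        if n.startswith("r_"):
            idx.append(names.index("l_" + n[2:]))
        elif n.startswith("l_"):
            idx.append(names.index("r_" + n[2:]))
        else:
            idx.append(names.index(n))
    return idx


def mirror_trial(trial: "CorpusTrial") -> "CorpusTrial":
    """Left-right mirrored copy of a corpus trial (swap sides, negate z)."""
    kp_idx = _mirror_names(trial.keypoint_names)
    mk_idx = _mirror_names(trial.marker_names)
    kp = trial.keypoints3d[:, kp_idx].copy()
    mk = trial.markers[:, mk_idx].copy()
    kp[:, :, 2] *= -1
    mk[:, :, 2] *= -1
    return CorpusTrial(trial.subject_id + "m", trial.height, trial.mass,
                       trial.task, trial.split, trial.times, kp, mk,
                       list(trial.keypoint_names), list(trial.marker_names))


def generate_augmenter_corpus(n_subjects: int = 50,
                              tasks: tuple = ("walk", "squat", "sit_to_stand", "static"),
                              model: SkeletalModel | None = None,
                              duration: float = 3.0, frame_rate: float = 60.0,
                              seed: int = 0,
                              height_range: tuple = (1.50, 1.95),
                              mass_range: tuple = (50.0, 100.0),
                              mirror: bool = True
                              ) -> list[CorpusTrial]:
    """Paired (keypoint, marker) trials over scaled fixture subjects with a
    subject-level ~80/10/10 train/val/test split.

    With ``mirror`` every trial is duplicated left-right mirrored, which
    makes the learned keypoint-to-marker map unbiased between limbs by
    construction.
    """
    base = model or demo3d()
    rng = np.random.default_rng(seed)
    n_val = max(1, round(0.1 * n_subjects))
    n_test = max(1, round(0.1 * n_subjects))
    split_labels = (["train"] * (n_subjects - n_val - n_test)
                    + ["val"] * n_val + ["test"] * n_test)
    trials = []
    for s_i in range(n_subjects):
        height = rng.uniform(*height_range)
        mass = rng.uniform(*mass_range) * (height / 1.72)  # taller -> heavier
        mass = float(np.clip(mass, *mass_range))
        subj = make_subject_model(base, height, mass, rng)
        for task in tasks:
            # random between-limb offsets decorrelate the left and right
            # channels, so the regressor cannot lean on mirror symmetry
            offset = float(rng.normal(0.0, 0.12)) if task != "walk" else 0.0
            traj = generate_motion(task, subj, duration=duration,
                                   frame_rate=frame_rate,
                                   seed=int(rng.integers(2 ** 31)),
                                   left_knee_offset=offset)
            fk = subj.forward_kinematics(traj.q)
            kp = fk.keypoint_positions()
            mk = fk.marker_positions()
            trial = CorpusTrial(
                subject_id=f"S{s_i:03d}", height=height, mass=mass, task=task,
                split=split_labels[s_i], times=traj.times,
                keypoints3d=np.stack([kp[n] for n in KEYPOINT_CANON], axis=1),
                markers=np.stack([mk[n] for n in base.marker_names], axis=1),
                marker_names=list(base.marker_names))
            trials.append(trial)
            if mirror:
                trials.append(mirror_trial(trial))
    return trials


@dataclass
class CohortTrial:
    subject_id: str
    condition: str  # natural | asymmetric
    model: SkeletalModel
    reference: CoordinateTrajectory
    height: float
    mass: float
    effect: float


def generate_cohort(study: str, n: int = 20, effect: float = 0.6,
                    seed: int = 0, duration: float = 1.6,
                    frame_rate: float = 60.0) -> list[CohortTrial]:
    """Paired-condition cohorts with a known imposed effect.

    ``squat_symmetry``: each subject squats "naturally" and "asymmetrically";
    the asymmetric condition adds extra left-knee flexion scaled by
    (1 - effect), unloading the left leg.  ``effect`` = 1 imposes no
    difference (the null).  Same subject anthropometry across conditions.
    """
    if study not in ("squat_symmetry", "sit_to_stand", "knee_loading"):
        raise ValueError(f"unknown study {study!r}")
    base = demo2d()
    rng = np.random.default_rng(seed)
    task = {"squat_symmetry": "squat", "sit_to_stand": "sit_to_stand",
            "knee_loading": "walk"}[study]
    out = []
    for i in range(n):
        height = rng.uniform(1.55, 1.92)
        mass = float(np.clip(rng.uniform(52, 98) * (height / 1.72), 50, 105))
        subj = make_subject_model(base, height, mass, rng)
        motion_seed = int(rng.integers(2 ** 31))
        for cond in ("natural", "asymmetric"):
            offset = 0.0
            if cond == "asymmetric" and task == "squat":
                # the effect scale is defined so f = 0.6 produces the near-
                # complete unloading of the involved limb seen in instructed
                # asymmetric squats; smaller (1 - f) shades gradually to none
                offset = (1.0 - effect) * 1.1  # rad of extra left-knee flexion
            # moderate squat depth keeps knee excursion plus imposed offset
            # well inside the joint bounds
            amp = 0.75 if task == "squat" else (1.0 if cond == "natural" else 1.15)
            traj = generate_motion(task, subj, duration=duration,
                                   frame_rate=frame_rate, seed=motion_seed,
                                   amplitude=amp, left_knee_offset=offset)
            out.append(CohortTrial(f"C{i:03d}", cond, subj, traj, height, mass, effect))
    return out
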