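"""Inverse kinematics and coordinate-trajectory processing.

IK solves, frame by frame, the weighted nonlinear least-squares problem

    min_q  sum_i w_i || m_i_model(q) - m_i_obs ||^2

over the model's generalized coordinates, warm-started from the previous
frame, with a tiny configurable regularization toward the previous frame to
resolve redundancy.  Gradients use the model's analytic marker Jacobians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.signal import butter, sosfiltfilt

from .io import MarkerTrajectorySet
from .models import SkeletalModel


@dataclass
class CoordinateTrajectory:
    """Generalized-coordinate time series q(t), optionally with derivatives."""

    coordinate_names: list[str]
    times: np.ndarray  # (T,)
    q: np.ndarray  # (T, nq) rad | m
    qd: np.ndarray | None = None
    qdd: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.q.shape != (len(self.times), len(self.coordinate_names)):
            raise ValueError("q shape mismatch")
        if len(self.times) > 1 and np.ptp(np.diff(self.times)) > 1e-6:
            raise ValueError("time base must be uniform")

    @property
    def dt(self) -> float:
        return float(np.mean(np.diff(self.times))) if len(self.times) > 1 else 0.0

    def column(self, name: str) -> np.ndarray:
        return self.q[:, self.coordinate_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times,
                             **{n: self.q[:, j] for j, n in enumerate(self.coordinate_names)}})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "CoordinateTrajectory":
        names = [c for c in df.columns if c != "time"]
        return cls(names, df["time"].to_numpy(), df[names].to_numpy())

    def copy(self) -> "CoordinateTrajectory":
        return CoordinateTrajectory(
            list(self.coordinate_names), self.times.copy(), self.q.copy(),
            None if self.qd is None else self.qd.copy(),
            None if self.qdd is None else self.qdd.copy())


class IKError(RuntimeError):
    pass


def inverse_kinematics(model: SkeletalModel, markers: MarkerTrajectorySet,
                       weights: dict[str, float] | None = None,
                       q0: np.ndarray | None = None,
                       regularization: float = 1e-6,
                       max_failure_fraction: float = 0.05
                       ) -> tuple[CoordinateTrajectory, np.ndarray]:
    """Track observed markers with the model.  Returns (trajectory, per-frame
    marker RMSE in meters).

    Markers present in both the observation set and the model are used;
    frames where an observation is NaN drop that marker for that frame.
    """
    att = []  # (name, segment, local)
    for s in model.segments:
        for name, local in s.markers.items():
            if name in markers.positions:
                att.append((name, s.name, local))
    if not att:
        raise IKError("no observed markers map onto model attachments")
    w = np.array([np.sqrt((weights or {}).get(name, 1.0)) for name, _, _ in att])
    obs = np.stack([markers.positions[name] for name, _, _ in att], axis=1)  # (T, M, 3)
    T, M = obs.shape[:2]
    nq = model.nq
    lo, hi = model.bounds.T
    q_prev = model.default_pose() if q0 is None else np.asarray(q0, dtype=float)
    reg = np.sqrt(regularization)

    qs = np.empty((T, nq))
    rmse = np.empty(T)
    failures = []
    for t in range(T):
        mask = np.all(np.isfinite(obs[t]), axis=1)
        target = obs[t]
        w_t = np.where(mask, w, 0.0)

        def resid(q):
            fk = model.forward_kinematics(q)
            r = np.empty(3 * M + nq)
            for i, (_, seg, local) in enumerate(att):
                r[3 * i:3 * i + 3] = w_t[i] * (fk.point(seg, local) - target[i])
            r[3 * M:] = reg * (q - q_prev)
            return r

        def jac(q):
            fk = model.forward_kinematics(q)
            J = np.zeros((3 * M + nq, nq))
            for i, (_, seg, local) in enumerate(att):
                if w_t[i] > 0:
                    J[3 * i:3 * i + 3] = w_t[i] * fk.point_jacobian(seg, local)
            J[3 * M:] = reg * np.eye(nq)
            return J

        sol = least_squares(resid, np.clip(q_prev, lo, hi), jac=jac, bounds=(lo, hi),
                            method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-10)
        if not sol.success:
            failures.append(t)
        qs[t] = sol.x
        err = sol.fun[:3 * M].reshape(M, 3)
        used = w_t > 0
        rmse[t] = np.sqrt(np.mean(np.sum((err[used] / w_t[used, None]) ** 2, axis=1))) \
            if used.any() else np.nan
        q_prev = sol.x
    if len(failures) > max_failure_fraction * T:
        raise IKError(f"IK failed on {len(failures)}/{T} frames: {failures[:20]}")
    return CoordinateTrajectory(list(model.coordinate_names), markers.times, qs), rmse


def lowpass_filter(traj, cutoff: float, order: int = 4):
    """Zero-lag (forward-backward) Butterworth low-pass filter.

    Accepts a CoordinateTrajectory (returns a filtered copy) or a plain array
    with a sampling rate given via ``traj=(array, fs)``.  Default cutoffs in
    this package follow gait practice: 12 Hz for gait, 30 Hz for non-gait.
    """
    if isinstance(traj, CoordinateTrajectory):
        fs = 1.0 / traj.dt
        if cutoff >= fs / 2:
            raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2} Hz)")
        sos = butter(order, cutoff, fs=fs, output="sos")
        out = traj.copy()
        out.q = sosfiltfilt(sos, traj.q, axis=0, padtype="odd")
        out.qd = out.qdd = None
        return out
    arr, fs = traj
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2} Hz)")
    sos = butter(order, cutoff, fs=fs, output="sos")
    return sosfiltfilt(sos, np.asarray(arr, dtype=float), axis=0, padtype="odd")


def differentiate(traj: CoordinateTrajectory) -> CoordinateTrajectory:
    """Central-difference velocities and accelerations (one-sided at ends)."""
    if len(traj.times) < 5:
        raise ValueError("need at least 5 frames to differentiate")
    out = traj.copy()
    out.qd = np.gradient(traj.q, traj.times, axis=0)
    out.qdd = np.gradient(out.qd, traj.times, axis=0)
    return out
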