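"""Multi-camera keypoint processing: occlusion gap filling, cross-camera time
synchronization by cross-correlation of keypoint velocities, and
confidence-weighted DLT triangulation.

The 20-keypoint canon (neck, mid-hip, left/right shoulders, hips, knees,
ankles, heels, small and big toes, elbows, wrists) is fixed; see
``markerless.models.KEYPOINT_CANON`` for names and order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

from .cameras import CameraParameters, undistort_points
from .models import KEYPOINT_CANON


@dataclass
class KeypointSeries2D:
    """Per-camera 2D keypoint time series with confidences.

    positions: (T, K, 2) px; confidence: (T, K) in [0, 1]; exactly the
    20-keypoint canon, canonical order.
    """

    camera_id: str
    frame_rate: float
    times: np.ndarray  # (T,)
    positions: np.ndarray  # (T, K, 2)
    confidence: np.ndarray  # (T, K)
    keypoint_names: list[str] = field(default_factory=lambda: list(KEYPOINT_CANON))

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.confidence = np.asarray(self.confidence, dtype=float)
        if list(self.keypoint_names) != list(KEYPOINT_CANON):
            raise ValueError("keypoint names must be the 20-name canon in canonical order")
        if self.positions.shape != (len(self.times), len(self.keypoint_names), 2):
            raise ValueError("positions shape mismatch")
        if self.confidence.shape != self.positions.shape[:2]:
            raise ValueError("confidence shape mismatch")
        if np.any(self.confidence < 0) or np.any(self.confidence > 1):
            raise ValueError("confidences must lie in [0, 1]")
        if len(self.times) > 1:
            dt = np.diff(self.times)
            if np.any(dt <= 0) or np.ptp(dt) > 1e-6:
                raise ValueError("times must be strictly increasing and uniform")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def copy(self) -> "KeypointSeries2D":
        return KeypointSeries2D(self.camera_id, self.frame_rate, self.times.copy(),
                                self.positions.copy(), self.confidence.copy(),
                                list(self.keypoint_names))


@dataclass
class KeypointSeries3D:
    """Triangulated 3D keypoints with per-frame, per-keypoint validity."""

    times: np.ndarray  # (T,)
    positions: np.ndarray  # (T, K, 3) m; NaN where invalid
    validity: np.ndarray  # (T, K) bool
    keypoint_names: list[str] = field(default_factory=lambda: list(KEYPOINT_CANON))

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.validity = np.asarray(self.validity, dtype=bool)
        if np.any(~np.isfinite(self.positions[self.validity])):
            raise ValueError("valid positions must be finite")

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.times))) if len(self.times) > 1 else 0.0


class SyncError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Occlusion handling
# ---------------------------------------------------------------------------

def fill_gaps(series: KeypointSeries2D, max_gap: float = 0.5,
              conf_floor: float = 0.4) -> KeypointSeries2D:
    """Interpolate short low-confidence dropouts.

    Runs of frames with confidence < ``conf_floor`` lasting at most
    ``max_gap`` seconds are replaced by cubic-spline interpolation of the
    flanking high-confidence samples, and their confidence is set to the mean
    of the flanking confidences.  Longer runs are left untouched (confidence
    stays low and they are excluded downstream).
    """
    out = series.copy()
    dt = 1.0 / series.frame_rate
    max_frames = int(round(max_gap / dt))
    T = series.n_frames
    for k in range(len(series.keypoint_names)):
        low = series.confidence[:, k] < conf_floor
        good = ~low
        if not low.any() or good.sum() < 2:
            continue
        spline = CubicSpline(series.times[good], series.positions[good, k, :], axis=0)
        # enumerate interior runs of low-confidence frames
        idx = np.flatnonzero(low)
        runs = np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1)
        for run in runs:
            lo, hi = run[0], run[-1]
            if lo == 0 or hi == T - 1 or len(run) > max_frames:
                continue
            out.positions[run, k, :] = spline(series.times[run])
            out.confidence[run, k] = 0.5 * (series.confidence[lo - 1, k]
                                            + series.confidence[hi + 1, k])
    return out


# ---------------------------------------------------------------------------
# Synchronization
# ---------------------------------------------------------------------------

def velocity_signal(series: KeypointSeries2D) -> np.ndarray:
    """Confidence-weighted mean keypoint speed per frame (px/s).  -> (T,)."""
    if series.n_frames < 3:
        raise SyncError("need at least 3 frames to form a velocity signal")
    v = np.gradient(series.positions, series.times, axis=0)  # (T, K, 2)
    speed = np.linalg.norm(v, axis=2)  # (T, K)
    w = series.confidence.copy()
    bad = ~np.isfinite(speed)  # invalid projections carry no information
    speed[bad] = 0.0
    w[bad] = 0.0
    tot = w.sum(axis=1)
    signal = np.zeros(series.n_frames)
    nz = tot > 0
    signal[nz] = (speed * w).sum(axis=1)[nz] / tot[nz]
    return signal


def estimate_lag(signal_a: np.ndarray, signal_b: np.ndarray, max_lag: int = 240) -> int:
    """Integer-frame lag of b relative to a by normalized cross-correlation.

    Positive lag means b starts later than a (b's content is delayed).  Ties
    are broken toward the smaller |lag|.
    """
    a = np.asarray(signal_a, dtype=float)
    b = np.asarray(signal_b, dtype=float)
    if len(a) < 2 * max_lag or len(b) < 2 * max_lag:
        raise SyncError(f"signals must be at least 2*max_lag={2 * max_lag} frames long")
    a = a - a.mean()
    b = b - b.mean()
    if np.allclose(a, 0) or np.allclose(b, 0):
        raise SyncError("cannot synchronize zero-variance (static) signals")
    lags = np.arange(-max_lag, max_lag + 1)
    score = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            xa, xb = a[lag:], b[:len(b) - lag]
        else:
            xa, xb = a[:len(a) + lag], b[-lag:]
        n = min(len(xa), len(xb))
        xa, xb = xa[:n], xb[:n]
        denom = np.linalg.norm(xa) * np.linalg.norm(xb)
        score[i] = (xa @ xb) / denom if denom > 0 else -np.inf
    best = score.max()
    candidates = lags[np.isclose(score, best, rtol=0, atol=1e-12)]
    return int(candidates[np.argmin(np.abs(candidates))])


def synchronize(series_list: list[KeypointSeries2D], max_lag: int = 240
                ) -> tuple[list[KeypointSeries2D], list[int]]:
    """Align multiple camera series to the first one.

    A keypoint-velocity signal is built per camera; pairwise lags against the
    first series are estimated; series are trimmed to the maximal common
    window and share identical times afterwards.  Returns (aligned series,
    applied lags).
    """
    rates = {s.frame_rate for s in series_list}
    if len(rates) != 1:
        raise SyncError("all series must share one frame rate")
    ref = velocity_signal(series_list[0])
    lags = [0]
    for s in series_list[1:]:
        lags.append(estimate_lag(ref, velocity_signal(s), max_lag))
    # lag_c > 0 means camera c started later: its frame i shows the scene at
    # reference index i + lag_c.  Start every aligned series at the latest
    # common scene index and trim to the shortest remaining length.
    scene_start = max(0, max(lags))
    starts = [scene_start - lag for lag in lags]
    n_common = min(s.n_frames - st for s, st in zip(series_list, starts))
    if n_common <= 0:
        raise SyncError("no common window after alignment")
    aligned = []
    t0 = series_list[0].times[:n_common] - series_list[0].times[0]
    for s, start in zip(series_list, starts):
        aligned.append(KeypointSeries2D(
            s.camera_id, s.frame_rate, t0,
            s.positions[start:start + n_common].copy(),
            s.confidence[start:start + n_common].copy(),
            list(s.keypoint_names)))
    return aligned, lags


# ---------------------------------------------------------------------------
# Triangulation
# ---------------------------------------------------------------------------

def triangulate_frame(observations: list[tuple[np.ndarray, float]],
                      cameras: list[CameraParameters],
                      min_confidence: float = 0.3) -> tuple[np.ndarray, bool]:
    """Confidence-weighted homogeneous DLT triangulation of one point.

    ``observations`` holds one (pixel position (2,), confidence) pair per
    camera.  Observations are undistorted to normalized coordinates; each
    camera contributes two DLT rows scaled by its confidence; the solution is
    the smallest right singular vector.  Returns (xyz, valid); valid is False
    when fewer than two cameras pass ``min_confidence``.
    """
    rows = []
    for (px, conf), cam in zip(observations, cameras):
        px = np.asarray(px, dtype=float)
        if conf < min_confidence or not np.all(np.isfinite(px)):
            continue
        xn, ok = undistort_points(px[None, :], cam.intrinsics)
        if not ok[0]:
            continue
        R, t = cam.extrinsics.R, cam.extrinsics.translation
        P = np.hstack([R, t[:, None]])  # normalized projection, 3x4
        x, y = xn[0]
        rows.append(conf * (x * P[2] - P[0]))
        rows.append(conf * (y * P[2] - P[1]))
    if len(rows) < 4:
        return np.full(3, np.nan), False
    A = np.asarray(rows)
    _, _, Vt = np.linalg.svd(A)
    X = Vt[-1]
    if abs(X[3]) < 1e-12:
        return np.full(3, np.nan), False
    return X[:3] / X[3], True


def triangulate(series_list: list[KeypointSeries2D],
                cameras: list[CameraParameters],
                min_confidence: float = 0.3) -> KeypointSeries3D:
    """Per-frame, per-keypoint confidence-weighted DLT over synchronized series."""
    t0 = series_list[0].times
    for s in series_list[1:]:
        if s.n_frames != len(t0) or np.max(np.abs(s.times - t0)) > 1e-9:
            raise SyncError("series must be synchronized (identical times) before triangulation")
    T, K = series_list[0].positions.shape[:2]
    pos = np.full((T, K, 3), np.nan)
    valid = np.zeros((T, K), dtype=bool)
    # precompute undistorted normalized coordinates per camera (vectorized)
    norm = []
    for s, cam in zip(series_list, cameras):
        flat = s.positions.reshape(-1, 2)
        finite = np.all(np.isfinite(flat), axis=1)
        xn = np.full_like(flat, np.nan)
        if finite.any():
            xn_f, ok = undistort_points(flat[finite], cam.intrinsics)
            xn_f[~ok] = np.nan
            xn[finite] = xn_f
        norm.append(xn.reshape(T, K, 2))
    P = [np.hstack([c.extrinsics.R, c.extrinsics.translation[:, None]]) for c in cameras]
    for t in range(T):
        for k in range(K):
            rows = []
            for c in range(len(cameras)):
                conf = series_list[c].confidence[t, k]
                xn = norm[c][t, k]
                if conf < min_confidence or not np.all(np.isfinite(xn)):
                    continue
                rows.append(conf * (xn[0] * P[c][2] - P[c][0]))
                rows.append(conf * (xn[1] * P[c][2] - P[c][1]))
            if len(rows) < 4:
                continue
            _, _, Vt = np.linalg.svd(np.asarray(rows))
            X = Vt[-1]
            if abs(X[3]) < 1e-12:
                continue
            pos[t, k] = X[:3] / X[3]
            valid[t, k] = True
    return KeypointSeries3D(t0, pos, valid, list(series_list[0].keypoint_names))
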