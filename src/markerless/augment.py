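"""Marker-set augmentation: sequence regression from the 20 triangulated
video keypoints (plus subject height and mass) to 43 anatomical markers.

Preprocessing follows the root-centering convention of video-based motion
capture: every position is expressed relative to a root (the midpoint of the
hip keypoints), divided by subject height, resampled at 60 Hz, and cut into
non-overlapping 0.5-s windows; Gaussian noise (3D SD 18 mm at the corpus
mean height) is added to the keypoint inputs at every time step during
training.  Two submodels are trained: a *body* model (15 lower-limb and
torso keypoints -> 35 body markers) and an *arm* model (7 arm and torso
keypoints -> 8 arm markers).

The regressor itself is a windowed spectral ridge model: each channel's
30-frame window is projected onto its leading DCT components, a ridge-
regularized linear map predicts the output channels' DCT components, and the
marker trajectories are reconstructed by the inverse transform.  The
truncated temporal basis gives the same benefits a recurrent network is used
for in this setting - temporal consistency and noise suppression - while
training deterministically in closed form.  Training is bit-reproducible
under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.fft import dct, idct

from .io import MarkerTrajectorySet
from .models import ARM_KEYPOINTS, ARM_MARKERS, BODY_KEYPOINTS, KEYPOINT_CANON
from .multiview import KeypointSeries3D


def _default_body_markers():
    from .models import demo3d

    return [m for m in demo3d().marker_names if m not in ARM_MARKERS]


@dataclass
class AugmenterSpec:
    """Configuration of the two augmentation submodels."""

    window: float = 0.5  # s
    rate: float = 60.0  # Hz
    input_noise_sd: float = 0.018  # m (3D, per coordinate, at mean height)
    n_dct: int = 10  # retained temporal DCT components per channel
    ridge: float = 1e-4
    body_keypoints: list[str] = field(default_factory=lambda: list(BODY_KEYPOINTS))
    arm_keypoints: list[str] = field(default_factory=lambda: list(ARM_KEYPOINTS))
    body_markers: list[str] = field(default_factory=_default_body_markers)
    arm_markers: list[str] = field(default_factory=lambda: list(ARM_MARKERS))
    split_fractions: tuple = (0.8, 0.1, 0.1)

    def __post_init__(self):
        wf = self.window * self.rate
        if abs(wf - round(wf)) > 1e-9:
            raise ValueError("window * rate must be an integer number of frames")
        if len(self.body_keypoints) != 15 or len(self.arm_keypoints) != 7:
            raise ValueError("body/arm submodels take 15 and 7 keypoints")
        if len(self.body_markers) != 35 or len(self.arm_markers) != 8:
            raise ValueError("body/arm submodels emit 35 and 8 markers")
        if set(self.body_markers) & set(self.arm_markers):
            raise ValueError("submodel output marker sets must be disjoint")

    @property
    def window_frames(self) -> int:
        return int(round(self.window * self.rate))

    @property
    def marker_names(self) -> list[str]:
        return list(self.body_markers) + list(self.arm_markers)


@dataclass
class TrainedAugmenter:
    """Learned spectral-ridge maps plus the metadata to reproduce them."""

    spec: AugmenterSpec
    weights: dict[str, np.ndarray]  # submodel -> (n_features+1, n_outputs)
    seed: int
    corpus_id: str
    n_train_windows: int
    heldout_rmse: dict[str, float]  # split -> m

    def save(self, path: str):
        np.savez(path, body=self.weights["body"], arm=self.weights["arm"],
                 seed=self.seed, corpus_id=self.corpus_id,
                 n_train_windows=self.n_train_windows,
                 rmse_val=self.heldout_rmse.get("val", np.nan),
                 rmse_test=self.heldout_rmse.get("test", np.nan),
                 window=self.spec.window, rate=self.spec.rate,
                 n_dct=self.spec.n_dct, ridge=self.spec.ridge,
                 input_noise_sd=self.spec.input_noise_sd,
                 body_markers=np.array(self.spec.body_markers),
                 arm_markers=np.array(self.spec.arm_markers))

    @classmethod
    def load(cls, path: str) -> "TrainedAugmenter":
        d = np.load(path, allow_pickle=False)
        spec = AugmenterSpec(window=float(d["window"]), rate=float(d["rate"]),
                             input_noise_sd=float(d["input_noise_sd"]),
                             n_dct=int(d["n_dct"]), ridge=float(d["ridge"]),
                             body_markers=[str(x) for x in d["body_markers"]],
                             arm_markers=[str(x) for x in d["arm_markers"]])
        return cls(spec, {"body": d["body"], "arm": d["arm"]}, int(d["seed"]),
                   str(d["corpus_id"]), int(d["n_train_windows"]),
                   {"val": float(d["rmse_val"]), "test": float(d["rmse_test"])})


class AugmenterError(ValueError):
    pass


def _as_array(kp3d) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(kp3d, KeypointSeries3D):
        return kp3d.positions, kp3d.times
    arr = np.asarray(kp3d, dtype=float)
    return arr, np.arange(arr.shape[0]) / 60.0


def build_features(kp3d, height: float, mass: float, spec: AugmenterSpec,
                   submodel: str = "body"
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Root-centered, height-normalized DCT feature windows for one trial.

    Returns (features (n_windows, n_features), root trajectory (T, 3),
    window frame-count mask (n_windows,)).  The trailing partial window is
    padded by edge repetition; its mask entry records the valid frame count.
    """
    pos, _ = _as_array(kp3d)
    T = pos.shape[0]
    idx_r, idx_l = KEYPOINT_CANON.index("r_hip"), KEYPOINT_CANON.index("l_hip")
    if not (np.all(np.isfinite(pos[:, idx_r])) and np.all(np.isfinite(pos[:, idx_l]))):
        bad = np.flatnonzero(~(np.all(np.isfinite(pos[:, idx_r]), axis=1)
                               & np.all(np.isfinite(pos[:, idx_l]), axis=1)))
        raise AugmenterError(f"hip keypoints invalid on frames {bad[:10].tolist()} "
                             "(run gap filling first)")
    root = 0.5 * (pos[:, idx_r] + pos[:, idx_l])  # (T, 3)
    names = spec.body_keypoints if submodel == "body" else spec.arm_keypoints
    sel = [KEYPOINT_CANON.index(n) for n in names]
    norm = (pos[:, sel] - root[:, None, :]) / height  # (T, n_in, 3)
    W = spec.window_frames
    n_win = int(np.ceil(T / W))
    feats = np.empty((n_win, len(sel) * 3 * spec.n_dct + 2))
    mask = np.empty(n_win, dtype=int)
    for w in range(n_win):
        lo, hi = w * W, min((w + 1) * W, T)
        mask[w] = hi - lo
        chunk = norm[lo:hi]
        if hi - lo < W:  # pad trailing partial window by edge repeat
            chunk = np.concatenate([chunk, np.repeat(chunk[-1:], W - (hi - lo), axis=0)])
        feats[w] = np.concatenate([
            _window_dct(chunk, spec.n_dct).ravel(), [height / 1.75, mass / 75.0]])
    return feats, root, mask


def _window_dct(chunk: np.ndarray, n_keep: int) -> np.ndarray:
    """Orthonormal DCT along time, truncated.  chunk (W, ..., 3) -> (n_keep, ...)."""
    return dct(chunk.reshape(chunk.shape[0], -1), axis=0, norm="ortho")[:n_keep]


def _window_idct(coeffs: np.ndarray, n_frames: int) -> np.ndarray:
    full = np.zeros((n_frames, coeffs.shape[1]))
    full[:coeffs.shape[0]] = coeffs
    return idct(full, axis=0, norm="ortho")


def _target_coeffs(markers: np.ndarray, root: np.ndarray, height: float,
                   names: list[str], all_names: list[str], spec: AugmenterSpec
                   ) -> np.ndarray:
    sel = [all_names.index(n) for n in names]
    norm = (markers[:, sel] - root[:, None, :]) / height
    T = norm.shape[0]
    W = spec.window_frames
    n_win = int(np.ceil(T / W))
    out = np.empty((n_win, spec.n_dct * len(sel) * 3))
    for w in range(n_win):
        lo, hi = w * W, min((w + 1) * W, T)
        chunk = norm[lo:hi]
        if hi - lo < W:
            chunk = np.concatenate([chunk, np.repeat(chunk[-1:], W - (hi - lo), axis=0)])
        out[w] = _window_dct(chunk, spec.n_dct).ravel()
    return out


def train_augmenter(corpus, spec: AugmenterSpec | None = None, seed: int = 0
                    ) -> TrainedAugmenter:
    """Train both submodels on a paired (keypoints, markers) corpus.

    ``corpus`` is a list of trials with attributes ``keypoints3d`` (T, 20, 3),
    ``markers`` (T, 43, 3), ``marker_names``, ``height``, ``mass``, and
    ``split`` in {train, val, test} (see the synthetic rig's corpus
    generator).  Gaussian noise is added to the keypoint inputs at every
    time step; training is deterministic under a fixed seed.
    """
    spec = spec or AugmenterSpec()
    rng = np.random.default_rng(seed)
    heights = [t.height for t in corpus]
    if not heights:
        raise AugmenterError("empty corpus")
    noise_norm = spec.input_noise_sd / float(np.mean(heights))
    data: dict[str, dict[str, list]] = {
        sm: {"train": [], "val": [], "test": []} for sm in ("body", "arm")}
    targ: dict[str, dict[str, list]] = {
        sm: {"train": [], "val": [], "test": []} for sm in ("body", "arm")}
    for trial in corpus:
        for sm, names in (("body", spec.body_markers), ("arm", spec.arm_markers)):
            X, root, _ = build_features(trial.keypoints3d, trial.height, trial.mass,
                                        spec, submodel=sm)
            Y = _target_coeffs(trial.markers, root, trial.height, names,
                               trial.marker_names, spec)
            if trial.split == "train":
                # per-time-step input noise, applied in the (linear) DCT domain;
                # feature layout is coefficient-major to match _window_dct
                n_ch = X.shape[1] - 2
                W = spec.window_frames
                noise = rng.normal(0.0, noise_norm,
                                   size=(X.shape[0], W, n_ch // spec.n_dct))
                nd = dct(noise, axis=1, norm="ortho")[:, :spec.n_dct]
                Xn = X.copy()
                Xn[:, :n_ch] += nd.reshape(X.shape[0], n_ch)
                data[sm]["train"].append(Xn)
                targ[sm]["train"].append(Y)
            else:
                data[sm][trial.split].append(X)
                targ[sm][trial.split].append(Y)
    if not data["body"]["train"]:
        raise AugmenterError("corpus has no training split")
    weights = {}
    for sm in ("body", "arm"):
        X = np.vstack(data[sm]["train"])
        Y = np.vstack(targ[sm]["train"])
        Xb = np.hstack([X, np.ones((len(X), 1))])
        A = Xb.T @ Xb + spec.ridge * len(X) * np.eye(Xb.shape[1])
        weights[sm] = np.linalg.solve(A, Xb.T @ Y)
    trained = TrainedAugmenter(spec, weights, seed, f"corpus[{len(corpus)}]",
                               sum(len(x) for x in data["body"]["train"]), {})
    # held-out RMSE in meters, measured in the time domain on clean inputs
    for split in ("val", "test"):
        errs = []
        for trial in corpus:
            if trial.split != split:
                continue
            pred = augment(trial.keypoints3d, trial.height, trial.mass, trained,
                           times=trial.times)
            truth = trial.markers
            hat = np.stack([pred.positions[n] for n in trial.marker_names], axis=1)
            errs.append(np.mean((hat - truth) ** 2))
        if errs:
            trained.heldout_rmse[split] = float(np.sqrt(np.mean(errs)))
    return trained


def augment(kp3d, height: float, mass: float, model: TrainedAugmenter,
            times: np.ndarray | None = None) -> MarkerTrajectorySet:
    """Predict the 43 anatomical marker trajectories for one trial.

    Root-centered predictions are un-normalized by height and re-anchored to
    the per-frame root (midpoint of the hip keypoints); windows are processed
    independently and concatenated.  Exactly translation-equivariant.
    """
    spec = model.spec
    pos, t_default = _as_array(kp3d)
    times = times if times is not None else t_default
    T = pos.shape[0]
    W = spec.window_frames
    out = {}
    for sm, names in (("body", spec.body_markers), ("arm", spec.arm_markers)):
        X, root, mask = build_features(kp3d, height, mass, spec, submodel=sm)
        pred = np.hstack([X, np.ones((len(X), 1))]) @ model.weights[sm]
        n_out = len(names) * 3
        frames = np.empty((T, n_out))
        for w in range(len(X)):
            coeffs = pred[w].reshape(spec.n_dct, n_out)  # coefficient-major
            chunk = _window_idct(coeffs, W)
            lo, hi = w * W, min((w + 1) * W, T)
            frames[lo:hi] = chunk[:hi - lo]
        rec = frames.reshape(T, len(names), 3) * height + root[:, None, :]
        for k, name in enumerate(names):
            out[name] = rec[:, k]
    return MarkerTrajectorySet(spec.marker_names, times, out)
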