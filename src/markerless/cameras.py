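"""Pinhole camera model with lens distortion, and single-image extrinsic
calibration from a planar checkerboard.

The camera model has fifteen parameters: 3 rotation + 3 translation
(extrinsics, world->camera), 2 focal lengths, 2 principal point coordinates,
and 5 distortion coefficients (radial k1, k2, k3 and tangential p1, p2).
World frame: right-handed, y-up, meters.  Image frame: origin top-left,
x right, y down, pixels.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation


@dataclass
class CameraIntrinsics:
    fx: float
    fy: float
    cx: float
    cy: float
    distortion: np.ndarray = field(default_factory=lambda: np.zeros(5))  # k1,k2,p1,p2,k3
    image_size: tuple[int, int] = (720, 1280)  # (width, height) px

    def __post_init__(self):
        self.distortion = np.asarray(self.distortion, dtype=float)
        if self.distortion.shape != (5,):
            raise ValueError("distortion must have 5 coefficients (k1,k2,p1,p2,k3)")
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        w, h = self.image_size
        if not (0 <= self.cx <= w and 0 <= self.cy <= h):
            raise ValueError("principal point must lie inside the image bounds")


@dataclass
class CameraExtrinsics:
    """World->camera rigid transform: x_cam = R x_world + t."""

    rotation_vector: np.ndarray  # (3,) axis-angle
    translation: np.ndarray  # (3,) m, world origin in camera frame

    def __post_init__(self):
        self.rotation_vector = np.asarray(self.rotation_vector, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)

    @property
    def R(self) -> np.ndarray:
        return Rotation.from_rotvec(self.rotation_vector).as_matrix()


@dataclass
class CameraParameters:
    intrinsics: CameraIntrinsics
    extrinsics: CameraExtrinsics
    camera_id: str = "cam"


@dataclass
class CheckerboardSpec:
    inner_corner_rows: int
    inner_corner_cols: int
    square_size: float  # m

    def __post_init__(self):
        if self.inner_corner_rows < 2 or self.inner_corner_cols < 2:
            raise ValueError("checkerboard needs at least 2x2 inner corners")
        if self.square_size <= 0:
            raise ValueError("square size must be positive")

    def corner_points(self) -> np.ndarray:
        """Board-frame (z=0) corner coordinates, row-major.  -> (N, 3)."""
        r, c = self.inner_corner_rows, self.inner_corner_cols
        jj, ii = np.meshgrid(np.arange(c), np.arange(r))
        pts = np.zeros((r * c, 3))
        pts[:, 0] = jj.ravel() * self.square_size
        pts[:, 1] = ii.ravel() * self.square_size
        return pts


def _distort(xn: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Apply the 5-coefficient distortion to normalized coords (N,2)."""
    k1, k2, p1, p2, k3 = dist
    x, y = xn[:, 0], xn[:, 1]
    r2 = x * x + y * y
    radial = 1 + k1 * r2 + k2 * r2 ** 2 + k3 * r2 ** 3
    xd = x * radial + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * radial + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    return np.stack([xd, yd], axis=1)


def project_points(points_world: np.ndarray, intr: CameraIntrinsics,
                   extr: CameraExtrinsics) -> tuple[np.ndarray, np.ndarray]:
    """Project world points (N,3) to pixels (N,2); also returns a validity
    mask that is False for points at non-positive depth."""
    pts = np.atleast_2d(np.asarray(points_world, dtype=float))
    pc = pts @ extr.R.T + extr.translation
    valid = pc[:, 2] > 1e-9
    z = np.where(valid, pc[:, 2], 1.0)
    xn = pc[:, :2] / z[:, None]
    xd = _distort(xn, intr.distortion)
    px = np.empty_like(xd)
    px[:, 0] = intr.fx * xd[:, 0] + intr.cx
    px[:, 1] = intr.fy * xd[:, 1] + intr.cy
    px[~valid] = np.nan
    return px, valid


def undistort_points(points_px: np.ndarray, intr: CameraIntrinsics,
                     max_iter: int = 50, tol: float = 1e-12
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Invert the distortion map: pixels (N,2) -> normalized coords (N,2).

    Newton/fixed-point iteration on the radial-tangential model; returns
    (normalized coords, converged mask).  Redistorting converged output
    reproduces the input to well below 1e-6 px.
    """
    px = np.atleast_2d(np.asarray(points_px, dtype=float))
    if not np.all(np.isfinite(px)):
        raise ValueError("points must be finite")
    xd = np.stack([(px[:, 0] - intr.cx) / intr.fx,
                   (px[:, 1] - intr.cy) / intr.fy], axis=1)
    if not np.any(intr.distortion):
        return xd, np.ones(len(xd), dtype=bool)
    xn = xd.copy()
    for _ in range(max_iter):
        err = _distort(xn, intr.distortion) - xd
        # Jacobian by forward differences on the 2x2 local map
        eps = 1e-8
        J = np.empty((len(xn), 2, 2))
        for j in range(2):
            dx = np.zeros_like(xn)
            dx[:, j] = eps
            J[:, :, j] = (_distort(xn + dx, intr.distortion) - _distort(xn, intr.distortion)) / eps
        det = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        ok = np.abs(det) > 1e-12
        step = np.zeros_like(xn)
        step[ok, 0] = (J[ok, 1, 1] * err[ok, 0] - J[ok, 0, 1] * err[ok, 1]) / det[ok]
        step[ok, 1] = (-J[ok, 1, 0] * err[ok, 0] + J[ok, 0, 0] * err[ok, 1]) / det[ok]
        xn = xn - step
        if np.nanmax(np.abs(err)) < tol:
            break
    final = _distort(xn, intr.distortion) - xd
    converged = np.linalg.norm(final, axis=1) * max(intr.fx, intr.fy) < 1e-6
    return xn, converged


def _homography(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """DLT homography src (N,2) -> dst (N,2) with Hartley normalization."""
    def normalizer(p):
        c = p.mean(axis=0)
        spread = np.mean(np.linalg.norm(p - c, axis=1))
        if spread < 1e-12:
            raise CalibrationError("degenerate point configuration (no spread)")
        s = np.sqrt(2) / spread
        T = np.array([[s, 0, -s * c[0]], [0, s, -s * c[1]], [0, 0, 1]])
        return T

    Ts, Td = normalizer(src), normalizer(dst)
    sh = (np.column_stack([src, np.ones(len(src))]) @ Ts.T)
    dh = (np.column_stack([dst, np.ones(len(dst))]) @ Td.T)
    A = []
    for (x, y, _), (u, v, _) in zip(sh, dh):
        A.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        A.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    _, _, Vt = np.linalg.svd(np.asarray(A))
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    return H / H[2, 2]


class CalibrationError(ValueError):
    pass


def estimate_extrinsics(corners_px: np.ndarray, board: CheckerboardSpec,
                        intr: CameraIntrinsics
                        ) -> tuple[CameraExtrinsics, float]:
    """Estimate the world->camera pose from one checkerboard image.

    The board frame is taken as the world frame (planar target, z=0).
    Initialization decomposes the board->normalized-image homography; the
    pose is then refined by nonlinear minimization of pixel reprojection
    error.  Returns (extrinsics, reprojection RMSE in px).
    """
    corners_px = np.atleast_2d(np.asarray(corners_px, dtype=float))
    obj = board.corner_points()
    if len(corners_px) != len(obj):
        raise CalibrationError(
            f"expected {len(obj)} corners for a "
            f"{board.inner_corner_rows}x{board.inner_corner_cols} board, got {len(corners_px)}")
    if len(obj) < 4:
        raise CalibrationError("need at least 4 corners")
    # collinearity check on the board points actually used
    c = obj[:, :2] - obj[:, :2].mean(axis=0)
    if np.linalg.matrix_rank(c, tol=1e-9) < 2:
        raise CalibrationError("degenerate (collinear) corner configuration")

    xn, _ = undistort_points(corners_px, intr)
    H = _homography(obj[:, :2], xn)
    lam = 1.0 / np.linalg.norm(H[:, 0])
    r1, r2, t = lam * H[:, 0], lam * H[:, 1], lam * H[:, 2]
    if t[2] < 0:  # board must sit in front of the camera
        r1, r2, t = -r1, -r2, -t
    R_approx = np.column_stack([r1, r2, np.cross(r1, r2)])
    U, _, Vt = np.linalg.svd(R_approx)
    R0 = U @ np.diag([1, 1, np.linalg.det(U @ Vt)]) @ Vt
    rv0 = Rotation.from_matrix(R0).as_rotvec()

    def resid(x):
        extr = CameraExtrinsics(x[:3], x[3:])
        px, valid = project_points(obj, intr, extr)
        r = (px - corners_px)
        r[~valid] = 1e3
        return r.ravel()

    sol = least_squares(resid, np.concatenate([rv0, t]), method="lm", xtol=1e-15, ftol=1e-15)
    extr = CameraExtrinsics(sol.x[:3], sol.x[3:])
    rv_norm = np.linalg.norm(extr.rotation_vector)
    if rv_norm > np.pi:  # wrap to the canonical [0, pi] representation
        extr = CameraExtrinsics(
            extr.rotation_vector * (1 - 2 * np.pi / rv_norm), extr.translation)
    rmse = float(np.sqrt(np.mean(sol.fun ** 2)))
    return extr, rmse


# -- camera parameter JSON (see io module docs for the schema) ----------------

def camera_to_dict(cam: CameraParameters) -> dict:
    return {
        "camera_id": cam.camera_id,
        "intrinsics": {
            "fx": cam.intrinsics.fx, "fy": cam.intrinsics.fy,
            "cx": cam.intrinsics.cx, "cy": cam.intrinsics.cy,
            "distortion": [float(v) for v in cam.intrinsics.distortion],
            "image_size": list(cam.intrinsics.image_size),
        },
        "extrinsics": {
            "rotation_vector": [float(v) for v in cam.extrinsics.rotation_vector],
            "translation": [float(v) for v in cam.extrinsics.translation],
        },
    }


def camera_from_dict(doc: dict) -> CameraParameters:
    i = doc["intrinsics"]
    e = doc["extrinsics"]
    return CameraParameters(
        CameraIntrinsics(i["fx"], i["fy"], i["cx"], i["cy"],
                         np.asarray(i.get("distortion", np.zeros(5))),
                         tuple(i.get("image_size", (720, 1280)))),
        CameraExtrinsics(np.asarray(e["rotation_vector"]), np.asarray(e["translation"])),
        doc.get("camera_id", "cam"),
    )


def write_camera_json(cam: CameraParameters, path: str):
    with open(path, "w") as fh:
        json.dump(camera_to_dict(cam), fh, indent=2)


def read_camera_json(path: str) -> CameraParameters:
    with open(path) as fh:
        return camera_from_dict(json.load(fh))
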