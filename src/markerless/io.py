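"""Readers and writers for the on-disk formats.

All unit conversion happens here: TRC files are written in millimeters and
MOT rotational columns in degrees (the conventions of the surrounding
motion-capture ecosystem), while everything in memory is SI (meters,
radians).

Keypoint exchange format: one CSV per camera with columns
``frame, time, <kp>_x, <kp>_y, <kp>_conf, ...`` over the 20-keypoint canon.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import KEYPOINT_CANON
from .multiview import KeypointSeries2D

log = logging.getLogger("markerless")


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Marker trajectories (TRC)
# ---------------------------------------------------------------------------

@dataclass
class MarkerTrajectorySet:
    """Named 3D marker trajectories sharing one time base (m, s)."""

    marker_names: list[str]
    times: np.ndarray  # (T,)
    positions: dict[str, np.ndarray]  # name -> (T, 3) m

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = {k: np.asarray(v, dtype=float) for k, v in self.positions.items()}
        if len(set(self.marker_names)) != len(self.marker_names):
            raise ValueError("marker names must be unique")
        for name in self.marker_names:
            if self.positions[name].shape != (len(self.times), 3):
                raise ValueError(f"ragged trajectory for marker {name!r}")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frame_rate(self) -> float:
        return 1.0 / float(np.mean(np.diff(self.times))) if self.n_frames > 1 else 0.0

    def stacked(self, names: list[str] | None = None) -> np.ndarray:
        names = names if names is not None else self.marker_names
        return np.stack([self.positions[n] for n in names], axis=1)  # (T, M, 3)


def read_trc(path: str) -> MarkerTrajectorySet:
    """Read a TRC marker file (mm on disk -> m in memory)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise ParseError(f"{path}: truncated TRC file ({len(lines)} lines)")
    hdr_names = lines[1].split("\t")
    hdr_vals = lines[2].split("\t")
    hdr = dict(zip(hdr_names, hdr_vals))
    try:
        n_frames = int(hdr["NumFrames"])
        n_markers = int(hdr["NumMarkers"])
        units = hdr["Units"]
    except (KeyError, ValueError) as exc:
        raise ParseError(f"{path}:3: malformed TRC header ({exc})") from exc
    scale = {"mm": 1e-3, "m": 1.0, "cm": 1e-2}.get(units)
    if scale is None:
        raise ParseError(f"{path}:3: unknown Units {units!r}")
    cols = lines[3].rstrip("\t").split("\t")
    markers = [c for c in cols[2:] if c]
    if len(markers) != n_markers:
        raise ParseError(f"{path}:4: header declares {n_markers} markers but "
                         f"{len(markers)} marker columns found")
    data_rows = [ln for ln in lines[5:] if ln.strip()]
    if len(data_rows) != n_frames:
        raise ParseError(f"{path}: expected {n_frames} data rows, found {len(data_rows)}")
    times = np.empty(n_frames)
    pos = np.empty((n_frames, n_markers, 3))
    for i, ln in enumerate(data_rows):
        parts = ln.split("\t")
        if len(parts) < 2 + 3 * n_markers:
            raise ParseError(f"{path}:{6 + i}: row has {len(parts)} fields, "
                             f"expected {2 + 3 * n_markers}")
        try:
            times[i] = float(parts[1])
            pos[i] = np.asarray(parts[2:2 + 3 * n_markers], dtype=float).reshape(n_markers, 3)
        except ValueError as exc:
            raise ParseError(f"{path}:{6 + i}: non-numeric value ({exc})") from exc
    if n_frames > 1 and np.any(np.diff(times) <= 0):
        bad = int(np.flatnonzero(np.diff(times) <= 0)[0])
        raise ParseError(f"{path}:{6 + bad + 1}: non-monotonic time")
    pos = pos * scale
    return MarkerTrajectorySet(markers, times, {m: pos[:, j] for j, m in enumerate(markers)})


def write_trc(markers: MarkerTrajectorySet, path: str):
    """Write a TRC marker file (m in memory -> mm on disk)."""
    if not markers.marker_names:
        raise ValueError("cannot write an empty marker set")
    rate = markers.frame_rate
    n_frames, n_markers = markers.n_frames, len(markers.marker_names)
    lines = [
        f"PathFileType\t4\t(X/Y/Z)\t{os.path.basename(path)}",
        "DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\tOrigDataRate\t"
        "OrigDataStartFrame\tOrigNumFrames",
        f"{rate:.6f}\t{rate:.6f}\t{n_frames}\t{n_markers}\tmm\t{rate:.6f}\t1\t{n_frames}",
        "Frame#\tTime\t" + "\t\t\t".join(markers.marker_names) + "\t\t",
        "\t\t" + "\t".join(f"X{j + 1}\tY{j + 1}\tZ{j + 1}" for j in range(n_markers)),
    ]
    stacked = markers.stacked() * 1e3  # mm
    for i in range(n_frames):
        vals = "\t".join(f"{v:.8f}" for v in stacked[i].ravel())
        lines.append(f"{i + 1}\t{markers.times[i]:.8f}\t{vals}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Coordinate / force tables (MOT, STO)
# ---------------------------------------------------------------------------

def _is_rotational(col: str) -> bool:
    return not any(col.endswith(sfx) for sfx in ("_tx", "_ty", "_tz")) and col != "time"


def read_motion(path: str) -> pd.DataFrame:
    """Read a MOT/STO table; rotational columns are converted to radians when
    the header declares inDegrees=yes.  Returns a DataFrame with a ``time``
    column first; the original column order is preserved."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    header = {}
    body_start = None
    for i, ln in enumerate(lines):
        if ln.strip().lower() == "endheader":
            body_start = i + 1
            break
        if "=" in ln:
            k, v = ln.split("=", 1)
            header[k.strip()] = v.strip()
    if body_start is None:
        raise ParseError(f"{path}: missing endheader sentinel")
    cols = lines[body_start].rstrip().split("\t")
    if cols[0] != "time":
        raise ParseError(f"{path}:{body_start + 1}: first column must be 'time'")
    rows = [ln.split("\t") for ln in lines[body_start + 1:] if ln.strip()]
    n_rows = header.get("nRows")
    if n_rows is not None and int(n_rows) != len(rows):
        raise ParseError(f"{path}: header declares nRows={n_rows} but body has {len(rows)} rows")
    n_cols = header.get("nColumns")
    if n_cols is not None and int(n_cols) != len(cols):
        raise ParseError(f"{path}: header declares nColumns={n_cols} but body has {len(cols)}")
    try:
        data = np.asarray(rows, dtype=float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric body value ({exc})") from exc
    df = pd.DataFrame(data, columns=cols)
    if header.get("inDegrees", "no").lower() == "yes":
        for c in cols:
            if _is_rotational(c):
                df[c] = np.deg2rad(df[c])
    return df


def write_motion(table: pd.DataFrame, path: str, name: str = "motion",
                 in_degrees: bool = True):
    """Write a MOT/STO table (time column first; rotational columns in
    degrees on disk when ``in_degrees``)."""
    if "time" not in table.columns:
        raise ValueError("table must contain a 'time' column")
    if len(table.columns) < 2:
        raise ValueError("table must contain at least one data column")
    cols = ["time"] + [c for c in table.columns if c != "time"]
    out = table[cols].copy()
    if in_degrees:
        for c in cols:
            if _is_rotational(c):
                out[c] = np.rad2deg(out[c])
    lines = [name, "version=1",
             f"nRows={len(out)}", f"nColumns={len(cols)}",
             f"inDegrees={'yes' if in_degrees else 'no'}", "endheader",
             "\t".join(cols)]
    for _, row in out.iterrows():
        lines.append("\t".join(f"{v:.10f}" for v in row.values))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# 2D keypoints (CSV per camera)
# ---------------------------------------------------------------------------

def read_keypoints(path: str, camera_id: str | None = None) -> KeypointSeries2D:
    """Read a per-camera keypoint CSV into canonical keypoint order.

    Confidences outside [0, 1] are clamped with a logged warning; unknown
    keypoint names and negative frame indices are errors.
    """
    df = pd.read_csv(path)
    if "frame" not in df.columns or "time" not in df.columns:
        raise ParseError(f"{path}: keypoint CSV needs 'frame' and 'time' columns")
    if (df["frame"] < 0).any():
        raise ParseError(f"{path}: negative frame index")
    names = []
    for c in df.columns:
        if c.endswith("_x"):
            names.append(c[:-2])
    unknown = sorted(set(names) - set(KEYPOINT_CANON))
    if unknown:
        raise ParseError(f"{path}: unknown keypoint names {unknown}")
    missing = sorted(set(KEYPOINT_CANON) - set(names))
    if missing:
        raise ParseError(f"{path}: missing keypoints {missing}")
    T = len(df)
    pos = np.empty((T, len(KEYPOINT_CANON), 2))
    conf = np.empty((T, len(KEYPOINT_CANON)))
    for k, name in enumerate(KEYPOINT_CANON):
        pos[:, k, 0] = df[f"{name}_x"]
        pos[:, k, 1] = df[f"{name}_y"]
        conf[:, k] = df[f"{name}_conf"]
    if (conf < 0).any() or (conf > 1).any():
        log.warning("%s: %d confidences outside [0, 1] were clamped",
                    path, int(((conf < 0) | (conf > 1)).sum()))
        conf = np.clip(conf, 0.0, 1.0)
    times = df["time"].to_numpy(dtype=float)
    rate = 1.0 / float(np.mean(np.diff(times))) if T > 1 else 60.0
    return KeypointSeries2D(camera_id or os.path.basename(path), rate, times, pos, conf)


def write_keypoints(series: KeypointSeries2D, path: str):
    data = {"frame": np.arange(series.n_frames), "time": series.times}
    for k, name in enumerate(series.keypoint_names):
        data[f"{name}_x"] = series.positions[:, k, 0]
        data[f"{name}_y"] = series.positions[:, k, 1]
        data[f"{name}_conf"] = series.confidence[:, k]
    pd.DataFrame(data).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Trial bundle
# ---------------------------------------------------------------------------

@dataclass
class TrialBundle:
    """References to everything one captured trial needs.

    Heights and masses are the two scalars the marker augmenter consumes in
    addition to keypoints.
    """

    subject_id: str
    height: float  # m
    mass: float  # kg
    task_label: str  # walk | squat | sit_to_stand | drop_jump | other
    keypoint_files: list[str] = field(default_factory=list)
    camera_files: list[str] = field(default_factory=list)
    sampling_rate: float = 60.0

    def __post_init__(self):
        if self.height <= 0 or self.mass <= 0 or self.sampling_rate <= 0:
            raise ValueError("height, mass, and sampling_rate must be positive")

    def validate_files(self):
        """Every referenced file must exist and parse before any stage runs."""
        from .cameras import read_camera_json

        for f in self.keypoint_files:
            read_keypoints(f)
        for f in self.camera_files:
            read_camera_json(f)
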