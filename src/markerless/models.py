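"""Articulated skeletal models: definition, serialization, forward kinematics,
anthropometric scaling, and recursive Newton-Euler inverse dynamics.

A model is a tree of rigid segments rooted at the pelvis.  Each segment
attaches to its parent through a fixed translation (the joint location in the
parent frame) followed by an ordered sequence of single-axis degrees of
freedom (rotations or translations).  Generalized coordinates q collect all
DOFs in tree order.  The world frame is right-handed, y-up, in meters; angles
are radians.

Forward kinematics and inverse dynamics are vectorized over time: q may be a
single configuration ``(nq,)`` or a trajectory ``(T, nq)``.
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field

import numpy as np
import yaml

GRAVITY = np.array([0.0, -9.81, 0.0])

def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cross product over the last axis (faster than np.cross for (T, 3))."""
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out



# ---------------------------------------------------------------------------
# Definition dataclasses
# ---------------------------------------------------------------------------

@dataclass
class Dof:
    """One generalized coordinate actuating a single joint axis."""

    name: str
    kind: str  # 'rotation' | 'translation'
    axis: np.ndarray  # (3,) unit vector, in the frame current when applied
    bounds: tuple[float, float] = (-np.pi, np.pi)

    def __post_init__(self):
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError(f"dof {self.name}: zero axis")
        self.axis = self.axis / n
        if self.kind not in ("rotation", "translation"):
            raise ValueError(f"dof {self.name}: unknown kind {self.kind!r}")


@dataclass
class Segment:
    name: str
    parent: str | None  # None for the root segment
    origin: np.ndarray  # joint location in parent frame (m); ignored for root
    dofs: list[Dof] = field(default_factory=list)
    mass: float = 1.0  # kg
    com: np.ndarray = field(default_factory=lambda: np.zeros(3))  # segment frame
    inertia: np.ndarray = field(default_factory=lambda: 1e-3 * np.ones(3))  # diag, about com
    markers: dict[str, np.ndarray] = field(default_factory=dict)
    keypoints: dict[str, np.ndarray] = field(default_factory=dict)
    scale_pair: tuple[str, str] | None = None  # two markers on this segment

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.com = np.asarray(self.com, dtype=float)
        self.inertia = np.asarray(self.inertia, dtype=float)
        self.markers = {k: np.asarray(v, dtype=float) for k, v in self.markers.items()}
        self.keypoints = {k: np.asarray(v, dtype=float) for k, v in self.keypoints.items()}


@dataclass
class MuscleTendonUnit:
    """Hill-type muscle-tendon actuator with a via-point path."""

    name: str
    path: list[tuple[str, np.ndarray]]  # [(segment, local position m), ...]
    max_isometric_force: float  # N
    optimal_fiber_length: float  # m
    tendon_slack_length: float  # m
    pennation_angle: float = 0.0  # rad, at optimal fiber length
    max_contraction_velocity: float = 10.0  # optimal fiber lengths / s
    activation_time_constant: float = 0.015  # s
    deactivation_time_constant: float = 0.060  # s

    def __post_init__(self):
        self.path = [(seg, np.asarray(p, dtype=float)) for seg, p in self.path]
        if self.max_isometric_force <= 0 or self.optimal_fiber_length <= 0:
            raise ValueError(f"muscle {self.name}: forces and lengths must be positive")
        if self.tendon_slack_length <= 0:
            raise ValueError(f"muscle {self.name}: tendon slack length must be positive")
        if self.activation_time_constant <= 0 or self.deactivation_time_constant < self.activation_time_constant:
            raise ValueError(f"muscle {self.name}: need 0 < tau_act <= tau_deact")


@dataclass
class TorqueMotor:
    """Ideal torque motor on one coordinate with first-order excitation lag."""

    coordinate: str
    max_torque: float  # N*m
    time_constant: float = 0.035  # s


@dataclass
class ContactSphere:
    """Smooth Hunt-Crossley foot-ground contact sphere."""

    segment: str
    position: np.ndarray  # local, m
    radius: float = 0.032
    stiffness: float = 2.5e5  # plane-strain, N/m^1.5
    dissipation: float = 2.0  # s/m
    friction: float = 0.8
    smoothing: float = 1e-4  # m, tanh/sqrt blending scale

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.radius <= 0 or self.stiffness <= 0:
            raise ValueError("contact sphere radius and stiffness must be positive")


class ModelError(ValueError):
    pass


class SkeletalModel:
    """Tree-structured articulated model with muscles, motors, and contact."""

    def __init__(self, name: str, segments: list[Segment],
                 muscles: list[MuscleTendonUnit] | None = None,
                 torque_motors: list[TorqueMotor] | None = None,
                 contact_spheres: list[ContactSphere] | None = None,
                 default_height: float = 1.75):
        self.name = name
        self.muscles = list(muscles or [])
        self.torque_motors = list(torque_motors or [])
        self.contact_spheres = list(contact_spheres or [])
        self.default_height = default_height
        self._set_segments(segments)

    # -- construction / validation -------------------------------------------------

    def _set_segments(self, segments: list[Segment]):
        names = [s.name for s in segments]
        if len(set(names)) != len(names):
            raise ModelError("duplicate segment names")
        by_name = {s.name: s for s in segments}
        roots = [s for s in segments if s.parent is None]
        if len(roots) != 1:
            raise ModelError(f"model must have exactly one root segment, found {len(roots)}")
        # topological order with cycle/orphan detection
        ordered: list[Segment] = []
        visiting: set[str] = set()
        done: set[str] = set()

        def visit(s: Segment):
            if s.name in done:
                return
            if s.name in visiting:
                raise ModelError(f"cycle in segment graph at {s.name!r}")
            visiting.add(s.name)
            if s.parent is not None:
                if s.parent not in by_name:
                    raise ModelError(f"segment {s.name!r} has unknown parent {s.parent!r}")
                visit(by_name[s.parent])
            visiting.discard(s.name)
            done.add(s.name)
            ordered.append(s)

        for s in segments:
            visit(s)
        self.segments = ordered
        self._seg_index = {s.name: i for i, s in enumerate(ordered)}

        # global coordinate list in tree order
        self.coordinates: list[Dof] = []
        self._dof_segment: list[int] = []  # segment index owning each dof
        for i, s in enumerate(ordered):
            for d in s.dofs:
                self.coordinates.append(d)
                self._dof_segment.append(i)
        cnames = [d.name for d in self.coordinates]
        if len(set(cnames)) != len(cnames):
            raise ModelError("duplicate coordinate names")
        self.coordinate_names = cnames
        self.nq = len(cnames)

        # which dofs affect which segment (all dofs on the path from root)
        S, nq = len(ordered), self.nq
        self._affects = np.zeros((S, nq), dtype=bool)
        dof_offset = {}
        k = 0
        for i, s in enumerate(ordered):
            dof_offset[s.name] = (k, k + len(s.dofs))
            k += len(s.dofs)
        for i, s in enumerate(ordered):
            cur = s
            while cur is not None:
                lo, hi = dof_offset[cur.name]
                self._affects[i, lo:hi] = True
                cur = by_name[cur.parent] if cur.parent is not None else None

        mk = [m for s in ordered for m in s.markers]
        if len(set(mk)) != len(mk):
            raise ModelError("duplicate marker names")
        self.marker_names = mk
        self.keypoint_names = [kpn for s in ordered for kpn in s.keypoints]
        muscle_coords = set()
        for m in self.muscles:
            for seg, _ in m.path:
                if seg not in self._seg_index:
                    raise ModelError(f"muscle {m.name}: unknown segment {seg!r}")
        for tm in self.torque_motors:
            if tm.coordinate not in self.coordinate_names:
                raise ModelError(f"torque motor on unknown coordinate {tm.coordinate!r}")

    def segment(self, name: str) -> Segment:
        return self.segments[self._seg_index[name]]

    def coordinate_index(self, name: str) -> int:
        return self.coordinate_names.index(name)

    @property
    def total_mass(self) -> float:
        return float(sum(s.mass for s in self.segments))

    @property
    def bounds(self) -> np.ndarray:
        return np.array([d.bounds for d in self.coordinates])  # (nq, 2)

    def default_pose(self) -> np.ndarray:
        q = np.zeros(self.nq)
        lo, hi = self.bounds.T
        return np.clip(q, lo, hi)

    def copy(self) -> "SkeletalModel":
        return copy.deepcopy(self)

    # -- forward kinematics --------------------------------------------------------

    def forward_kinematics(self, q: np.ndarray) -> "FKResult":
        """Compose joint transforms root-to-leaf.  q: (nq,) or (T, nq)."""
        q = np.asarray(q, dtype=float)
        single = q.ndim == 1
        if single:
            q = q[None, :]
        if q.shape[1] != self.nq:
            raise ValueError(f"expected {self.nq} coordinates, got {q.shape[1]}")
        T = q.shape[0]
        S = len(self.segments)
        R = np.zeros((S, T, 3, 3))
        p = np.zeros((S, T, 3))
        axis_w = np.zeros((self.nq, T, 3))
        point_w = np.zeros((self.nq, T, 3))
        k = 0
        for i, s in enumerate(self.segments):
            if s.parent is None:
                Rc = np.broadcast_to(np.eye(3), (T, 3, 3)).copy()
                pc = np.zeros((T, 3))
            else:
                j = self._seg_index[s.parent]
                Rc = R[j].copy()
                pc = p[j] + np.einsum("tij,j->ti", R[j], s.origin)
            for d in s.dofs:
                a_w = np.einsum("tij,j->ti", Rc, d.axis)
                axis_w[k] = a_w
                point_w[k] = pc
                qi = q[:, k]
                if d.kind == "rotation":
                    Rc = Rc @ _axis_angle_matrix(d.axis, qi)
                else:
                    pc = pc + a_w * qi[:, None]
                k += 1
            R[i] = Rc
            p[i] = pc
        return FKResult(self, q, R, p, axis_w, point_w, single)


class FKResult:
    """Batched forward-kinematics state: world segment frames and DOF axes."""

    def __init__(self, model, q, R, p, axis_w, point_w, single):
        self.model = model
        self.q = q
        self.R = R  # (S, T, 3, 3)
        self.p = p  # (S, T, 3)
        self.axis_w = axis_w  # (nq, T, 3)
        self.point_w = point_w  # (nq, T, 3)
        self._single = single

    @property
    def n_frames(self) -> int:
        return self.q.shape[0]

    def point(self, segment: str, local: np.ndarray) -> np.ndarray:
        """World position of a point fixed in a segment.  -> (T, 3) or (3,)."""
        i = self.model._seg_index[segment]
        local = np.asarray(local, dtype=float)
        out = self.p[i] + np.einsum("tij,j->ti", self.R[i], local)
        return out[0] if self._single else out

    def _points_batch(self, attachments: list[tuple[str, np.ndarray]]) -> np.ndarray:
        out = np.empty((self.q.shape[0], len(attachments), 3))
        for k, (seg, local) in enumerate(attachments):
            i = self.model._seg_index[seg]
            out[:, k] = self.p[i] + np.einsum("tij,j->ti", self.R[i], local)
        return out

    def marker_positions(self) -> dict[str, np.ndarray]:
        out = {}
        for s in self.model.segments:
            i = self.model._seg_index[s.name]
            for name, local in s.markers.items():
                v = self.p[i] + np.einsum("tij,j->ti", self.R[i], local)
                out[name] = v[0] if self._single else v
        return out

    def keypoint_positions(self) -> dict[str, np.ndarray]:
        out = {}
        for s in self.model.segments:
            i = self.model._seg_index[s.name]
            for name, local in s.keypoints.items():
                v = self.p[i] + np.einsum("tij,j->ti", self.R[i], local)
                out[name] = v[0] if self._single else v
        return out

    def point_jacobian(self, segment: str, local: np.ndarray) -> np.ndarray:
        """d(world point)/dq, analytic.  -> (T, 3, nq) or (3, nq)."""
        m = self.model
        i = m._seg_index[segment]
        T = self.q.shape[0]
        x = self.p[i] + np.einsum("tij,j->ti", self.R[i], np.asarray(local, dtype=float))
        J = np.zeros((T, 3, m.nq))
        for j in np.flatnonzero(m._affects[i]):
            d = m.coordinates[j]
            if d.kind == "rotation":
                J[:, :, j] = _cross(self.axis_w[j], x - self.point_w[j])
            else:
                J[:, :, j] = self.axis_w[j]
        return J[0] if self._single else J


def _axis_angle_matrix(axis: np.ndarray, angle: np.ndarray) -> np.ndarray:
    """Rodrigues rotation matrices for a fixed axis and angles (T,) -> (T,3,3)."""
    angle = np.atleast_1d(angle)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    s = np.sin(angle)[:, None, None]
    c = np.cos(angle)[:, None, None]
    return np.eye(3) + s * K + (1 - c) * (K @ K)


# ---------------------------------------------------------------------------
# Kinematic state propagation (velocities and accelerations, world frame)
# ---------------------------------------------------------------------------

class KinematicState:
    """World-frame velocity/acceleration of every segment for given q, qd, qdd."""

    def __init__(self, model: SkeletalModel, q, qd, qdd=None):
        q = np.atleast_2d(np.asarray(q, dtype=float))
        qd = np.atleast_2d(np.asarray(qd, dtype=float))
        qdd = np.zeros_like(q) if qdd is None else np.atleast_2d(np.asarray(qdd, dtype=float))
        T = q.shape[0]
        S = len(model.segments)
        self.model = model
        self.fk = model.forward_kinematics(q)
        if self.fk._single:
            self.fk._single = False
        self.omega = np.zeros((S, T, 3))
        self.alpha = np.zeros((S, T, 3))
        self.v_origin = np.zeros((S, T, 3))
        self.a_origin = np.zeros((S, T, 3))
        k = 0
        for i, s in enumerate(model.segments):
            if s.parent is None:
                Rc = np.broadcast_to(np.eye(3), (T, 3, 3)).copy()
                pc = np.zeros((T, 3))
                w = np.zeros((T, 3)); al = np.zeros((T, 3))
                v = np.zeros((T, 3)); a = np.zeros((T, 3))
            else:
                j = model._seg_index[s.parent]
                Rc = self.fk.R[j].copy()
                d = np.einsum("tij,j->ti", Rc, s.origin)
                w = self.omega[j].copy(); al = self.alpha[j].copy()
                pc = self.fk.p[j] + d
                v = self.v_origin[j] + _cross(self.omega[j], d)
                a = (self.a_origin[j] + _cross(self.alpha[j], d)
                     + _cross(self.omega[j], _cross(self.omega[j], d)))
            for dof in s.dofs:
                aw = np.einsum("tij,j->ti", Rc, dof.axis)
                qi, qdi, qddi = q[:, k], qd[:, k], qdd[:, k]
                if dof.kind == "rotation":
                    al = al + aw * qddi[:, None] + _cross(w, aw * qdi[:, None])
                    w = w + aw * qdi[:, None]
                    Rc = Rc @ _axis_angle_matrix(dof.axis, qi)
                else:
                    dvec = aw * qi[:, None]
                    a = (a + aw * qddi[:, None] + 2 * _cross(w, aw * qdi[:, None])
                         + _cross(al, dvec) + _cross(w, _cross(w, dvec)))
                    v = v + aw * qdi[:, None] + _cross(w, dvec)
                    pc = pc + dvec
                k += 1
            self.omega[i], self.alpha[i] = w, al
            self.v_origin[i], self.a_origin[i] = v, a

    def point_state(self, segment: str, local) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World (position, velocity, acceleration) of a segment-fixed point."""
        i = self.model._seg_index[segment]
        r = np.einsum("tij,j->ti", self.fk.R[i], np.asarray(local, dtype=float))
        p = self.fk.p[i] + r
        v = self.v_origin[i] + _cross(self.omega[i], r)
        a = (self.a_origin[i] + _cross(self.alpha[i], r)
             + _cross(self.omega[i], _cross(self.omega[i], r)))
        return p, v, a


def inverse_dynamics(model: SkeletalModel, q, qd, qdd,
                     external_forces: list[tuple[str, np.ndarray, np.ndarray]] | None = None,
                     gravity: np.ndarray = GRAVITY,
                     kinematic_state: "KinematicState | None" = None) -> np.ndarray:
    """Net generalized forces required to produce the motion (q, qd, qdd).

    ``external_forces`` is a list of (segment, local application point, world
    force (T,3)).  The returned tau (T, nq) includes the six root residuals:
    a dynamically consistent motion with all applied forces passed in yields
    tau = applied actuator torques (zero at unactuated root coordinates).
    """
    q = np.atleast_2d(np.asarray(q, dtype=float))
    T = q.shape[0]
    ks = kinematic_state if kinematic_state is not None else KinematicState(model, q, qd, qdd)
    fk = ks.fk
    tau = np.zeros((T, model.nq))
    # inertial + gravitational generalized forces via the Jacobian transpose
    for i, s in enumerate(model.segments):
        r = np.einsum("tij,j->ti", fk.R[i], s.com)
        a_c = (ks.a_origin[i] + _cross(ks.alpha[i], r)
               + _cross(ks.omega[i], _cross(ks.omega[i], r)))
        c = fk.p[i] + r
        F = s.mass * (a_c - gravity)
        I_w = np.einsum("tij,j,tkj->tik", fk.R[i], s.inertia, fk.R[i])
        N = (np.einsum("tij,tj->ti", I_w, ks.alpha[i])
             + _cross(ks.omega[i], np.einsum("tij,tj->ti", I_w, ks.omega[i])))
        for j in np.flatnonzero(model._affects[i]):
            d = model.coordinates[j]
            if d.kind == "rotation":
                Jv = _cross(fk.axis_w[j], c - fk.point_w[j])
                tau[:, j] += np.einsum("ti,ti->t", F, Jv) + np.einsum("ti,ti->t", N, fk.axis_w[j])
            else:
                tau[:, j] += np.einsum("ti,ti->t", F, fk.axis_w[j])
    # external forces contribute along -J^T F
    for seg, local, force in external_forces or []:
        i = model._seg_index[seg]
        x = fk.p[i] + np.einsum("tij,j->ti", fk.R[i], np.asarray(local, dtype=float))
        force = np.atleast_2d(np.asarray(force, dtype=float))
        for j in np.flatnonzero(model._affects[i]):
            d = model.coordinates[j]
            if d.kind == "rotation":
                Jv = _cross(fk.axis_w[j], x - fk.point_w[j])
                tau[:, j] -= np.einsum("ti,ti->t", force, Jv)
            else:
                tau[:, j] -= np.einsum("ti,ti->t", force, fk.axis_w[j])
    return tau


def center_of_mass(model: SkeletalModel, q) -> np.ndarray:
    """Whole-body center of mass (T, 3) for configurations q."""
    fk = model.forward_kinematics(np.atleast_2d(q))
    if fk._single:
        fk._single = False
    com = np.zeros((fk.q.shape[0], 3))
    for i, s in enumerate(model.segments):
        com += s.mass * (fk.p[i] + np.einsum("tij,j->ti", fk.R[i], s.com))
    return com / model.total_mass


def mechanical_energy(model: SkeletalModel, q, qd, gravity=GRAVITY) -> tuple[np.ndarray, np.ndarray]:
    """(kinetic, potential) energy time series for a trajectory."""
    ks = KinematicState(model, q, qd)
    fk = ks.fk
    T = ks.fk.q.shape[0]
    ke = np.zeros(T)
    pe = np.zeros(T)
    for i, s in enumerate(model.segments):
        r = np.einsum("tij,j->ti", fk.R[i], s.com)
        v_c = ks.v_origin[i] + _cross(ks.omega[i], r)
        c = fk.p[i] + r
        I_w = np.einsum("tij,j,tkj->tik", fk.R[i], s.inertia, fk.R[i])
        ke += 0.5 * s.mass * np.einsum("ti,ti->t", v_c, v_c)
        ke += 0.5 * np.einsum("ti,tij,tj->t", ks.omega[i], I_w, ks.omega[i])
        pe += -s.mass * np.einsum("ti,i->t", c, gravity)
    return ke, pe


# ---------------------------------------------------------------------------
# Muscle path geometry
# ---------------------------------------------------------------------------

def muscle_tendon_length(model: SkeletalModel, muscle: MuscleTendonUnit, q) -> np.ndarray:
    """Total via-point path length (T,) for configurations q."""
    fk = model.forward_kinematics(np.atleast_2d(q))
    pts = fk._points_batch(muscle.path)  # (T, P, 3)
    return np.linalg.norm(np.diff(pts, axis=1), axis=2).sum(axis=1)


def muscle_moment_arms(model: SkeletalModel, muscle: MuscleTendonUnit, q) -> np.ndarray:
    """Moment arms r = -dL/dq, analytic via point Jacobians.  -> (T, nq)."""
    q2 = np.atleast_2d(np.asarray(q, dtype=float))
    fk = model.forward_kinematics(q2)
    if fk._single:
        fk._single = False
    pts = fk._points_batch(muscle.path)
    jacs = [fk.point_jacobian(seg, local) for seg, local in muscle.path]
    dL = np.zeros((q2.shape[0], model.nq))
    for k in range(len(muscle.path) - 1):
        seg_vec = pts[:, k + 1] - pts[:, k]
        n = np.linalg.norm(seg_vec, axis=1, keepdims=True)
        n = np.where(n < 1e-12, 1.0, n)
        e = seg_vec / n
        dL += np.einsum("ti,tij->tj", e, jacs[k + 1] - jacs[k])
    return -dL


# ---------------------------------------------------------------------------
# Anthropometric scaling
# ---------------------------------------------------------------------------

def scale_model(model: SkeletalModel, neutral_markers, height: float, mass: float):
    """Scale a model to a subject from a neutral standing trial.

    Per-segment uniform scale factors are the ratio of measured to default
    inter-marker distances for each segment's declared scale pair (averaged
    over the trial); segments without a pair inherit the mean factor.  Masses
    are rescaled so segment mass fractions are preserved and sum to ``mass``.
    Returns (scaled model, {segment: factor}).
    """
    from .io import MarkerTrajectorySet  # local import to avoid a cycle

    if isinstance(neutral_markers, MarkerTrajectorySet):
        measured = neutral_markers.positions  # {name: (T,3)}
    else:
        measured = {k: np.atleast_2d(v) for k, v in neutral_markers.items()}
    default_fk = model.forward_kinematics(model.default_pose())
    default_pos = default_fk.marker_positions()

    factors: dict[str, float] = {}
    missing: list[str] = []
    for s in model.segments:
        if s.scale_pair is None:
            continue
        a, b = s.scale_pair
        if a not in measured or b not in measured:
            missing += [m for m in (a, b) if m not in measured]
            continue
        d_meas = float(np.mean(np.linalg.norm(np.asarray(measured[a]) - np.asarray(measured[b]), axis=1)))
        d_def = float(np.linalg.norm(default_pos[a] - default_pos[b]))
        factors[s.name] = d_meas / d_def
    if missing:
        raise ModelError(f"scaling requires markers missing from the neutral trial: {sorted(set(missing))}")
    mean_f = float(np.mean(list(factors.values()))) if factors else 1.0
    for s in model.segments:
        factors.setdefault(s.name, mean_f)

    scaled = model.copy()
    for s in scaled.segments:
        f = factors[s.name]
        s.com = s.com * f
        s.inertia = s.inertia * f ** 2
        s.markers = {k: v * f for k, v in s.markers.items()}
        s.keypoints = {k: v * f for k, v in s.keypoints.items()}
        for child in scaled.segments:
            if child.parent == s.name:
                child.origin = child.origin * f
    for m in scaled.muscles:
        m.path = [(seg, p * factors[seg]) for seg, p in m.path]
        mean_leg = float(np.mean([factors[seg] for seg, _ in m.path]))
        m.optimal_fiber_length *= mean_leg
        m.tendon_slack_length *= mean_leg
    for c in scaled.contact_spheres:
        c.position = c.position * factors[c.segment]
    total0 = scaled.total_mass
    for s in scaled.segments:
        s.mass = s.mass * mass / total0
    scaled.default_height = model.default_height * mean_f
    return scaled, factors


# ---------------------------------------------------------------------------
# Serialization (YAML model files)
# ---------------------------------------------------------------------------

def _arr(x):
    return [float(v) for v in np.asarray(x).ravel()]


def save_model(model: SkeletalModel, path=None) -> str:
    doc = {
        "name": model.name,
        "default_height": float(model.default_height),
        "segments": [
            {
                "name": s.name,
                "parent": s.parent,
                "origin": _arr(s.origin),
                "mass": float(s.mass),
                "com": _arr(s.com),
                "inertia": _arr(s.inertia),
                "dofs": [
                    {"name": d.name, "kind": d.kind, "axis": _arr(d.axis),
                     "bounds": [float(d.bounds[0]), float(d.bounds[1])]}
                    for d in s.dofs
                ],
                "markers": {k: _arr(v) for k, v in s.markers.items()},
                "keypoints": {k: _arr(v) for k, v in s.keypoints.items()},
                "scale_pair": list(s.scale_pair) if s.scale_pair else None,
            }
            for s in model.segments
        ],
        "muscles": [
            {
                "name": m.name,
                "path": [[seg, _arr(p)] for seg, p in m.path],
                "max_isometric_force": float(m.max_isometric_force),
                "optimal_fiber_length": float(m.optimal_fiber_length),
                "tendon_slack_length": float(m.tendon_slack_length),
                "pennation_angle": float(m.pennation_angle),
                "max_contraction_velocity": float(m.max_contraction_velocity),
                "activation_time_constant": float(m.activation_time_constant),
                "deactivation_time_constant": float(m.deactivation_time_constant),
            }
            for m in model.muscles
        ],
        "torque_motors": [
            {"coordinate": t.coordinate, "max_torque": float(t.max_torque),
             "time_constant": float(t.time_constant)}
            for t in model.torque_motors
        ],
        "contact_spheres": [
            {"segment": c.segment, "position": _arr(c.position), "radius": float(c.radius),
             "stiffness": float(c.stiffness), "dissipation": float(c.dissipation),
             "friction": float(c.friction), "smoothing": float(c.smoothing)}
            for c in model.contact_spheres
        ],
    }
    text = yaml.safe_dump(doc, sort_keys=False)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def load_model(source) -> SkeletalModel:
    """Load a model from a YAML path/stream, or by fixture name.

    ``load_model('demo2d')`` and ``load_model('demo3d')`` return the shipped
    fixture models.
    """
    if isinstance(source, str) and source in ("demo2d", "demo3d"):
        return demo2d() if source == "demo2d" else demo3d()
    if isinstance(source, str) and "\n" not in source:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, str):
        doc = yaml.safe_load(io.StringIO(source))
    else:
        doc = yaml.safe_load(source)
    segments = [
        Segment(
            name=sd["name"], parent=sd.get("parent"), origin=sd.get("origin", [0, 0, 0]),
            dofs=[Dof(d["name"], d["kind"], d["axis"], tuple(d.get("bounds", (-np.pi, np.pi))))
                  for d in sd.get("dofs", [])],
            mass=sd.get("mass", 1.0), com=sd.get("com", [0, 0, 0]),
            inertia=sd.get("inertia", [1e-3] * 3),
            markers=sd.get("markers", {}) or {}, keypoints=sd.get("keypoints", {}) or {},
            scale_pair=tuple(sd["scale_pair"]) if sd.get("scale_pair") else None,
        )
        for sd in doc["segments"]
    ]
    muscles = [
        MuscleTendonUnit(
            name=md["name"], path=[(seg, np.asarray(p)) for seg, p in md["path"]],
            max_isometric_force=md["max_isometric_force"],
            optimal_fiber_length=md["optimal_fiber_length"],
            tendon_slack_length=md["tendon_slack_length"],
            pennation_angle=md.get("pennation_angle", 0.0),
            max_contraction_velocity=md.get("max_contraction_velocity", 10.0),
            activation_time_constant=md.get("activation_time_constant", 0.015),
            deactivation_time_constant=md.get("deactivation_time_constant", 0.060),
        )
        for md in doc.get("muscles", [])
    ]
    motors = [TorqueMotor(t["coordinate"], t["max_torque"], t.get("time_constant", 0.035))
              for t in doc.get("torque_motors", [])]
    spheres = [ContactSphere(c["segment"], c["position"], c.get("radius", 0.032),
                             c.get("stiffness", 1.0e6), c.get("dissipation", 2.0),
                             c.get("friction", 0.8), c.get("smoothing", 1e-4))
               for c in doc.get("contact_spheres", [])]
    return SkeletalModel(doc["name"], segments, muscles, motors, spheres,
                         default_height=doc.get("default_height", 1.75))


# ---------------------------------------------------------------------------
# Fixture models
# ---------------------------------------------------------------------------

# the 20-keypoint canon, canonical order
KEYPOINT_CANON = [
    "neck", "mid_hip",
    "r_shoulder", "l_shoulder", "r_hip", "l_hip", "r_knee", "l_knee",
    "r_ankle", "l_ankle", "r_heel", "l_heel", "r_small_toe", "l_small_toe",
    "r_big_toe", "l_big_toe", "r_elbow", "l_elbow", "r_wrist", "l_wrist",
]

BODY_KEYPOINTS = [  # 15 lower-limb and torso inputs of the body submodel
    "mid_hip", "r_shoulder", "l_shoulder", "r_hip", "l_hip", "r_knee", "l_knee",
    "r_ankle", "l_ankle", "r_heel", "l_heel", "r_small_toe", "l_small_toe",
    "r_big_toe", "l_big_toe",
]
ARM_KEYPOINTS = ["neck", "r_shoulder", "l_shoulder", "r_elbow", "l_elbow",
                 "r_wrist", "l_wrist"]  # 7 arm and torso inputs

ARM_MARKERS = ["r_acromion", "l_acromion", "r_elbow_lat", "l_elbow_lat",
               "r_wrist_radial", "l_wrist_radial", "r_wrist_ulnar", "l_wrist_ulnar"]


def _leg_segments(side: str, z: float, thigh_l: float, shank_l: float,
                  foot_h: float, foot_l: float, planar: bool) -> list[Segment]:
    s = side
    hip_dofs = [Dof(f"hip_flexion_{s}", "rotation", [0, 0, 1], (-0.7, 2.2))]
    if not planar:
        hip_dofs += [Dof(f"hip_adduction_{s}", "rotation", [1, 0, 0], (-0.9, 0.9)),
                     Dof(f"hip_rotation_{s}", "rotation", [0, 1, 0], (-0.9, 0.9))]
    ankle_dofs = [Dof(f"ankle_angle_{s}", "rotation", [0, 0, 1], (-0.9, 0.9))]
    if not planar:
        ankle_dofs += [Dof(f"subtalar_angle_{s}", "rotation", [1, 0, 0], (-0.6, 0.6))]
    thigh = Segment(
        f"thigh_{s}", "pelvis", origin=[0.0, -0.07, z], dofs=hip_dofs,
        mass=9.0, com=[0, -0.17, 0], inertia=[0.13, 0.03, 0.13],
        markers={
            f"{s}_thigh_cluster1": [0.05, -0.15, 0.02 * np.sign(z)],
            f"{s}_thigh_cluster2": [0.05, -0.25, 0.04 * np.sign(z)],
            f"{s}_thigh_cluster3": [0.04, -0.32, 0.0],
            f"{s}_knee_lat": [0.0, -thigh_l, 0.05 * np.sign(z)],
            f"{s}_knee_med": [0.0, -thigh_l, -0.05 * np.sign(z)],
        },
        keypoints={f"{s}_knee": [0.0, -thigh_l, 0.0]},
        scale_pair=(f"{s}_thigh_cluster1", f"{s}_knee_lat"),
    )
    shank = Segment(
        f"shank_{s}", f"thigh_{s}", origin=[0.0, -thigh_l, 0.0],
        dofs=[Dof(f"knee_angle_{s}", "rotation", [0, 0, 1], (-2.1, 0.05))],
        mass=3.7, com=[0, -0.18, 0], inertia=[0.05, 0.007, 0.05],
        markers={
            f"{s}_shank_cluster1": [0.04, -0.12, 0.02 * np.sign(z)],
            f"{s}_shank_cluster2": [0.04, -0.22, 0.03 * np.sign(z)],
            f"{s}_shank_cluster3": [0.03, -0.30, 0.0],
            f"{s}_ankle_lat": [0.0, -shank_l, 0.045 * np.sign(z)],
            f"{s}_ankle_med": [0.0, -shank_l, -0.045 * np.sign(z)],
        },
        keypoints={f"{s}_ankle": [0.0, -shank_l, 0.0]},
        scale_pair=(f"{s}_shank_cluster1", f"{s}_ankle_lat"),
    )
    foot = Segment(
        f"foot_{s}", f"shank_{s}", origin=[0.0, -shank_l, 0.0], dofs=ankle_dofs,
        mass=1.2, com=[0.06, -0.04, 0], inertia=[0.002, 0.006, 0.006],
        markers={
            f"{s}_calc": [-0.05, -foot_h + 0.015, 0.0],
            f"{s}_mt1": [foot_l - 0.04, -foot_h + 0.012, -0.025 * np.sign(z)],
            f"{s}_mt5": [foot_l - 0.06, -foot_h + 0.012, 0.035 * np.sign(z)],
            f"{s}_toe": [foot_l + 0.02, -foot_h + 0.01, 0.0],
        },
        keypoints={
            f"{s}_heel": [-0.05, -foot_h + 0.02, 0.0],
            f"{s}_big_toe": [foot_l + 0.01, -foot_h + 0.01, -0.02 * np.sign(z)],
            f"{s}_small_toe": [foot_l - 0.03, -foot_h + 0.01, 0.04 * np.sign(z)],
        },
        scale_pair=(f"{s}_calc", f"{s}_toe"),
    )
    return [thigh, shank, foot]


def _pelvis_torso(planar: bool, lumbar: bool) -> list[Segment]:
    pelvis_dofs = [Dof("pelvis_tx", "translation", [1, 0, 0], (-5.0, 5.0)),
                   Dof("pelvis_ty", "translation", [0, 1, 0], (0.0, 2.5)),
                   Dof("pelvis_tilt", "rotation", [0, 0, 1], (-1.2, 1.2))]
    if not planar:
        pelvis_dofs = [Dof("pelvis_tx", "translation", [1, 0, 0], (-5.0, 5.0)),
                       Dof("pelvis_ty", "translation", [0, 1, 0], (0.0, 2.5)),
                       Dof("pelvis_tz", "translation", [0, 0, 1], (-2.0, 2.0)),
                       Dof("pelvis_tilt", "rotation", [0, 0, 1], (-1.2, 1.2)),
                       Dof("pelvis_list", "rotation", [1, 0, 0], (-1.2, 1.2)),
                       Dof("pelvis_rotation", "rotation", [0, 1, 0], (-3.2, 3.2))]
    pelvis = Segment(
        "pelvis", None, origin=[0, 0, 0], dofs=pelvis_dofs,
        mass=11.8, com=[0, 0, 0], inertia=[0.08, 0.09, 0.07],
        markers={"r_asis": [0.08, 0.02, 0.12], "l_asis": [0.08, 0.02, -0.12],
                 "r_psis": [-0.10, 0.03, 0.05], "l_psis": [-0.10, 0.03, -0.05]},
        keypoints={"mid_hip": [0.0, -0.07, 0.0],
                   "r_hip": [0.0, -0.07, 0.09], "l_hip": [0.0, -0.07, -0.09]},
        scale_pair=("r_asis", "l_asis"),
    )
    torso_dofs = []
    if lumbar:
        torso_dofs = [Dof("lumbar_extension", "rotation", [0, 0, 1], (-1.1, 1.1)),
                      Dof("lumbar_bending", "rotation", [1, 0, 0], (-0.8, 0.8)),
                      Dof("lumbar_rotation", "rotation", [0, 1, 0], (-0.8, 0.8))]
    torso = Segment(
        "torso", "pelvis", origin=[-0.02, 0.10, 0.0], dofs=torso_dofs,
        mass=34.4, com=[0, 0.25, 0], inertia=[1.3, 0.55, 1.4],
        markers={"c7": [-0.06, 0.44, 0.0], "sternum": [0.08, 0.32, 0.0],
                 "t10": [-0.08, 0.20, 0.0]},
        keypoints={
            "neck": [0.0, 0.42, 0.0],
            "r_shoulder": [0.0, 0.40, 0.17], "l_shoulder": [0.0, 0.40, -0.17],
            # rigid, slightly flexed arms fixed to the torso
            "r_elbow": [0.04, 0.12, 0.20], "l_elbow": [0.04, 0.12, -0.20],
            "r_wrist": [0.12, -0.10, 0.21], "l_wrist": [0.12, -0.10, -0.21],
        },
        scale_pair=("c7", "sternum"),
    )
    # 8 arm markers ride on the torso (fixture arms are rigid)
    torso.markers.update({k: np.asarray(v, dtype=float) for k, v in {
        "r_acromion": [-0.01, 0.42, 0.18], "l_acromion": [-0.01, 0.42, -0.18],
        "r_elbow_lat": [0.04, 0.12, 0.235], "l_elbow_lat": [0.04, 0.12, -0.235],
        "r_wrist_radial": [0.13, -0.10, 0.19], "l_wrist_radial": [0.13, -0.10, -0.19],
        "r_wrist_ulnar": [0.11, -0.10, 0.235], "l_wrist_ulnar": [0.11, -0.10, -0.235],
    }.items()})
    return [pelvis, torso]


def _default_muscles(model_segments_exist: bool, thigh_l: float, shank_l: float,
                     foot_h: float) -> list[MuscleTendonUnit]:
    muscles = []
    for s, z in (("r", 0.09), ("l", -0.09)):
        muscles += [
            MuscleTendonUnit(
                f"hip_flexor_{s}", [("pelvis", [0.04, -0.01, z]), (f"thigh_{s}", [0.03, -0.13, 0])],
                max_isometric_force=2500, optimal_fiber_length=0.11, tendon_slack_length=1.0),
            MuscleTendonUnit(
                f"hip_extensor_{s}", [("pelvis", [-0.07, 0.02, z]), (f"thigh_{s}", [-0.03, -0.12, 0])],
                max_isometric_force=3500, optimal_fiber_length=0.12, tendon_slack_length=1.0),
            MuscleTendonUnit(
                f"vasti_{s}", [(f"thigh_{s}", [0.03, -0.20, 0]),
                               (f"thigh_{s}", [0.045, -thigh_l + 0.02, 0]),
                               (f"shank_{s}", [0.04, -0.07, 0])],
                max_isometric_force=6000, optimal_fiber_length=0.10, tendon_slack_length=1.0),
            MuscleTendonUnit(
                f"plantarflexor_{s}", [(f"shank_{s}", [-0.025, -0.12, 0]),
                                       (f"foot_{s}", [-0.055, -foot_h + 0.02, 0])],
                max_isometric_force=5500, optimal_fiber_length=0.06, tendon_slack_length=1.0),
        ]
    return muscles


def _finalize_tendons(model: SkeletalModel):
    """Set tendon slack so fibers sit at optimal length in the default pose."""
    q0 = model.default_pose()
    for m in model.muscles:
        lmt0 = float(muscle_tendon_length(model, m, q0)[0])
        lts = lmt0 - m.optimal_fiber_length * np.cos(m.pennation_angle)
        m.tendon_slack_length = max(lts, 0.3 * m.optimal_fiber_length)


_THIGH_L, _SHANK_L, _FOOT_H, _FOOT_L = 0.42, 0.43, 0.077, 0.18


def demo2d() -> SkeletalModel:
    """Sagittal 9-DOF test model: pelvis (3) + hips + knees + ankles, both legs.

    Carries the full 43-marker / 20-keypoint attachment set, 8 Hill-type
    muscles, reserve torque motors on the leg coordinates, and two contact
    spheres per foot, so the whole pipeline runs on it.
    """
    segs = _pelvis_torso(planar=True, lumbar=False)
    segs += _leg_segments("r", 0.09, _THIGH_L, _SHANK_L, _FOOT_H, _FOOT_L, planar=True)
    segs += _leg_segments("l", -0.09, _THIGH_L, _SHANK_L, _FOOT_H, _FOOT_L, planar=True)
    muscles = _default_muscles(True, _THIGH_L, _SHANK_L, _FOOT_H)
    motors = [TorqueMotor(c, 30.0) for c in
              ["hip_flexion_r", "hip_flexion_l", "knee_angle_r", "knee_angle_l",
               "ankle_angle_r", "ankle_angle_l"]]
    spheres = []
    for s in ("r", "l"):
        spheres += [ContactSphere(f"foot_{s}", [-0.04, -_FOOT_H + 0.032, 0.0]),
                    ContactSphere(f"foot_{s}", [0.14, -_FOOT_H + 0.032, 0.0])]
    m = SkeletalModel("demo2d", segs, muscles, motors, spheres)
    _finalize_tendons(m)
    return m


def demo3d() -> SkeletalModel:
    """21-DOF fixture: 6-DOF pelvis, 3-DOF hips, knees, 2-DOF ankles, 3-DOF lumbar."""
    segs = _pelvis_torso(planar=False, lumbar=True)
    segs += _leg_segments("r", 0.09, _THIGH_L, _SHANK_L, _FOOT_H, _FOOT_L, planar=False)
    segs += _leg_segments("l", -0.09, _THIGH_L, _SHANK_L, _FOOT_H, _FOOT_L, planar=False)
    muscles = _default_muscles(True, _THIGH_L, _SHANK_L, _FOOT_H)
    motors = [TorqueMotor(c, 50.0) for c in
              ["lumbar_extension", "lumbar_bending", "lumbar_rotation"]]
    spheres = []
    for s in ("r", "l"):
        spheres += [ContactSphere(f"foot_{s}", [-0.04, -_FOOT_H + 0.032, 0.0]),
                    ContactSphere(f"foot_{s}", [0.14, -_FOOT_H + 0.032, 0.0])]
    m = SkeletalModel("demo3d", segs, muscles, motors, spheres)
    _finalize_tendons(m)
    return m
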