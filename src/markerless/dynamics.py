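"""Muscle-driven tracking simulation by direct collocation, plus inverse
dynamics helpers, joint-moment extraction, and a static-optimization
cross-check.

The tracking problem minimizes

    J = integral( w1*|a|^2 + w2*|e_tm|^2 + w3*|q_ref - q|^2
                  + w4*|qd_ref - qd|^2 + w5*|qdd_ref - qdd|^2 ) dt
        + penalty terms on the remaining controls,

subject to activation dynamics, implicit skeleton dynamics (inverse-dynamics
residuals must vanish at every collocation point), and smooth compliant
foot-ground contact.  The root (pelvis) coordinates carry no actuator, so a
converged solution is dynamically consistent by construction: ground
reaction forces are whatever the contact model must produce for the pelvis
equations to balance.

Transcription: trapezoidal collocation on a fixed mesh.  States are the
coordinates q, velocities qd, muscle activations a, and torque-motor states;
controls are the coordinate accelerations qdd (implicit dynamics), muscle
excitations e, motor excitations, and heavily penalized reserve torques.
The nonlinear least-squares stage (tracking cost + weighted constraint
residuals) is followed by a feasibility refinement that drives the
constraint residuals to solver precision, so accepted solutions satisfy the
dynamics far below the convergence tolerance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import least_squares

from .contact import contact_force
from .kinematics import CoordinateTrajectory
from .models import KinematicState, SkeletalModel, inverse_dynamics
from .muscles import MusclePolynomial, activation_dynamics, fit_muscle_polynomials, hill_equilibrium

log = logging.getLogger("markerless")

_TAU_SCALE = 100.0  # N*m, nondimensionalization of dynamics residuals


@dataclass
class TrackingWeights:
    """Cost weights of the tracking problem (dimensionless).

    These are configuration, tuned on the fixture models, not constants.
    """

    w1: float = 1.0      # muscle activations
    w2: float = 1.0      # torque-motor excitations
    w3: float = 1000.0   # position tracking
    w4: float = 10.0     # velocity tracking
    w5: float = 1e-3     # acceleration tracking
    wp: float = 1e-2     # penalty on remaining controls (excitations / torques)
    w_reserve: float = 400.0  # penalty on reserve torques
    t0: float | None = None
    tf: float | None = None

    def __post_init__(self):
        if min(self.w1, self.w2, self.w4, self.w5, self.wp, self.w_reserve) < 0 or self.w3 <= 0:
            raise ValueError("weights must be >= 0 and w3 > 0")


@dataclass
class TrackingSettings:
    mesh_hz: float = 50.0          # collocation intervals per second
    actuation: str = "muscle"      # 'muscle' | 'torque'
    tolerance: float = 1e-4        # convergence tolerance (scaled residuals)
    reserve_scale: float = 25.0    # N*m at reserve = 1
    torque_scale: float = 150.0    # N*m at control = 1 (torque mode)
    surrogate_postures: int = 1500
    max_nfev: int = 200
    seed: int = 0


@dataclass
class TrackingSolution:
    times: np.ndarray
    coordinate_names: list[str]
    q: np.ndarray
    qd: np.ndarray
    qdd: np.ndarray
    activations: np.ndarray          # (T, nm)
    excitations: np.ndarray          # (T, nm)
    motor_excitations: np.ndarray    # (T, nt)
    motor_torques: np.ndarray        # (T, nt) N*m
    reserve_torques: np.ndarray      # (T, n_act) N*m
    muscle_names: list[str]
    motor_coordinates: list[str]
    actuated_coordinates: list[str]
    grf: dict[str, np.ndarray]       # foot segment -> (T, 3) N
    cop: dict[str, np.ndarray]       # foot segment -> (T, 3) m
    joint_moments: np.ndarray        # (T, nq) N*m (actuator torques per coordinate)
    cost: float
    cost_breakdown: dict[str, float]
    dynamics_residual: float         # max |N*m| over collocation points
    defect_residual: float
    status: str
    converged: bool


class _Transcription:
    """Trapezoidal transcription with structured residuals and sparse FD Jacobian."""

    def __init__(self, model: SkeletalModel, reference: CoordinateTrajectory,
                 weights: TrackingWeights, settings: TrackingSettings,
                 surrogates: dict[str, MusclePolynomial] | None):
        if reference.qd is None or reference.qdd is None:
            raise ValueError("reference must be filtered and differentiated first")
        self.model = model
        self.w = weights
        self.s = settings
        t0 = weights.t0 if weights.t0 is not None else reference.times[0]
        tf = weights.tf if weights.tf is not None else reference.times[-1]
        N = max(4, int(round((tf - t0) * settings.mesh_hz)))
        self.times = np.linspace(t0, tf, N + 1)
        self.h = (tf - t0) / N
        self.N = N
        nq = model.nq
        # reference interpolated onto the mesh
        self.q_ref = np.column_stack([np.interp(self.times, reference.times, reference.q[:, j])
                                      for j in range(nq)])
        self.qd_ref = np.column_stack([np.interp(self.times, reference.times, reference.qd[:, j])
                                       for j in range(nq)])
        self.qdd_ref = np.column_stack([np.interp(self.times, reference.times, reference.qdd[:, j])
                                        for j in range(nq)])

        # with ground contact, the root (pelvis) is unactuated: its equations
        # must balance through the contact forces alone (dynamic consistency);
        # models without contact (e.g. a pendulum) are actuated everywhere
        if model.contact_spheres:
            root_dofs = [j for j, seg in enumerate(model._dof_segment) if seg == 0]
        else:
            root_dofs = []
        self.actuated = [j for j in range(nq) if j not in root_dofs]
        self.muscle_mode = settings.actuation == "muscle"
        self.muscles = model.muscles if self.muscle_mode else []
        self.motors = model.torque_motors if self.muscle_mode else []
        self.nm = len(self.muscles)
        self.nt = len(self.motors)
        self.nr = len(self.actuated)
        self.motor_idx = [model.coordinate_index(t.coordinate) for t in self.motors]
        if self.muscle_mode:
            self.surr = surrogates or fit_muscle_polynomials(
                model, n_postures=settings.surrogate_postures, max_order=7,
                seed=settings.seed)
        else:
            self.surr = {}
        # per-node block: [q, qd, a, m, qdd, e, etm, r]
        self.off_q = 0
        self.off_qd = nq
        self.off_a = 2 * nq
        self.off_m = 2 * nq + self.nm
        self.off_qdd = 2 * nq + self.nm + self.nt
        self.off_e = 3 * nq + self.nm + self.nt
        self.off_etm = 3 * nq + 2 * self.nm + self.nt
        self.off_r = 3 * nq + 2 * self.nm + 2 * self.nt
        self.B = 3 * nq + 2 * self.nm + 2 * self.nt + self.nr
        self.nz = (N + 1) * self.B

    # -- packing ---------------------------------------------------------------

    def unpack(self, z: np.ndarray) -> dict[str, np.ndarray]:
        blocks = z.reshape(self.N + 1, self.B)
        nq, nm, nt = self.model.nq, self.nm, self.nt
        return {
            "q": blocks[:, self.off_q:self.off_q + nq],
            "qd": blocks[:, self.off_qd:self.off_qd + nq],
            "a": blocks[:, self.off_a:self.off_a + nm],
            "m": blocks[:, self.off_m:self.off_m + nt],
            "qdd": blocks[:, self.off_qdd:self.off_qdd + nq],
            "e": blocks[:, self.off_e:self.off_e + nm],
            "etm": blocks[:, self.off_etm:self.off_etm + nt],
            "r": blocks[:, self.off_r:self.off_r + self.nr],
        }

    def pack(self, **parts) -> np.ndarray:
        blocks = np.zeros((self.N + 1, self.B))
        nq, nm, nt = self.model.nq, self.nm, self.nt
        for key, off, width in (("q", self.off_q, nq), ("qd", self.off_qd, nq),
                                ("a", self.off_a, nm), ("m", self.off_m, nt),
                                ("qdd", self.off_qdd, nq), ("e", self.off_e, nm),
                                ("etm", self.off_etm, nt), ("r", self.off_r, self.nr)):
            if key in parts and width:
                blocks[:, off:off + width] = parts[key]
        return blocks.ravel()

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        nq = self.model.nq
        lo = np.full(self.B, -np.inf)
        hi = np.full(self.B, np.inf)
        blo, bhi = self.model.bounds.T
        lo[self.off_q:self.off_q + nq] = blo - 1e-9
        hi[self.off_q:self.off_q + nq] = bhi + 1e-9
        lo[self.off_qd:self.off_qd + nq], hi[self.off_qd:self.off_qd + nq] = -50, 50
        lo[self.off_qdd:self.off_qdd + nq], hi[self.off_qdd:self.off_qdd + nq] = -2000, 2000
        if self.nm:
            lo[self.off_a:self.off_a + self.nm], hi[self.off_a:self.off_a + self.nm] = 0, 1
            lo[self.off_e:self.off_e + self.nm], hi[self.off_e:self.off_e + self.nm] = 0, 1
        if self.nt:
            lo[self.off_m:self.off_m + self.nt], hi[self.off_m:self.off_m + self.nt] = -1, 1
            lo[self.off_etm:self.off_etm + self.nt], hi[self.off_etm:self.off_etm + self.nt] = -1, 1
        if self.nr:
            lo[self.off_r:self.off_r + self.nr], hi[self.off_r:self.off_r + self.nr] = -4, 4
        return np.tile(lo, self.N + 1), np.tile(hi, self.N + 1)

    # -- physics ---------------------------------------------------------------

    def actuator_torques(self, v: dict[str, np.ndarray]) -> np.ndarray:
        """Muscle + motor + reserve generalized torques at every node (T, nq)."""
        T = v["q"].shape[0]
        tau = np.zeros((T, self.model.nq))
        for i, mu in enumerate(self.muscles):
            poly = self.surr[mu.name]
            lmt = poly.length(v["q"])
            vmt = poly.velocity(v["q"], v["qd"])
            f = hill_equilibrium(v["a"][:, i], lmt, vmt, mu)
            tau += f[:, None] * poly.moment_arms(v["q"])
        for t, j, k in zip(self.motors, self.motor_idx, range(self.nt)):
            tau[:, j] += v["m"][:, k] * t.max_torque
        scale = self.s.torque_scale if not self.muscle_mode else self.s.reserve_scale
        for k, j in enumerate(self.actuated):
            tau[:, j] += v["r"][:, k] * scale
        return tau

    def contact_torques(self, ks: KinematicState) -> tuple[np.ndarray, dict, dict]:
        """Generalized contact torques (T, nq), per-foot GRF, sphere forces."""
        T = ks.fk.q.shape[0]
        tau = np.zeros((T, self.model.nq))
        grf: dict[str, np.ndarray] = {}
        cop_num: dict[str, np.ndarray] = {}
        for sphere in self.model.contact_spheres:
            p, vel, _ = ks.point_state(sphere.segment, sphere.position)
            F = contact_force(p, vel, sphere)
            J = ks.fk.point_jacobian(sphere.segment, sphere.position)
            tau += np.einsum("ti,tij->tj", F, J)
            grf.setdefault(sphere.segment, np.zeros((T, 3)))
            grf[sphere.segment] += F
            cop_num.setdefault(sphere.segment, np.zeros((T, 3)))
            cop_num[sphere.segment] += F[:, 1:2] * p
        cop = {}
        for seg, num in cop_num.items():
            fy = grf[seg][:, 1:2]
            c = np.where(np.abs(fy) > 1e-9, num / np.where(np.abs(fy) > 1e-9, fy, 1.0), np.nan)
            c[:, 1] = 0.0
            cop[seg] = c
        return tau, grf, cop

    def dynamics_residuals(self, v: dict[str, np.ndarray]) -> np.ndarray:
        """Scaled implicit skeleton-dynamics residuals at every node (T, nq)."""
        return self._dynamics_residuals_raw(v)

    def _dynamics_residuals_raw(self, v: dict[str, np.ndarray]) -> np.ndarray:
        ks = KinematicState(self.model, v["q"], v["qd"], v["qdd"])
        tau_net = inverse_dynamics(self.model, v["q"], v["qd"], v["qdd"],
                                   kinematic_state=ks)
        tau_c, _, _ = self.contact_torques(ks)
        tau_a = self.actuator_torques(v)
        return (tau_net - tau_c - tau_a) / _TAU_SCALE

    def activation_defects(self, v: dict[str, np.ndarray]) -> np.ndarray:
        if not self.nm:
            return np.zeros((self.N, 0))
        taus = np.array([[mu.activation_time_constant, mu.deactivation_time_constant]
                         for mu in self.muscles])
        adot = activation_dynamics(v["e"], v["a"], taus[:, 0], taus[:, 1])
        return (v["a"][1:] - v["a"][:-1]
                - 0.5 * self.h * (adot[1:] + adot[:-1])) / self.h

    def linear_defects(self, v: dict[str, np.ndarray]) -> np.ndarray:
        h = self.h
        dq = (v["q"][1:] - v["q"][:-1] - 0.5 * h * (v["qd"][1:] + v["qd"][:-1])) / h
        dqd = (v["qd"][1:] - v["qd"][:-1] - 0.5 * h * (v["qdd"][1:] + v["qdd"][:-1])) / h
        parts = [dq, dqd]
        if self.nt:
            tc = np.array([t.time_constant for t in self.motors])
            mdot = (v["etm"] - v["m"]) / tc
            parts.append((v["m"][1:] - v["m"][:-1] - 0.5 * h * (mdot[1:] + mdot[:-1])) / h)
        return np.concatenate(parts, axis=1)

    def cost_residuals(self, v: dict[str, np.ndarray]) -> np.ndarray:
        w, h = self.w, self.h
        quad = np.full(self.N + 1, h)
        quad[[0, -1]] = h / 2
        sq = np.sqrt(quad)[:, None]
        parts = [
            np.sqrt(w.w3) * sq * (v["q"] - self.q_ref),
            np.sqrt(w.w4) * sq * (v["qd"] - self.qd_ref),
            np.sqrt(w.w5) * sq * (v["qdd"] - self.qdd_ref),
        ]
        if self.nm:
            parts += [np.sqrt(w.w1) * sq * v["a"], np.sqrt(w.wp) * sq * v["e"]]
        if self.nt:
            parts.append(np.sqrt(w.w2) * sq * v["etm"])
        if self.nr:
            wr = w.w_reserve if self.muscle_mode else w.wp
            parts.append(np.sqrt(wr) * sq * v["r"])
        return np.concatenate(parts, axis=1)

    # -- assembled residuals and Jacobian --------------------------------------

    def residuals(self, z: np.ndarray, rho_def: float, rho_dyn: float,
                  feasibility_only: bool = False, anchor: np.ndarray | None = None
                  ) -> np.ndarray:
        v = self.unpack(z)
        dyn = rho_dyn * self.dynamics_residuals(v).ravel()
        defs = rho_def * np.concatenate([self.linear_defects(v).ravel(),
                                         self.activation_defects(v).ravel()])
        if feasibility_only:
            tie = 1e-6 * (z - anchor)
            return np.concatenate([defs, dyn, tie])
        return np.concatenate([self.cost_residuals(v).ravel(), defs, dyn])

    def jacobian(self, z: np.ndarray, rho_def: float, rho_dyn: float,
                 feasibility_only: bool = False, anchor=None) -> sp.csr_matrix:
        """Structured Jacobian: constant rows analytically, nonlinear rows by
        batched finite differences exploiting the per-node block structure."""
        v = self.unpack(z)
        n_cost = 0 if feasibility_only else self.cost_residuals(v).size
        lin = self.linear_defects(v)
        act = self.activation_defects(v)
        # FD of the dynamics rows: each residual depends only on its own node
        # block, so all B perturbations (applied to every node at once) stack
        # into one batched physics evaluation alongside the baseline.
        step = 1e-6
        base = z.reshape(self.N + 1, self.B)
        stacked = np.repeat(base[None, :, :], 2 * self.B, axis=0)
        for i in range(self.B):
            stacked[i, :, i] += step
            stacked[self.B + i, :, i] -= step
        flat = stacked.reshape(-1, self.B)
        v_all = {
            "q": flat[:, self.off_q:self.off_q + self.model.nq],
            "qd": flat[:, self.off_qd:self.off_qd + self.model.nq],
            "a": flat[:, self.off_a:self.off_a + self.nm],
            "m": flat[:, self.off_m:self.off_m + self.nt],
            "qdd": flat[:, self.off_qdd:self.off_qdd + self.model.nq],
            "e": flat[:, self.off_e:self.off_e + self.nm],
            "etm": flat[:, self.off_etm:self.off_etm + self.nt],
            "r": flat[:, self.off_r:self.off_r + self.nr],
        }
        dyn_all = self._dynamics_residuals_raw(v_all).reshape(
            2 * self.B, self.N + 1, self.model.nq)
        blocks_dyn = (dyn_all[:self.B] - dyn_all[self.B:]) / (2 * step)
        rows, cols, vals = [], [], []
        nq, nm, nt, N, B, h = self.model.nq, self.nm, self.nt, self.N, self.B, self.h
        row = 0
        if not feasibility_only:
            # cost rows: diagonal blocks, analytic
            quad = np.full(N + 1, h)
            quad[[0, -1]] = h / 2
            sq = np.sqrt(quad)
            w = self.w
            specs = [(np.sqrt(w.w3), self.off_q, nq), (np.sqrt(w.w4), self.off_qd, nq),
                     (np.sqrt(w.w5), self.off_qdd, nq)]
            if nm:
                specs += [(np.sqrt(w.w1), self.off_a, nm), (np.sqrt(w.wp), self.off_e, nm)]
            if nt:
                specs.append((np.sqrt(w.w2), self.off_etm, nt))
            if self.nr:
                wr = w.w_reserve if self.muscle_mode else w.wp
                specs.append((np.sqrt(wr), self.off_r, self.nr))
            width = sum(wd for _, _, wd in specs)
            for k in range(N + 1):
                c = 0
                for scale, off, wd in specs:
                    for i in range(wd):
                        rows.append(row + k * width + c)
                        cols.append(k * B + off + i)
                        vals.append(scale * sq[k])
                        c += 1
            row += (N + 1) * width
        # linear defects (q, qd, m): analytic, rows per interval
        n_lin = lin.shape[1]
        for k in range(N):
            base = row + k * n_lin
            for j in range(nq):  # q defect row j
                r = base + j
                for (node, off, val) in ((k, self.off_q, -1 / h), (k + 1, self.off_q, 1 / h),
                                         (k, self.off_qd, -0.5), (k + 1, self.off_qd, -0.5)):
                    rows.append(r); cols.append(node * B + off + j); vals.append(rho_def * val)
            for j in range(nq):  # qd defect
                r = base + nq + j
                for (node, off, val) in ((k, self.off_qd, -1 / h), (k + 1, self.off_qd, 1 / h),
                                         (k, self.off_qdd, -0.5), (k + 1, self.off_qdd, -0.5)):
                    rows.append(r); cols.append(node * B + off + j); vals.append(rho_def * val)
            for j in range(nt):  # motor state defect
                r = base + 2 * nq + j
                tc = self.motors[j].time_constant
                for (node, off, val) in ((k, self.off_m, -1 / h - 0.5 / tc * (-1)),
                                         (k + 1, self.off_m, 1 / h + 0.5 / tc),
                                         (k, self.off_etm, -0.5 / tc),
                                         (k + 1, self.off_etm, -0.5 / tc)):
                    rows.append(r); cols.append(node * B + off + j); vals.append(rho_def * val)
        row += N * n_lin
        # activation defects: analytic partials of the smoothed Raasch dynamics
        if nm:
            taus = np.array([[mu.activation_time_constant, mu.deactivation_time_constant]
                             for mu in self.muscles])
            e_arr, a_arr = v["e"], v["a"]
            b = 0.1  # smoothing width, matches activation_dynamics default
            th = np.tanh((e_arr - a_arr) / b)
            s = 0.5 + 0.5 * th
            rate = s / taus[:, 0] + (1 - s) / taus[:, 1]
            ds = 0.5 / b * (1 - th ** 2)
            dadot_de = rate + (e_arr - a_arr) * ds * (1 / taus[:, 0] - 1 / taus[:, 1])
            dadot_da = -dadot_de
            for k in range(N):
                for i in range(nm):
                    r = row + k * nm + i
                    entries = (
                        (k, self.off_a, (-1 / h - 0.5 * dadot_da[k, i])),
                        (k + 1, self.off_a, (1 / h - 0.5 * dadot_da[k + 1, i])),
                        (k, self.off_e, -0.5 * dadot_de[k, i]),
                        (k + 1, self.off_e, -0.5 * dadot_de[k + 1, i]),
                    )
                    for node, off, val in entries:
                        rows.append(r); cols.append(node * B + off + i)
                        vals.append(rho_def * val)
            row += N * nm
        # dynamics rows: diagonal blocks from batched FD
        for i in range(B):
            M = blocks_dyn[i]  # (N+1, nq)
            rr, cc = np.nonzero(np.abs(M) > 1e-14)
            for k, j in zip(rr, cc):
                rows.append(row + k * nq + j)
                cols.append(k * B + i)
                vals.append(rho_dyn * M[k, j])
        row += (N + 1) * nq
        if feasibility_only:
            for i in range(self.nz):
                rows.append(row + i); cols.append(i); vals.append(1e-6)
            row += self.nz
        return sp.csr_matrix((vals, (rows, cols)), shape=(row, self.nz))


def find_static_equilibrium(model: SkeletalModel, q_init: np.ndarray,
                            free: list[str] | None = None,
                            surrogates: dict[str, MusclePolynomial] | None = None,
                            reserve_scale: float = 25.0,
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Find a standing equilibrium near ``q_init``: adjust the free
    coordinates (default: root coordinates), muscle activations, and reserve
    torques so the static dynamics residual vanishes with minimal effort.

    Returns (q_eq, activations, reserve torques in N*m).
    """
    nq = model.nq
    free_idx = ([model.coordinate_index(c) for c in free] if free is not None
                else [j for j, seg in enumerate(model._dof_segment) if seg == 0])
    nm = len(model.muscles)
    if nm and surrogates is None:
        surrogates = fit_muscle_polynomials(model, n_postures=1500, max_order=7)
    actuated = [j for j in range(nq) if j not in
                [i for i, seg in enumerate(model._dof_segment) if seg == 0]]
    nr = len(actuated)
    q_init = np.asarray(q_init, dtype=float)
    zeros = np.zeros((1, nq))

    def resid(x):
        q = q_init.copy()
        q[free_idx] = x[:len(free_idx)]
        a = x[len(free_idx):len(free_idx) + nm]
        r = x[len(free_idx) + nm:]
        ks = KinematicState(model, q[None], zeros, zeros)
        tau = inverse_dynamics(model, q[None], zeros, zeros, kinematic_state=ks)
        for i, mu in enumerate(model.muscles):
            poly = surrogates[mu.name]
            lmt = poly.length(q[None])
            f = hill_equilibrium(a[i], lmt, np.zeros(1), mu)
            tau -= f[:, None] * poly.moment_arms(q[None])
        for k, j in enumerate(actuated):
            tau[0, j] -= r[k] * reserve_scale
        # contact torques
        for sphere in model.contact_spheres:
            p, vel, _ = ks.point_state(sphere.segment, sphere.position)
            F = contact_force(p, vel, sphere)
            J = ks.fk.point_jacobian(sphere.segment, sphere.position)
            tau -= np.einsum("ti,tij->tj", F, J)
        return np.concatenate([tau[0] / _TAU_SCALE * 50.0, 0.05 * a, 0.5 * r])

    x0 = np.concatenate([q_init[free_idx], np.full(nm, 0.05), np.zeros(nr)])
    lo = np.concatenate([model.bounds[free_idx, 0], np.zeros(nm), -np.full(nr, 4)])
    hi = np.concatenate([model.bounds[free_idx, 1], np.ones(nm), np.full(nr, 4)])
    sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400)
    q_eq = q_init.copy()
    q_eq[free_idx] = sol.x[:len(free_idx)]
    a_eq = sol.x[len(free_idx):len(free_idx) + nm]
    r_eq = sol.x[len(free_idx) + nm:] * reserve_scale
    return q_eq, a_eq, r_eq


def _feasibility_polish(tr: _Transcription, z: np.ndarray, lo: np.ndarray,
                        hi: np.ndarray, tol: float, max_iter: int = 25
                        ) -> tuple[np.ndarray, int]:
    """Drive the collocation constraint residuals to solver precision.

    Column-scaled Gauss-Newton steps (sparse LSMR) with backtracking and
    bound clipping; the least-norm step leaves the stage-one optimum nearly
    untouched while restoring exact feasibility.
    """
    from scipy.sparse.linalg import lsmr as sparse_lsmr

    def feas(zz):
        v = tr.unpack(zz)
        return np.concatenate([tr.linear_defects(v).ravel(),
                               tr.activation_defects(v).ravel(),
                               tr.dynamics_residuals(v).ravel()])

    r = feas(z)
    it = 0
    for it in range(1, max_iter + 1):
        if np.abs(r).max() < tol:
            break
        cost0 = 0.5 * r @ r
        J = tr.jacobian(z, 1.0, 1.0, feasibility_only=True)[:len(r)]
        coln = np.sqrt(np.asarray(J.multiply(J).sum(axis=0)).ravel())
        coln[coln < 1e-12] = 1.0
        Dm = sp.diags(1.0 / coln)
        step = Dm @ sparse_lsmr(J @ Dm, -r, damp=1e-8, atol=1e-14, btol=1e-14,
                                maxiter=3000)[0]
        improved = False
        alpha = 1.0
        for _ in range(30):
            z2 = np.clip(z + alpha * step, lo, hi)
            r2 = feas(z2)
            if 0.5 * r2 @ r2 < cost0:
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break
        z, r = z2, r2
    return z, it


def solve_tracking(model: SkeletalModel, reference: CoordinateTrajectory,
                   weights: TrackingWeights | None = None,
                   settings: TrackingSettings | None = None,
                   surrogates: dict[str, MusclePolynomial] | None = None
                   ) -> TrackingSolution:
    """Solve the muscle- (or torque-) driven tracking problem.

    ``reference`` must carry qd and qdd (use ``lowpass_filter`` then
    ``differentiate``).  Raises RuntimeError with diagnostics when the
    constraint residuals cannot be driven below tolerance.
    """
    weights = weights or TrackingWeights()
    settings = settings or TrackingSettings()
    tr = _Transcription(model, reference, weights, settings, surrogates)
    # initial guess from the reference; torques warm-started from inverse dynamics
    v0 = {"q": tr.q_ref.copy(), "qd": tr.qd_ref.copy(), "qdd": tr.qdd_ref.copy(),
          "a": np.full((tr.N + 1, tr.nm), 0.1), "e": np.full((tr.N + 1, tr.nm), 0.1),
          "m": np.zeros((tr.N + 1, tr.nt)), "etm": np.zeros((tr.N + 1, tr.nt)),
          "r": np.zeros((tr.N + 1, tr.nr))}
    ks0 = KinematicState(model, v0["q"], v0["qd"], v0["qdd"])
    tau_net0 = inverse_dynamics(model, v0["q"], v0["qd"], v0["qdd"], kinematic_state=ks0)
    tau_c0, _, _ = tr.contact_torques(ks0)
    resid0 = tau_net0 - tau_c0
    if not tr.muscle_mode:
        scale = settings.torque_scale
        for k, j in enumerate(tr.actuated):
            v0["r"][:, k] = np.clip(resid0[:, j] / scale, -3.9, 3.9)
    else:
        # distribute the required torques over muscles/reserves per node
        # (bounded ridge least squares), so the solver starts near balance
        from scipy.optimize import lsq_linear
        nm, nt, nr = tr.nm, tr.nt, tr.nr
        gains = np.zeros((tr.N + 1, nr, nm))
        passive = np.zeros((tr.N + 1, nr))
        for i, mu in enumerate(tr.muscles):
            poly = tr.surr[mu.name]
            lmt = poly.length(v0["q"])
            vmt = poly.velocity(v0["q"], v0["qd"])
            f1 = hill_equilibrium(1.0, lmt, vmt, mu)
            f0 = hill_equilibrium(0.0, lmt, vmt, mu)
            arms = poly.moment_arms(v0["q"])[:, tr.actuated]
            gains[:, :, i] = (f1 - f0)[:, None] * arms
            passive += f0[:, None] * arms
        motor_map = np.zeros((nr, nt))
        for kk, j in enumerate(tr.motor_idx):
            if j in tr.actuated:
                motor_map[tr.actuated.index(j), kk] = tr.motors[kk].max_torque
        for k in range(tr.N + 1):
            A = np.hstack([gains[k], motor_map, settings.reserve_scale * np.eye(nr)])
            ridge = np.diag(np.concatenate([np.full(nm, 3.0), np.full(nt, 5.0),
                                            np.full(nr, 50.0)]))
            A = np.vstack([A, ridge])
            b = np.concatenate([resid0[k, tr.actuated] - passive[k],
                                np.zeros(nm + nt + nr)])
            ws = lsq_linear(A, b, bounds=(
                np.concatenate([np.zeros(nm), -np.ones(nt), -np.full(nr, 3.9)]),
                np.concatenate([np.ones(nm), np.ones(nt), np.full(nr, 3.9)])))
            v0["a"][k] = ws.x[:nm]
            v0["m"][k] = ws.x[nm:nm + nt]
            v0["r"][k] = ws.x[nm + nt:]
        v0["e"] = v0["a"].copy()
        v0["etm"] = v0["m"].copy()
    z0 = tr.pack(**v0)
    lo, hi = tr.bounds()
    z0 = np.clip(z0, lo, hi)

    rho_def, rho_dyn = 30.0, 30.0
    # variable scaling: balances coordinates, velocities, accelerations, and
    # unit-interval controls for the trust-region subproblems
    xs_block = np.ones(tr.B)
    nq = model.nq
    xs_block[tr.off_q:tr.off_q + nq] = 0.3
    xs_block[tr.off_qd:tr.off_qd + nq] = 3.0
    xs_block[tr.off_qdd:tr.off_qdd + nq] = 30.0
    for off, width in ((tr.off_a, tr.nm), (tr.off_e, tr.nm), (tr.off_m, tr.nt),
                       (tr.off_etm, tr.nt), (tr.off_r, tr.nr)):
        xs_block[off:off + width] = 0.3
    xs = np.tile(xs_block, tr.N + 1)
    lsmr_opts = {"atol": 1e-12, "btol": 1e-12}
    sol = least_squares(
        lambda z: tr.residuals(z, rho_def, rho_dyn),
        z0, jac=lambda z: tr.jacobian(z, rho_def, rho_dyn),
        bounds=(lo, hi), method="trf", tr_solver="lsmr",
        tr_options=lsmr_opts,
        xtol=1e-10, ftol=1e-8, gtol=1e-12, max_nfev=settings.max_nfev)
    # feasibility refinement: column-scaled Gauss-Newton with backtracking
    # drives the constraint residuals to solver precision
    z, polish_iters = _feasibility_polish(tr, sol.x, lo, hi,
                                          tol=settings.tolerance / 10, max_iter=25)
    v = tr.unpack(z)
    dyn = tr.dynamics_residuals(v) * _TAU_SCALE
    defect = np.concatenate([tr.linear_defects(v).ravel(), tr.activation_defects(v).ravel()])
    dyn_max = float(np.abs(dyn).max())
    def_max = float(np.abs(defect).max())
    converged = dyn_max / _TAU_SCALE < settings.tolerance and def_max < settings.tolerance * 10
    status = (f"stage1 {sol.status}/{sol.nfev} evals; polish {polish_iters} iters; "
              f"max dynamics residual {dyn_max:.2e} N*m; max defect {def_max:.2e}")
    if not converged:
        log.warning("tracking solve did not reach tolerance: %s", status)

    ks = KinematicState(model, v["q"], v["qd"], v["qdd"])
    _, grf, cop = tr.contact_torques(ks)
    tau_act = tr.actuator_torques(v)
    cost_parts = {}
    quad = np.full(tr.N + 1, tr.h)
    quad[[0, -1]] = tr.h / 2
    w = weights
    cost_parts["activations"] = float(w.w1 * np.sum(quad[:, None] * v["a"] ** 2))
    cost_parts["motor_excitations"] = float(w.w2 * np.sum(quad[:, None] * v["etm"] ** 2))
    cost_parts["position_tracking"] = float(w.w3 * np.sum(quad[:, None] * (v["q"] - tr.q_ref) ** 2))
    cost_parts["velocity_tracking"] = float(w.w4 * np.sum(quad[:, None] * (v["qd"] - tr.qd_ref) ** 2))
    cost_parts["acceleration_tracking"] = float(w.w5 * np.sum(quad[:, None] * (v["qdd"] - tr.qdd_ref) ** 2))
    cost_parts["control_penalty"] = float(w.wp * np.sum(quad[:, None] * v["e"] ** 2)) if tr.nm else 0.0
    wr = w.w_reserve if tr.muscle_mode else w.wp
    cost_parts["reserve_penalty"] = float(wr * np.sum(quad[:, None] * v["r"] ** 2))
    scale = settings.reserve_scale if tr.muscle_mode else settings.torque_scale
    return TrackingSolution(
        times=tr.times, coordinate_names=list(model.coordinate_names),
        q=v["q"], qd=v["qd"], qdd=v["qdd"],
        activations=v["a"], excitations=v["e"],
        motor_excitations=v["etm"],
        motor_torques=v["m"] * np.array([t.max_torque for t in tr.motors]).reshape(1, -1)
        if tr.nt else np.zeros((tr.N + 1, 0)),
        reserve_torques=v["r"] * scale,
        muscle_names=[m.name for m in tr.muscles],
        motor_coordinates=[t.coordinate for t in tr.motors],
        actuated_coordinates=[model.coordinate_names[j] for j in tr.actuated],
        grf=grf, cop=cop, joint_moments=tau_act,
        cost=float(sum(cost_parts.values())), cost_breakdown=cost_parts,
        dynamics_residual=dyn_max, defect_residual=def_max,
        status=status, converged=converged)


def extract_joint_moments(solution: TrackingSolution, model: SkeletalModel) -> np.ndarray:
    """Per-coordinate actuator moments (muscle + motor + reserve), (T, nq).

    Equal, within solver tolerance, to the inverse dynamics of the solution's
    own kinematics under its own ground reaction forces.
    """
    return solution.joint_moments


def total_grf(solution: TrackingSolution) -> np.ndarray:
    """Summed ground reaction force over all feet, (T, 3) N."""
    return np.sum([g for g in solution.grf.values()], axis=0)


def static_optimization(model: SkeletalModel, q: np.ndarray, qd: np.ndarray,
                        joint_moments: dict[str, np.ndarray],
                        surrogates: dict[str, MusclePolynomial] | None = None,
                        reserve_scale: float = 25.0, reserve_penalty: float = 1e3,
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame muscle redundancy resolution: minimize sum(a^2) subject to
    the moment equality at each listed coordinate and a in [0, 1].

    Returns (activations (T, nm), reserve_flag (T,)) where the flag marks
    frames where a reserve actuator carried > 1 N*m.
    """
    from scipy.optimize import minimize

    surrogates = surrogates or fit_muscle_polynomials(model, n_postures=1500, max_order=7)
    q = np.atleast_2d(q)
    qd = np.atleast_2d(qd)
    T = q.shape[0]
    coords = list(joint_moments.keys())
    cidx = [model.coordinate_index(c) for c in coords]
    nm = len(model.muscles)
    nc = len(coords)
    acts = np.zeros((T, nm))
    flags = np.zeros(T, dtype=bool)
    for t in range(T):
        gains = np.zeros((nc, nm))
        passive = np.zeros(nc)
        for i, mu in enumerate(model.muscles):
            poly = surrogates[mu.name]
            lmt = poly.length(q[t:t + 1])
            vmt = poly.velocity(q[t:t + 1], qd[t:t + 1])
            arms = poly.moment_arms(q[t:t + 1])[0, cidx]
            f1 = hill_equilibrium(1.0, lmt, vmt, mu)[0]
            f0 = hill_equilibrium(0.0, lmt, vmt, mu)[0]
            gains[:, i] = (f1 - f0) * arms
            passive += f0 * arms
        target = np.array([joint_moments[c][t] for c in coords]) - passive

        def objective(x):
            a, r = x[:nm], x[nm:]
            return float(np.sum(a ** 2) + reserve_penalty * np.sum(r ** 2))

        def grad(x):
            return np.concatenate([2 * x[:nm], 2 * reserve_penalty * x[nm:]])

        cons = {"type": "eq",
                "fun": lambda x: gains @ x[:nm] + reserve_scale * x[nm:] - target,
                "jac": lambda x: np.hstack([gains, reserve_scale * np.eye(nc)])}
        x0 = np.concatenate([np.full(nm, 0.2), np.zeros(nc)])
        res = minimize(objective, x0, jac=grad, bounds=[(0, 1)] * nm + [(-10, 10)] * nc,
                       constraints=[cons], method="SLSQP",
                       options={"maxiter": 200, "ftol": 1e-12})
        acts[t] = res.x[:nm]
        achieved = gains @ res.x[:nm] + reserve_scale * res.x[nm:]
        flags[t] = bool(np.any(np.abs(res.x[nm:] * reserve_scale) > 1.0)
                        or not res.success
                        or np.any(np.abs(achieved - target) > 1.0))
    return acts, flags
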