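"""Muscle excitation-activation coupling, Hill-type muscle-tendon mechanics,
and polynomial surrogates of muscle-tendon geometry.

Activation dynamics follow Raasch's first-order coupling with separate
activation and deactivation time constants, blended smoothly (tanh) so the
vector field is differentiable for the optimizer.

The Hill model combines a Gaussian active force-length curve, an
asinh-shaped force-velocity curve (normalized so f_v(0) = 1), and an
exponential passive force-length curve; a rigid tendon is the default, so
fiber kinematics follow algebraically from muscle-tendon length.

Muscle-tendon lengths and moment arms are fit as multivariate polynomials of
the joint coordinates each muscle spans (sampled over the coordinate bounds);
moment arms are the analytic partial derivatives -dL/dq of the fitted length
polynomial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .models import (MuscleTendonUnit, SkeletalModel, muscle_moment_arms,
                     muscle_tendon_length)

# force-length / force-velocity curve constants
_FL_WIDTH = 0.45          # Gaussian active force-length width
_PAS_KPE = 4.0            # passive exponential shape
_PAS_E0 = 0.6             # passive strain at max isometric force
_FV_D2 = 5.0              # force-velocity steepness
_FV_D1 = 1.0 / np.arcsinh(_FV_D2)  # normalizes f_v(-1) = 0, f_v(0) = 1


def activation_dynamics(e, a, tau_act: float = 0.015, tau_deact: float = 0.060,
                        smoothing: float = 0.1):
    """da/dt for excitation e and activation a (both in [0, 1]).

    First-order dynamics with the activation time constant when e > a and the
    deactivation constant when e <= a, blended by a tanh switch of width
    ``smoothing`` for differentiability.
    """
    e = np.asarray(e, dtype=float)
    a = np.asarray(a, dtype=float)
    s = 0.5 + 0.5 * np.tanh((e - a) / smoothing)
    rate = s / tau_act + (1.0 - s) / tau_deact
    return (e - a) * rate


def active_force_length(lm_norm):
    return np.exp(-((np.asarray(lm_norm) - 1.0) ** 2) / _FL_WIDTH)


def passive_force_length(lm_norm):
    return (np.exp(_PAS_KPE * (np.asarray(lm_norm) - 1.0) / _PAS_E0) - 1.0) / (np.exp(_PAS_KPE) - 1.0)


def force_velocity(v_norm):
    """Normalized force-velocity curve; v_norm = fiber velocity / (v_max * l_opt),
    negative when shortening.  f_v(-1) = 0, f_v(0) = 1, monotone increasing."""
    return 1.0 + _FV_D1 * np.arcsinh(_FV_D2 * np.asarray(v_norm))


def hill_equilibrium(a, lmt, vmt, muscle: MuscleTendonUnit):
    """Rigid-tendon Hill mechanics: tendon force (N) for activation ``a``,
    muscle-tendon length ``lmt`` (m) and velocity ``vmt`` (m/s).

    With a rigid tendon the fiber length along the tendon is lmt - l_ts; a
    constant-thickness pennation model maps it to fiber length and the fiber
    velocity follows from vmt.  All inputs broadcast.
    """
    a = np.asarray(a, dtype=float)
    lmt = np.asarray(lmt, dtype=float)
    vmt = np.asarray(vmt, dtype=float)
    w = muscle.optimal_fiber_length * np.sin(muscle.pennation_angle)  # constant thickness
    proj = np.maximum(lmt - muscle.tendon_slack_length, 0.01 * muscle.optimal_fiber_length)
    lm = np.sqrt(proj ** 2 + w ** 2)
    cos_pen = proj / lm
    lm_norm = lm / muscle.optimal_fiber_length
    vm_norm = (vmt * cos_pen) / (muscle.max_contraction_velocity * muscle.optimal_fiber_length)
    f_active = a * active_force_length(lm_norm) * force_velocity(vm_norm)
    f = muscle.max_isometric_force * (f_active + passive_force_length(lm_norm)) * cos_pen
    return f


# ---------------------------------------------------------------------------
# Polynomial surrogates of muscle geometry
# ---------------------------------------------------------------------------

def _monomial_exponents(n_vars: int, max_degree: int) -> np.ndarray:
    """All exponent tuples with total degree <= max_degree.  -> (n_terms, n_vars)."""
    exps = [np.zeros(n_vars, dtype=int)]
    frontier = [np.zeros(n_vars, dtype=int)]
    for _ in range(max_degree):
        nxt = []
        seen = set()
        for e in frontier:
            for j in range(n_vars):
                e2 = e.copy()
                e2[j] += 1
                key = tuple(e2)
                if key not in seen:
                    seen.add(key)
                    nxt.append(e2)
        exps.extend(nxt)
        frontier = nxt
    return np.unique(np.asarray(exps), axis=0)


@dataclass
class MusclePolynomial:
    """Polynomial surrogate L(q_dep) for one muscle's tendon length."""

    muscle_name: str
    dependent: list[int]  # coordinate indices the length depends on
    exponents: np.ndarray  # (n_terms, n_dep)
    coefficients: np.ndarray  # (n_terms,)
    order: int
    heldout_length_rmse: float
    heldout_moment_arm_rmse: float

    def _design(self, qd: np.ndarray) -> np.ndarray:
        # qd: (T, n_dep) -> (T, n_terms)
        return np.prod(qd[:, None, :] ** self.exponents[None, :, :], axis=2)

    def length(self, q: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(q)
        return self._design(q[:, self.dependent]) @ self.coefficients

    def moment_arms(self, q: np.ndarray) -> np.ndarray:
        """r = -dL/dq over the full coordinate vector.  -> (T, nq)."""
        q = np.atleast_2d(q)
        qd = q[:, self.dependent]
        out = np.zeros((q.shape[0], q.shape[1]))
        for j_local, j in enumerate(self.dependent):
            exps = self.exponents.copy()
            pw = exps[:, j_local].astype(float)
            exps[:, j_local] = np.maximum(exps[:, j_local] - 1, 0)
            basis = np.prod(qd[:, None, :] ** exps[None, :, :], axis=2) * pw[None, :]
            out[:, j] = -(basis @ self.coefficients)
        return out

    def velocity(self, q: np.ndarray, qdot: np.ndarray) -> np.ndarray:
        """dL/dt = -r . qdot."""
        return -np.einsum("tj,tj->t", self.moment_arms(np.atleast_2d(q)),
                          np.atleast_2d(qdot))


def _dependent_coordinates(model: SkeletalModel, muscle: MuscleTendonUnit) -> list[int]:
    """Coordinates that change the muscle-tendon length (probed numerically)."""
    q0 = model.default_pose()
    base = muscle_tendon_length(model, muscle, q0)[0]
    deps = []
    for j in range(model.nq):
        lo, hi = model.bounds[j]
        probe = []
        for val in (lo + 0.25 * (hi - lo), lo + 0.75 * (hi - lo)):
            q = q0.copy()
            q[j] = val
            probe.append(muscle_tendon_length(model, muscle, q)[0])
        if max(abs(p - base) for p in probe) > 1e-9:
            deps.append(j)
    return deps


def fit_muscle_polynomials(model: SkeletalModel, n_postures: int = 5000,
                           max_order: int = 9, seed: int = 0,
                           tol: float = 1.0e-3,
                           ) -> dict[str, MusclePolynomial]:
    """Fit per-muscle polynomial surrogates of muscle-tendon geometry.

    Samples ``n_postures`` postures uniformly within the coordinate bounds,
    fits total-degree polynomials of increasing order (up to ``max_order``)
    on an 80% split, and keeps the lowest order whose held-out length and
    moment-arm RMSE drop below ``tol`` (m), else the best order found.
    Rank-deficient fits trigger an order reduction with a warning.
    """
    import logging
    log = logging.getLogger("markerless")
    rng = np.random.default_rng(seed)
    lo, hi = model.bounds.T
    Q = rng.uniform(lo, hi, size=(n_postures, model.nq))
    n_train = int(0.8 * n_postures)
    out: dict[str, MusclePolynomial] = {}
    for muscle in model.muscles:
        deps = _dependent_coordinates(model, muscle)
        if not deps:
            continue
        L = muscle_tendon_length(model, muscle, Q)
        R = muscle_moment_arms(model, muscle, Q)[:, deps]
        best = None
        for order in range(2, max_order + 1):
            exps = _monomial_exponents(len(deps), order)
            if len(exps) > n_train // 2:
                break
            X = np.prod(Q[:n_train, None, deps] ** exps[None, :, :], axis=2)
            coef, _, rank, _ = np.linalg.lstsq(X, L[:n_train], rcond=None)
            if rank < X.shape[1]:
                log.warning("muscle %s: rank-deficient at order %d, keeping lower order",
                            muscle.name, order)
                break
            poly = MusclePolynomial(muscle.name, deps, exps, coef, order, np.inf, np.inf)
            l_hat = poly.length(Q[n_train:])
            r_hat = poly.moment_arms(Q[n_train:])[:, deps]
            l_rmse = float(np.sqrt(np.mean((l_hat - L[n_train:]) ** 2)))
            r_rmse = float(np.sqrt(np.mean((r_hat - R[n_train:]) ** 2)))
            poly.heldout_length_rmse = l_rmse
            poly.heldout_moment_arm_rmse = r_rmse
            if best is None or max(l_rmse, r_rmse) < max(best.heldout_length_rmse,
                                                        best.heldout_moment_arm_rmse):
                best = poly
            if l_rmse < tol and r_rmse < tol:
                break
        out[muscle.name] = best
    return out
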