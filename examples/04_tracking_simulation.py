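"""Muscle-driven standing simulation: ground reaction forces from physics.

Finds a standing equilibrium of the planar fixture model, tracks it with
the muscle-driven collocation solver, and checks that the contact model
supports exactly one bodyweight.
"""
import numpy as np

from markerless import (TrackingSettings, TrackingWeights, demo2d,
                        find_static_equilibrium, solve_tracking, total_grf)
from markerless.kinematics import CoordinateTrajectory, differentiate
from markerless.muscles import fit_muscle_polynomials

model = demo2d()
surr = fit_muscle_polynomials(model, n_postures=1500, max_order=7, seed=0)
q0 = np.zeros(model.nq)
q0[model.coordinate_index("pelvis_ty")] = 0.994
q_eq, a_eq, _ = find_static_equilibrium(model, q0, surrogates=surr)

t = np.arange(0, 1.0, 1 / 60.0)
ref = differentiate(CoordinateTrajectory(list(model.coordinate_names), t,
                                         np.tile(q_eq, (len(t), 1))))
sol = solve_tracking(model, ref, TrackingWeights(),
                     TrackingSettings(mesh_hz=20, max_nfev=60), surrogates=surr)

W = model.total_mass * 9.81
fy = total_grf(sol)[:, 1]
print("converged:", sol.converged,
      "| max dynamics residual: %.1e N*m" % sol.dynamics_residual)
print("vertical GRF / bodyweight: %.4f (should be 1)" % (fy.mean() / W))
print("peak muscle activation: %.3f" % sol.activations.max())
# quiet standing needs only a few percent activation; GRF equals weight
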