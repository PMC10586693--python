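"""Smooth compliant foot-ground contact (Hunt-Crossley type).

The ground is the plane y = 0 with the normal +y.  The normal force is
k * d^1.5 * (1 + c * d_dot) with penetration depth d and penetration rate
d_dot, blended by square-root smoothing so the force and its derivatives
vanish smoothly as the sphere leaves the ground.  Friction is a regularized
Coulomb model opposing tangential slip; everything is differentiable.
"""

from __future__ import annotations

import numpy as np

from .models import ContactSphere

_V_EPS = 0.01  # m/s, tangential-velocity regularization


def _smooth_pos(x, eps):
    """Smooth positive part: 0.5 * (x + sqrt(x^2 + eps^2)) -> max(x, 0)."""
    return 0.5 * (x + np.sqrt(x * x + eps * eps))


def contact_force(position, velocity, sphere: ContactSphere) -> np.ndarray:
    """World-frame force (…, 3) on the body from one contact sphere.

    ``position``/``velocity`` are the world position and velocity of the
    sphere center, shape (3,) or (T, 3).
    """
    p = np.atleast_2d(np.asarray(position, dtype=float))
    v = np.atleast_2d(np.asarray(velocity, dtype=float))
    depth = sphere.radius - p[:, 1]          # penetration, >0 in contact
    depth_rate = -v[:, 1]
    d = _smooth_pos(depth, sphere.smoothing)
    hc = 1.0 + sphere.dissipation * depth_rate
    fn = sphere.stiffness * d ** 1.5 * _smooth_pos(hc, sphere.smoothing)
    vt = v[:, [0, 2]]
    slip = np.sqrt(np.sum(vt ** 2, axis=1) + _V_EPS ** 2)
    ft = -sphere.friction * fn[:, None] * vt / slip[:, None]
    out = np.zeros_like(p)
    out[:, 1] = fn
    out[:, [0, 2]] = ft
    return out[0] if np.asarray(position).ndim == 1 else out


def equilibrium_penetration(sphere: ContactSphere, load: float) -> float:
    """Static penetration depth solving k * d^1.5 = load (N)."""
    return float((load / sphere.stiffness) ** (2.0 / 3.0))
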