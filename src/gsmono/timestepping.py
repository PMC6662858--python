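"""Third-order TVD (Shu-Osher) Runge-Kutta stepping.

One step of the scheme, for state w and right-hand side L:

    w1   = w  + dt L(w)
    w2   = w1 + dt/4 [ -3 L(w) + L(w1) ]
    wnew = w2 + dt/12 [ -L(w) - L(w1) + 8 L(w2) ]

The stage combination (1; -3/4, 1/4; -1/12, -1/12, 8/12) is algebraically
identical to the standard SSPRK3 convex form; for a linear rhs L = lam * w
the amplification factor is 1 + z + z^2/2 + z^3/6 with z = lam * dt.  The
membrane ODE variant freezes the interpolated potential across the three
stages (it is updated once per step, after the potential solve).
"""

from __future__ import annotations

import numpy as np

from .errors import NumericalError

__all__ = ["rk3_step", "rk3_ode_step"]


def _check(stage: str, w) -> None:
    if not np.all(np.isfinite(w)):
        raise NumericalError(f"non-finite values after RK3 stage {stage}")


def rk3_step(rhs, state, dt: float, check: bool = True):
    """Advance ``state`` by one TVD-RK3 step of ``d state/dt = rhs(state)``."""
    L0 = rhs(state)
    w1 = state + dt * L0
    if check:
        _check("1", w1)
    L1 = rhs(w1)
    w2 = w1 + (dt / 4.0) * (-3.0 * L0 + L1)
    if check:
        _check("2", w2)
    L2 = rhs(w2)
    out = w2 + (dt / 12.0) * (-L0 - L1 + 8.0 * L2)
    if check:
        _check("3", out)
    return out


def rk3_ode_step(cell_model, v_tilde: np.ndarray, y: np.ndarray, dt: float,
                 check: bool = True) -> np.ndarray:
    """Advance the per-node membrane states with the potential frozen.

    ``v_tilde`` is the freshly interpolated/projected potential at the nodes
    (held constant over the three stages); ``y`` has shape
    ``(n_nodes, state_dim)``.
    """
    return rk3_step(lambda w: cell_model.rhs(v_tilde, w), y, dt, check=check)
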