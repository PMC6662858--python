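"""Membrane kinetics: the FitzHugh-Nagumo model, the generic cell-model
contract, and a plateau-morphology surrogate ventricular myocyte.

A cell model supplies, at every Lagrangian node, a state vector ``y``, its
right-hand side ``f(V, y)`` and the ionic current ``g(V, y)``.  The solver
advances the Eulerian potential with

    dV/dt = (1/Cm) { (1/Am) div(sigma grad V) - [I_ion + I_s] }

so ``g`` must return the ionic current in the *subtracted* convention: a
negative ``g`` depolarizes.  The classic normalized FitzHugh-Nagumo equations
instead *add* their cubic reaction term; the FHN adapter therefore registers
``current_sign = +1`` and returns the negated cubic, which makes the generic
update reproduce the normalized model exactly when Cm = Am = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "CellModel",
    "FHNParameters",
    "fhn_current",
    "fhn_recovery_rhs",
    "fhn_model",
    "PlateauParameters",
    "surrogate_ventricular_model",
]


@dataclass(frozen=True)
class CellModel:
    """Contract between the solver and a membrane model.

    Attributes
    ----------
    name : str
    state_dim : int
        Number of Lagrangian state variables per node (the potential is not
        part of ``y``; it lives on the Eulerian grid and is interpolated).
    rhs : callable
        ``f(V, y) -> dy/dt`` with ``V`` shape ``(n,)`` and ``y`` shape
        ``(n, state_dim)``.
    current : callable
        ``g(V, y) -> I_ion`` in the subtracted (monodomain) convention.
    initial_state : ndarray, shape (state_dim,)
    rest_potential : float
        Resting transmembrane potential in the model's own units.
    current_sign : int
        +1 if the model's native formulation *adds* its reaction term (so
        ``current`` returns the negated native term), -1 if the native
        formulation already subtracts it.
    observables : dict
        Named accessors ``name -> f(V, y) -> array``; e.g. the intracellular
        calcium concentration for ionic-style models.
    """

    name: str
    state_dim: int
    rhs: Callable[[np.ndarray, np.ndarray], np.ndarray]
    current: Callable[[np.ndarray, np.ndarray], np.ndarray]
    initial_state: np.ndarray
    rest_potential: float = 0.0
    current_sign: int = -1
    observables: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "initial_state",
                           np.atleast_1d(np.asarray(self.initial_state, dtype=float)))
        if self.initial_state.shape != (self.state_dim,):
            raise ValueError("initial_state length must equal state_dim")


# ---------------------------------------------------------------------------
# FitzHugh-Nagumo
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FHNParameters:
    """Dimensionless FitzHugh-Nagumo parameters (benchmark defaults)."""

    a: float = 0.1
    epsilon: float = 0.01
    beta: float = 0.5
    gamma: float = 1.0
    sigma: float = 0.0
    # diffusion coefficients of the normalized model; the solver maps them
    # onto the monodomain conductivities with Cm = Am = 1
    Kx: float = 1e-4
    Ky: float = 1e-4


def fhn_current(u, v, params: FHNParameters = FHNParameters()):
    """Native (added) FHN reaction term  u(1-u)(u-a) - v."""
    return u * (1.0 - u) * (u - params.a) - v


def fhn_recovery_rhs(u, v, params: FHNParameters = FHNParameters()):
    """Recovery kinetics  dv/dt = eps(beta u - gamma v - sigma)."""
    return params.epsilon * (params.beta * u - params.gamma * v - params.sigma)


def fhn_model(params: FHNParameters = FHNParameters()) -> CellModel:
    """FHN wrapped in the generic contract (y = (v,), current negated)."""

    def rhs(u, y):
        return fhn_recovery_rhs(u, y[..., 0], params)[..., None]

    def current(u, y):
        return -fhn_current(u, y[..., 0], params)

    return CellModel(
        name="fhn",
        state_dim=1,
        rhs=rhs,
        current=current,
        initial_state=np.zeros(1),
        rest_potential=0.0,
        current_sign=+1,
    )


# ---------------------------------------------------------------------------
# Surrogate ventricular myocyte
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlateauParameters:
    """Two-gate phenomenological ventricular myocyte with a calcium-like
    observable.

    The voltage kinetics are of the Mitchell-Schaeffer type: a recovery gate
    ``h`` feeds a fast cubic inward current (phase 0), closes during the
    plateau (phase 2) and reopens slowly at rest, which yields an effective
    refractory period.  A third variable ``c`` is a phenomenological
    intracellular-calcium transient whose onset tracks the upstroke.

    Units: mV, ms, uM.  These parameters are design choices of this package
    (the benchmark literature for the ghost-structure scheme uses a detailed
    human ionic model whose equations live in its own reference); they were
    picked to give a recognizable human-ventricle AP morphology — ~110 mV
    amplitude, a few-hundred-ms plateau — with an upstroke slow enough to be
    resolvable on the coarse demo grids.
    """

    v_rest: float = -85.0
    v_amplitude: float = 110.0
    tau_in: float = 1.2       # ms, upstroke (phase 0) time scale
    tau_out: float = 14.0     # ms, repolarization (phase 3) time scale
    tau_open: float = 120.0   # ms, gate recovery at rest
    tau_close: float = 240.0  # ms, gate closure during the plateau
    u_gate: float = 0.13      # dimensionless threshold on (V - v_rest)/amp
    cm: float = 0.01          # uF/mm^2 (1 uF/cm^2), for the current scaling
    ca_base: float = 0.1      # uM diastolic calcium
    ca_amp: float = 1.0       # uM systolic transient amplitude
    tau_ca_on: float = 20.0   # ms transient rise
    tau_ca_off: float = 80.0  # ms transient decay


def _plateau_u(V, p: PlateauParameters):
    return (np.asarray(V, dtype=float) - p.v_rest) / p.v_amplitude


def surrogate_ventricular_model(params: PlateauParameters = PlateauParameters()) -> CellModel:
    """Build the plateau-AP surrogate as a :class:`CellModel`.

    State ``y = (h, c)``: recovery gate and calcium-like concentration.
    ``current`` returns ``-Cm * amp * (h u^2 (1-u)/tau_in - u/tau_out)`` so
    that the generic monodomain update gives the native du/dt reaction term.
    """
    p = params

    def rhs(V, y):
        u = _plateau_u(V, p)
        h = y[..., 0]
        c = y[..., 1]
        dh = np.where(u < p.u_gate, (1.0 - h) / p.tau_open, -h / p.tau_close)
        # calcium: activates smoothly once the cell depolarizes past ~1/3
        s = np.clip((u - 0.3) / 0.1, 0.0, 1.0)
        c_target = p.ca_base + p.ca_amp * s
        tau_c = np.where(c_target > c, p.tau_ca_on, p.tau_ca_off)
        dc = (c_target - c) / tau_c
        return np.stack([dh, dc], axis=-1)

    def current(V, y):
        u = _plateau_u(V, p)
        h = y[..., 0]
        dudt = h * u * u * (1.0 - u) / p.tau_in - u / p.tau_out
        return -p.cm * p.v_amplitude * dudt

    def calcium(V, y):
        return y[..., 1]

    return CellModel(
        name="plateau_surrogate",
        state_dim=2,
        rhs=rhs,
        current=current,
        initial_state=np.array([1.0, p.ca_base]),
        rest_potential=p.v_rest,
        current_sign=-1,
        observables={"calcium": calcium},
    )
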