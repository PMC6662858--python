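"""Ghost-structure monodomain time stepping.

One step advances, in order:

1. (moving structures) the motion map, with the transfer stencils rebuilt;
2. the Lagrangian ionic current at quadrature points — membrane state is
   interpolated node -> quadrature through the P1 basis, the stimulus is
   added where the protocol is active — which is spread to the Eulerian
   ionic-current field;
3. the Eulerian potential by TVD-RK3 of
   dV/dt = (1/Cm){ (1/Am) div(sigma grad V) - [I_ion + I_s] },
   with the reaction either re-evaluated at every RK stage (interpolate ->
   g -> spread, membrane state frozen) or frozen over the whole step;
4. interpolation of the new potential to quadrature points and L^2
   projection to mesh nodes;
5. the membrane ODEs by TVD-RK3 with the nodal potential frozen;
6. the ghost-region refresh: cells farther than the kernel support from the
   structure are reset to the resting potential, leaving a 2-cell halo for
   the PDE so the kernel never reads stale values.

With no randomness anywhere, two runs from the same configuration produce
bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .cells import CellModel
from .errors import ConfigurationError, NumericalError
from .grid import CartesianGrid, ConductivityTensor, laplacian_values
from .mesh import LagrangianMesh, MotionModel, advance_motion, check_refinement
from .timestepping import rk3_ode_step, rk3_step
from .transfer import TransferMaps, _kernel_matrix

__all__ = [
    "Constants", "StimulusProtocol", "SolverOptions", "SimulationState",
    "Simulation", "RunResult", "apply_stimulus", "ventricular_constants",
]


@dataclass(frozen=True)
class Constants:
    """Physical constants of the monodomain update, in consistent units.

    For the dimensionless FitzHugh-Nagumo benchmarks cm = am = 1 and
    sigma_l/sigma_t are the diffusion coefficients (Kx, Ky) directly.
    For ventricular runs use :func:`ventricular_constants`.
    """

    cm: float = 1.0        # membrane capacitance per area
    am: float = 1.0        # surface-to-volume ratio
    sigma_l: float = 1e-4  # effective monodomain conductivity, axis 1
    sigma_t: float = 1e-4  # effective monodomain conductivity, axis 2

    @property
    def diffusion(self) -> tuple[float, float]:
        """(D1, D2) = sigma / (cm * am): the diffusivities seen by the PDE."""
        return (self.sigma_l / (self.cm * self.am),
                self.sigma_t / (self.cm * self.am))


def ventricular_constants(cond: ConductivityTensor, *,
                          cm_uF_per_cm2: float = 1.0,
                          am_per_um: float = 0.24) -> Constants:
    """Convert tissue constants to the internal (mV, ms, mm) unit system.

    This is the single place unit conversions happen:
    S/m == mS/mm (no factor); uF/cm^2 -> uF/mm^2 is 1e-2; um^-1 -> mm^-1 is
    1e3.  The per-direction monodomain conductivity is the harmonic
    combination sigma_i sigma_e / (sigma_i + sigma_e).
    """
    return Constants(
        cm=cm_uF_per_cm2 * 1e-2,
        am=am_per_um * 1e3,
        sigma_l=cond.mono_l,
        sigma_t=cond.mono_t,
    )


@dataclass(frozen=True)
class StimulusProtocol:
    """Stimulus window applied at Lagrangian quadrature points.

    ``quad_mask`` flags the quadrature points of the active region(s);
    ``amplitude`` is *added* to the Lagrangian current I~_s during
    [start, start + duration).  In the monodomain update the bracket
    [I_ion + I_s] is subtracted, so a depolarizing stimulus has negative
    amplitude; :func:`gsmono.geometry.stimulus_protocol` handles the sign.
    """

    quad_mask: np.ndarray
    amplitude: float
    start: float = 0.0
    duration: float = 1.0
    mode: str = "healthy"

    def __post_init__(self):
        if self.duration <= 0:
            raise ConfigurationError("stimulus duration must be > 0")

    def active(self, t: float) -> bool:
        return self.start <= t < self.start + self.duration


def apply_stimulus(quad_values: np.ndarray, protocol: Optional[StimulusProtocol],
                   t: float) -> np.ndarray:
    """Add the protocol's amplitude to the masked quadrature points at time t."""
    if protocol is None or not protocol.active(t):
        return quad_values
    out = quad_values.copy()
    out[protocol.quad_mask] += protocol.amplitude
    return out


@dataclass(frozen=True)
class SolverOptions:
    reaction_mode: str = "per_stage"   # or "frozen"
    ghost_refresh_interval: int = 1    # steps; 0 disables the refresh
    blowup_guard: float = 1e3          # abort when max|V - rest| exceeds this
    lumped_mass: bool = False
    enforce_refinement: bool = True
    refinement_factor: float = 0.5

    def __post_init__(self):
        if self.reaction_mode not in ("per_stage", "frozen"):
            raise ConfigurationError(
                f"reaction_mode must be 'per_stage' or 'frozen', got {self.reaction_mode!r}")


@dataclass
class SimulationState:
    """Coupled Eulerian/Lagrangian state at one time level."""

    t: float
    V: np.ndarray                 # (n1, n2) Eulerian potential
    y: np.ndarray                 # (n_nodes, state_dim) membrane states
    v_tilde_nodes: np.ndarray     # nodal projected potential
    step_index: int = 0


class RunResult:
    """Outputs of :meth:`Simulation.run`."""

    def __init__(self):
        self.snapshot_times: list[float] = []
        self.snapshots: list[np.ndarray] = []
        self.probe_times: list[float] = []
        self.probe_V: list[np.ndarray] = []          # (n_probe,) per step
        self.probe_patches: list[np.ndarray] = []    # (n_probe, 4, 4) per step
        self.probe_observables: dict[str, list[np.ndarray]] = {}
        self.centroid_times: list[float] = []
        self.excitation_centroids: list[np.ndarray] = []
        self.log: list[dict] = []

    def as_arrays(self):
        self.snapshots = [np.asarray(s) for s in self.snapshots]
        self.probe_times = np.asarray(self.probe_times)
        self.probe_V = np.asarray(self.probe_V)
        if self.probe_patches:
            self.probe_patches = np.asarray(self.probe_patches)
        for k in self.probe_observables:
            self.probe_observables[k] = np.asarray(self.probe_observables[k])
        self.centroid_times = np.asarray(self.centroid_times)
        self.excitation_centroids = np.asarray(self.excitation_centroids)
        return self


class Simulation:
    """Orchestrates the ghost-structure step and the run loop."""

    def __init__(self, grid: CartesianGrid, mesh: LagrangianMesh,
                 model: CellModel, constants: Constants, dt: float,
                 stimulus: Optional[StimulusProtocol] = None,
                 motion: Optional[MotionModel] = None,
                 options: SolverOptions = SolverOptions()):
        if dt <= 0:
            raise ConfigurationError("dt must be > 0")
        self.grid = grid
        self.mesh = mesh
        self.model = model
        self.constants = constants
        self.dt = float(dt)
        self.stimulus = stimulus
        self.motion = motion
        self.options = options
        if options.enforce_refinement:
            check_refinement(mesh, grid, options.refinement_factor)
        self.maps = TransferMaps(grid, mesh, lumped_mass=options.lumped_mass)
        self._refresh_reset_mask()
        rest = model.rest_potential
        V0 = np.full(grid.shape, rest)
        y0 = np.tile(model.initial_state, (mesh.n_nodes, 1))
        vt0 = np.full(mesh.n_nodes, rest)
        self.state = SimulationState(t=0.0, V=V0, y=y0, v_tilde_nodes=vt0)
        self._vq_cache: Optional[np.ndarray] = None
        self.rebuilt_last_step = False

    # -- setup --------------------------------------------------------------
    def _refresh_reset_mask(self):
        flat = np.ones(self.grid.n1 * self.grid.n2, dtype=bool)
        flat[self.maps.support_cells] = False
        self._reset_flat = np.flatnonzero(flat)

    def set_initial_potential(self, ic: Callable[[np.ndarray], np.ndarray]) -> None:
        """Initialize V by spreading the IC sampled at quadrature points
        (the L^2-consistent route), with the far ghost region at rest."""
        uq = np.asarray(ic(self.mesh.quad_current), dtype=float)
        V = self.maps.spread(uq)
        V[self._reset_flat] = self.model.rest_potential
        self.state.V = V.reshape(self.grid.shape)
        vq = self.maps.interpolate(self.state.V)
        self.state.v_tilde_nodes = self.maps.project_to_nodes(vq)
        self._vq_cache = vq

    def set_initial_state(self, ic: Callable[[np.ndarray], np.ndarray],
                          component: int = 0) -> None:
        """Initialize one membrane state component from a position function
        sampled at the mesh nodes."""
        self.state.y[:, component] = np.asarray(ic(self.mesh.nodes), dtype=float)

    # -- core step ----------------------------------------------------------
    def _reaction_field(self, vq: np.ndarray, yq: np.ndarray, t: float) -> np.ndarray:
        iq = self.model.current(vq, yq)
        iq = apply_stimulus(iq, self.stimulus, t)
        return self.maps.spread(iq)

    def step(self) -> SimulationState:
        st = self.state
        c = self.constants
        grid = self.grid
        rest = self.model.rest_potential
        dt = self.dt

        # (1) motion + stencil rebuild (last step clipped to the window end)
        self.rebuilt_last_step = False
        if self.motion is not None and self.motion.is_active(st.t):
            dt_m = min(dt, self.motion.t_stop - st.t)
            advance_motion(self.mesh, self.motion, dt_m,
                           box_lo=grid.extent_lo, box_hi=grid.extent_hi)
            self.maps.rebuild()
            self._refresh_reset_mask()
            self._vq_cache = None
            self.rebuilt_last_step = True

        # (2) Lagrangian currents at quadrature points
        yq = self.mesh.basis @ st.y                      # frozen over the step
        Vflat = st.V.ravel()
        if self._vq_cache is None:
            self._vq_cache = self.maps.interpolate(Vflat)

        inv_cm = 1.0 / c.cm
        inv_cmam = 1.0 / (c.cm * c.am)

        if self.options.reaction_mode == "per_stage":
            def L(v):
                lap = laplacian_values(v.reshape(grid.shape), grid,
                                       c.sigma_l, c.sigma_t, boundary_value=rest)
                I = self._reaction_field(self.maps.interpolate(v), yq, st.t)
                return inv_cmam * lap.ravel() - inv_cm * I
        else:  # frozen reaction over the step
            I = self._reaction_field(self._vq_cache, yq, st.t)

            def L(v):
                lap = laplacian_values(v.reshape(grid.shape), grid,
                                       c.sigma_l, c.sigma_t, boundary_value=rest)
                return inv_cmam * lap.ravel() - inv_cm * I

        # (3) potential update
        try:
            Vnew = rk3_step(L, Vflat, dt)
        except NumericalError as exc:
            raise NumericalError(
                f"{exc} (t={st.t:.6g}, step={st.step_index})") from exc

        # (4) new potential at quadrature points, projected to nodes
        vq_new = self.maps.interpolate(Vnew)
        vt_nodes = self.maps.project_to_nodes(vq_new)

        # (5) membrane ODEs with the nodal potential frozen
        y_new = rk3_ode_step(self.model, vt_nodes, st.y, dt)

        # (6) ghost refresh
        k = self.options.ghost_refresh_interval
        if k > 0 and (st.step_index + 1) % k == 0:
            Vnew[self._reset_flat] = rest

        guard = self.options.blowup_guard
        vmax = float(np.max(np.abs(Vnew - rest)))
        if not np.isfinite(vmax) or vmax > guard:
            raise NumericalError(
                f"potential blow-up: max|V - rest| = {vmax:.3g} exceeds guard "
                f"{guard:.3g} at t={st.t + dt:.6g} (step {st.step_index})")

        self._vq_cache = vq_new
        self.state = SimulationState(
            t=st.t + dt, V=Vnew.reshape(grid.shape), y=y_new,
            v_tilde_nodes=vt_nodes, step_index=st.step_index + 1)
        return self.state

    # -- run loop -----------------------------------------------------------
    def _probe_setup(self, probes):
        pos = np.atleast_2d(np.asarray(probes, dtype=float))
        P = _kernel_matrix(self.grid, pos).T.tocsr()  # (n_probes, n_cells)
        # index of nearest mesh node per probe, for observable traces
        nearest = np.array([
            int(np.argmin(np.linalg.norm(self.mesh.nodes - p, axis=1)))
            for p in pos])
        # origin of the 4x4 cell patch straddling each probe
        i0 = np.floor((pos[:, 0] - self.grid.extent_lo[0]) / self.grid.dx1 - 0.5
                      ).astype(int) - 1
        j0 = np.floor((pos[:, 1] - self.grid.extent_lo[1]) / self.grid.dx2 - 0.5
                      ).astype(int) - 1
        return pos, P, nearest, np.c_[i0, j0]

    def run(self, n_steps: int, *, snapshot_interval: int = 0,
            probes=None, record_patches: bool = False,
            centroid_interval: int = 0, centroid_threshold: float = 0.5,
            progress: Optional[Callable[[int, float], None]] = None) -> RunResult:
        """Advance ``n_steps`` steps, recording snapshots/probe traces.

        ``snapshot_interval``/``centroid_interval`` are in steps (0 = off);
        the initial state is always included when enabled.  Probes record the
        interpolated potential (and each cell-model observable at the nearest
        mesh node) every step; with ``record_patches`` the raw 4x4 cell patch
        around each probe is kept for front-timing estimators.
        """
        res = RunResult()
        if probes is not None:
            ppos, P, nearest, patch0 = self._probe_setup(probes)
        if centroid_interval:
            XX, YY = self.grid.meshgrid()

        def record(st: SimulationState, is_last: bool):
            i = st.step_index
            if snapshot_interval and (i % snapshot_interval == 0 or is_last):
                if not res.snapshot_times or res.snapshot_times[-1] != st.t:
                    res.snapshot_times.append(st.t)
                    res.snapshots.append(st.V.copy())
            if probes is not None:
                res.probe_times.append(st.t)
                res.probe_V.append(P @ st.V.ravel())
                for name, fn in self.model.observables.items():
                    res.probe_observables.setdefault(name, []).append(
                        fn(st.v_tilde_nodes[nearest], st.y[nearest]))
                if record_patches:
                    res.probe_patches.append(np.stack([
                        st.V[i0:i0 + 4, j0:j0 + 4] for i0, j0 in patch0]))
            if centroid_interval and i % centroid_interval == 0:
                exc = st.V > centroid_threshold   # absolute threshold
                if np.any(exc):
                    cen = np.array([XX[exc].mean(), YY[exc].mean()])
                else:
                    cen = np.array([np.nan, np.nan])
                res.centroid_times.append(st.t)
                res.excitation_centroids.append(cen)

        record(self.state, n_steps == 0)
        for k in range(n_steps):
            st = self.step()
            record(st, k == n_steps - 1)
            if progress is not None:
                progress(st.step_index, st.t)
            res.log.append({"step": st.step_index, "t": st.t,
                            "max_abs_V": float(np.max(np.abs(st.V))),
                            "maps_rebuilt": self.rebuilt_last_step})
        return res.as_arrays()
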