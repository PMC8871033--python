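"""D3Q19 BGK solver with two populations (double distribution function).

The flow population f_i carries mass and momentum; a second population g_i
carries the dimensionless blood-oxygen content C_b on the convention
C_b = -1 at the venae cavae and C_b = +1 at the pulmonary vein.  Both relax
toward second-order Maxwell equilibria,

    f_i^eq = rho w_i [1 + c.u/cs^2 + (c.u)^2/(2 cs^4) - u^2/(2 cs^2)],
    g_i^eq = rho C_b w_i [ same bracket ],

with no external force term — the flow is driven entirely through the
inlet ports.  Macroscopic fields are moments: rho = sum f_i,
rho u = sum f_i c_i, C_b = (1/rho) sum g_i.  The Chapman-Enskog relations
link relaxation factors to transport coefficients in lattice units:

    mu    = rho cs^2 (1/omega_f - 1/2) dt,
    alpha =     cs^2 (1/omega_g - 1/2) dt.

Walls: half-way bounce-back for f (no-slip), specular-adiabatic reflection
for g (zero flux); both are baked into the gather tables of the
BoundaryMap.  Ports: inlets impose a velocity by replacing the node's flow
populations with f^eq(rho_interior, u_inlet) and pin C_b = +/-1 through
g^eq; outlets are free-flow (zero-gradient copy of the interior node).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels, lattice
from .geometry import BoundaryMap, FLUID

__all__ = [
    "FluidParams",
    "DistributionField",
    "MacroscopicFields",
    "SimulationResult",
    "Simulation",
    "DivergenceError",
    "StabilityError",
    "equilibrium_f",
    "equilibrium_g",
    "moments",
    "collide_stream",
    "apply_ports",
    "run_to_steady",
    "viscosity_from_omega",
    "omega_from_viscosity",
    "diffusivity_from_omega",
    "omega_from_diffusivity",
    "plane_flux",
]

CS2 = lattice.CS2
#: low-Mach stability guard on any nodal speed (lattice units)
MAX_SPEED = 0.1


class StabilityError(ValueError):
    """A requested velocity violates the low-Mach stability guard."""


class DivergenceError(RuntimeError):
    """The simulation produced NaN/overflow or exceeded the speed guard."""


# ----------------------------------------------------------------- parameters

def _check_omega(omega: float, name: str) -> None:
    if not 0.0 < omega < 2.0:
        raise ValueError(f"{name} must lie strictly in (0, 2), got {omega}")


def viscosity_from_omega(omega_f: float, rho: float = 1.0) -> float:
    """Dynamic viscosity mu = rho cs^2 (1/omega_f - 1/2) (lattice units)."""
    _check_omega(omega_f, "omega_f")
    return rho * CS2 * (1.0 / omega_f - 0.5)


def omega_from_viscosity(mu: float, rho: float = 1.0) -> float:
    if mu <= 0:
        raise ValueError("viscosity must be positive")
    return 1.0 / (mu / (rho * CS2) + 0.5)


def diffusivity_from_omega(omega_g: float) -> float:
    """Scalar diffusivity alpha = cs^2 (1/omega_g - 1/2) (lattice units)."""
    _check_omega(omega_g, "omega_g")
    return CS2 * (1.0 / omega_g - 0.5)


def omega_from_diffusivity(alpha: float) -> float:
    if alpha <= 0:
        raise ValueError("diffusivity must be positive")
    return 1.0 / (alpha / CS2 + 0.5)


@dataclass
class FluidParams:
    """Relaxation factors and the physical scales used in post-processing.

    ``temperature`` is the absolute body temperature entering the entropy
    rate (310 K by default); it never feeds back into the flow.
    """

    omega_f: float = 1.0
    omega_g: float = 1.0
    temperature: float = 310.0
    rho0: float = 1.0

    def __post_init__(self) -> None:
        _check_omega(self.omega_f, "omega_f")
        _check_omega(self.omega_g, "omega_g")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def viscosity(self) -> float:
        return viscosity_from_omega(self.omega_f, self.rho0)

    @property
    def kinematic_viscosity(self) -> float:
        return CS2 * (1.0 / self.omega_f - 0.5)

    @property
    def diffusivity(self) -> float:
        return diffusivity_from_omega(self.omega_g)


# ---------------------------------------------------------------- equilibria

def _second_order_bracket(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    speed = np.sqrt((u * u).sum(axis=-1))
    if np.any(speed >= np.sqrt(CS2)):
        raise StabilityError(
            f"|u| = {speed.max():.4f} exceeds the lattice sound speed"
        )
    cu = u @ lattice.C.T.astype(float)           # (..., 19)
    usq = (u * u).sum(axis=-1)[..., None]
    return 1.0 + cu / CS2 + cu * cu / (2 * CS2 * CS2) - usq / (2 * CS2)


def equilibrium_f(rho, u) -> np.ndarray:
    """Second-order Maxwell equilibrium of the flow population."""
    rho = np.asarray(rho, dtype=float)
    return lattice.W * rho[..., None] * _second_order_bracket(u)


def equilibrium_g(rho, cb, u) -> np.ndarray:
    """Scalar equilibrium: the flow bracket scaled by rho C_b."""
    rho = np.asarray(rho, dtype=float)
    cb = np.asarray(cb, dtype=float)
    return lattice.W * (rho * cb)[..., None] * _second_order_bracket(u)


# -------------------------------------------------------------------- fields

@dataclass
class DistributionField:
    """Both populations over the solver's flattened node list."""

    f: np.ndarray       # (Nn, 19)
    g: np.ndarray       # (Nn, 19)

    def copy(self) -> "DistributionField":
        return DistributionField(self.f.copy(), self.g.copy())


@dataclass
class MacroscopicFields:
    """Moments of the populations on the flattened node list."""

    rho: np.ndarray     # (Nn,)
    u: np.ndarray       # (Nn, 3)
    cb: np.ndarray      # (Nn,)
    bmap: BoundaryMap | None = None

    @property
    def speed(self) -> np.ndarray:
        return np.sqrt((self.u * self.u).sum(axis=1))

    def pressure_dimless(self, p_ref: tuple[float, float] | None = None) -> np.ndarray:
        """Map lattice pressure cs^2 rho affinely onto [0, 1].

        With no reference pair the run-wide minimum maps to 0 (diastolic)
        and the maximum to 1 (systolic); a uniform field maps to 0.5.
        """
        p = CS2 * self.rho
        if p_ref is None:
            lo, hi = float(p.min()), float(p.max())
        else:
            lo, hi = p_ref
        if hi - lo < 1e-300:
            return np.full_like(p, 0.5)
        return (p - lo) / (hi - lo)

    def u_grid(self) -> np.ndarray:
        return self.bmap.to_grid(self.u, fill=0.0)

    def cb_grid(self) -> np.ndarray:
        return self.bmap.to_grid(self.cb, fill=0.0)

    def rho_grid(self) -> np.ndarray:
        return self.bmap.to_grid(self.rho, fill=0.0)


def moments(state: DistributionField, bmap: BoundaryMap | None = None) -> MacroscopicFields:
    """rho = sum f_i, rho u = sum f_i c_i, C_b = (1/rho) sum g_i."""
    rho = state.f.sum(axis=1)
    if np.any(rho <= 0) or not np.all(np.isfinite(rho)):
        bad = int(np.argmin(rho))
        raise DivergenceError(f"non-positive or non-finite density at node {bad}")
    u = (state.f @ lattice.C.astype(float)) / rho[:, None]
    cb = state.g.sum(axis=1) / rho
    return MacroscopicFields(rho=rho, u=u, cb=cb, bmap=bmap)


# ------------------------------------------------------------------- stepping

_CX = np.ascontiguousarray(lattice.C[:, 0], dtype=np.float64)
_CY = np.ascontiguousarray(lattice.C[:, 1], dtype=np.float64)
_CZ = np.ascontiguousarray(lattice.C[:, 2], dtype=np.float64)
_W = np.ascontiguousarray(lattice.W)


def collide_stream(state: DistributionField, params: FluidParams,
                   bmap: BoundaryMap) -> DistributionField:
    """One BGK collision plus streaming step (walls included, ports not).

    Collision happens first, then every post-collision value propagates
    along its link — bulk links to the neighbour, wall links by bounce-back
    (f) or specular-adiabatic reflection (g) — in one gather per population.
    """
    f = np.ascontiguousarray(state.f)
    g = np.ascontiguousarray(state.g)
    _kernels.bgk_collide(f, g, _CX, _CY, _CZ, _W,
                         params.omega_f, params.omega_g)
    f_new = np.empty_like(f)
    g_new = np.empty_like(g)
    _kernels.gather(bmap.src_f, f, f_new)
    _kernels.gather(bmap.src_g, g, g_new)
    return DistributionField(f_new, g_new)


def _port_velocity(binding, port_config) -> np.ndarray:
    """Per-voxel inlet velocity (n, 3) from a port's runtime config."""
    cfg = dict(port_config.get(binding.spec.name, {}))
    if "velocity" in cfg:
        vel = np.asarray(cfg["velocity"], dtype=float)
        if vel.shape == (3,):
            vel = np.broadcast_to(vel, (len(binding.nodes), 3)).copy()
        if vel.shape != (len(binding.nodes), 3):
            raise ValueError(
                f"port {binding.spec.name}: velocity must be (3,) or (n, 3)"
            )
    else:
        speed = float(cfg.get("speed", 0.02))
        vel = speed * np.broadcast_to(binding.normal, (len(binding.nodes), 3)).copy()
    if np.sqrt((vel * vel).sum(axis=1)).max() >= MAX_SPEED:
        raise StabilityError(
            f"port {binding.spec.name}: inlet speed must stay below {MAX_SPEED}"
        )
    return vel


def apply_ports(state: DistributionField, bmap: BoundaryMap,
                port_config: dict | None = None,
                rho0: float = 1.0) -> DistributionField:
    """Impose inlet velocities and free-flow outlets (in place).

    Inlets: f <- f^eq(rho_interior, u_inlet); the scalar is pinned to the
    port's oxygen class (g <- g^eq(rho, +/-1, u)) or copied for class
    'free'.  Outlets: zero-gradient copy of the interior neighbour for
    both populations.
    """
    port_config = port_config or {}
    for binding in bmap.ports.values():
        q = binding.interior
        p = binding.nodes
        cfg = port_config.get(binding.spec.name, {})
        if binding.spec.role == "inlet":
            if "density" in cfg:
                # pressure inlet: fixed density, zero-gradient velocity —
                # the flow rate through the port is an outcome, not an input
                rho_in = np.full(len(p), float(cfg["density"]))
                rho_q = state.f[q].sum(axis=1)
                vel = (state.f[q] @ lattice.C.astype(float)) / rho_q[:, None]
                if np.sqrt((vel * vel).sum(axis=1)).max() >= MAX_SPEED:
                    raise StabilityError(
                        f"port {binding.spec.name}: extrapolated inlet speed "
                        f"reached the {MAX_SPEED} guard"
                    )
            else:
                # velocity inlet: imposed profile, density from the interior
                rho_in = state.f[q].sum(axis=1)
                vel = _port_velocity(binding, port_config)
            state.f[p] = equilibrium_f(rho_in, vel)
            cbv = binding.spec.cb_value
            if cbv is None:
                state.g[p] = state.g[q]
            else:
                state.g[p] = equilibrium_g(rho_in, np.full(len(p), cbv), vel)
        else:
            # free-flow outlet: zero-gradient velocity and non-equilibrium
            # part, density anchored at rho0.  A plain population copy
            # leaves the pressure level of the whole system floating, so
            # mass drifts without bound; the anchor makes the outlet the
            # pressure reference while the residual inlet/outlet imbalance
            # stays visible in the diagnostics.
            rho_q = state.f[q].sum(axis=1)
            u_q = (state.f[q] @ lattice.C.astype(float)) / rho_q[:, None]
            feq_q = equilibrium_f(rho_q, u_q)
            state.f[p] = equilibrium_f(np.full(len(p), rho0), u_q) + (
                state.f[q] - feq_q)
            state.g[p] = state.g[q]
    return state


# ----------------------------------------------------------------- simulation

@dataclass
class SimulationResult:
    """Bundle of a finished (or aborted) run."""

    fields: MacroscopicFields
    state: DistributionField
    params: FluidParams
    steps: int
    converged: bool
    history: list[tuple[int, float]]
    diagnostics: dict
    bmap: BoundaryMap


class Simulation:
    """Stateful wrapper: populations + geometry + parameters.

    The step order is fixed (collide -> wall reflections -> stream -> port
    update) so that conservation diagnostics are bit-reproducible.
    """

    def __init__(self, bmap: BoundaryMap, params: FluidParams,
                 port_config: dict | None = None):
        self.bmap = bmap
        self.params = params
        self.port_config = port_config or {}
        # fail fast on bad port config
        for binding in bmap.ports.values():
            cfg = self.port_config.get(binding.spec.name, {})
            if binding.spec.role == "inlet" and "density" not in cfg:
                _port_velocity(binding, self.port_config)
        self.state = DistributionField(
            f=np.tile(lattice.W, (bmap.n_nodes, 1)),
            g=np.zeros((bmap.n_nodes, 19)),
        )
        self.step_count = 0

    def set_state(self, rho=1.0, u=(0.0, 0.0, 0.0), cb=0.0) -> None:
        """Initialize both populations at equilibrium for given fields
        (scalars broadcast over nodes)."""
        n = self.bmap.n_nodes
        rho = np.broadcast_to(np.asarray(rho, dtype=float), (n,))
        u = np.broadcast_to(np.asarray(u, dtype=float), (n, 3))
        cb = np.broadcast_to(np.asarray(cb, dtype=float), (n,))
        self.state = DistributionField(
            f=equilibrium_f(rho, u), g=equilibrium_g(rho, cb, u))
        self.step_count = 0

    def step(self, n_steps: int = 1, check_every: int = 50) -> None:
        for _ in range(n_steps):
            self.state = collide_stream(self.state, self.params, self.bmap)
            apply_ports(self.state, self.bmap, self.port_config,
                        rho0=self.params.rho0)
            self.step_count += 1
            if check_every and self.step_count % check_every == 0:
                self._guard()

    def _guard(self) -> None:
        f = self.state.f
        if not np.all(np.isfinite(f)):
            bad = int(np.argwhere(~np.isfinite(f))[0, 0])
            raise DivergenceError(
                f"non-finite population at node {bad} after step {self.step_count}"
            )
        mac = moments(self.state, self.bmap)
        vmax = mac.speed.max()
        if vmax >= MAX_SPEED:
            bad = int(np.argmax(mac.speed))
            raise DivergenceError(
                f"speed {vmax:.3f} >= {MAX_SPEED} at node {bad} "
                f"after step {self.step_count} (under-resolved or unstable run)"
            )

    def macroscopic(self) -> MacroscopicFields:
        return moments(self.state, self.bmap)

    # -- diagnostics ---------------------------------------------------------

    def total_mass(self) -> float:
        return float(self.state.f.sum())

    def total_scalar_mass(self) -> float:
        return float(self.state.g.sum())

    def port_fluxes(self) -> dict[str, float]:
        """Mass flux through each port, positive into the domain."""
        mac = moments(self.state, self.bmap)
        out = {}
        for name, b in self.bmap.ports.items():
            un = mac.u[b.nodes] @ b.normal
            out[name] = float((mac.rho[b.nodes] * un).sum())
        return out

    def run_to_steady(self, max_steps: int = 20000, conv_tol: float = 1e-4,
                      window: int = 100) -> SimulationResult:
        """Iterate until the relative L2 change of u over ``window`` steps
        drops below ``conv_tol`` (or ``max_steps`` is reached)."""
        mass0 = self.total_mass()
        smass0 = self.total_scalar_mass()
        mac_prev = moments(self.state, self.bmap)
        history: list[tuple[int, float]] = []
        converged = False
        while self.step_count < max_steps:
            todo = min(window, max_steps - self.step_count)
            self.step(todo)
            mac_now = moments(self.state, self.bmap)
            rel_u = (np.linalg.norm(mac_now.u - mac_prev.u)
                     / (np.linalg.norm(mac_now.u) + 1e-300))
            rel_cb = (np.linalg.norm(mac_now.cb - mac_prev.cb)
                      / (np.linalg.norm(mac_now.cb) + 1e-300))
            rel = max(rel_u, rel_cb)
            history.append((self.step_count, rel))
            mac_prev = mac_now
            if todo == window and rel < conv_tol:
                converged = True
                break
        mac = moments(self.state, self.bmap)
        fluxes = self.port_fluxes()
        inflow = sum(v for v in fluxes.values() if v > 0)
        outflow = -sum(v for v in fluxes.values() if v < 0)
        diagnostics = {
            "mass_initial": mass0,
            "mass_final": self.total_mass(),
            "scalar_mass_initial": smass0,
            "scalar_mass_final": self.total_scalar_mass(),
            "port_fluxes": fluxes,
            "flux_imbalance": inflow - outflow,
            "max_speed": float(mac.speed.max()),
            "cb_overshoot": float(max(mac.cb.max() - 1.0, -1.0 - mac.cb.min(), 0.0)),
        }
        return SimulationResult(
            fields=mac, state=self.state, params=self.params,
            steps=self.step_count, converged=converged,
            history=history, diagnostics=diagnostics, bmap=self.bmap,
        )


def run_to_steady(bmap: BoundaryMap, params: FluidParams,
                  port_config: dict | None = None,
                  max_steps: int = 20000, conv_tol: float = 1e-4,
                  initial_cb: float = 0.0) -> SimulationResult:
    """Convenience wrapper: quiescent equilibrium start, then iterate."""
    sim = Simulation(bmap, params, port_config)
    sim.set_state(rho=params.rho0, cb=initial_cb)
    return sim.run_to_steady(max_steps=max_steps, conv_tol=conv_tol)


def plane_flux(result: SimulationResult, axis: int, index: int) -> dict[str, float]:
    """Mass and scalar fluxes through the voxel plane pos[axis] == index
    (fluid nodes only; an all-solid plane gives exactly zero)."""
    bmap = result.bmap
    sel = bmap.positions[:, axis] == index
    sel &= bmap.labels_flat == FLUID
    mac = result.fields
    un = mac.u[sel, axis]
    return {
        "mass_flux": float((mac.rho[sel] * un).sum()),
        "scalar_flux": float((mac.rho[sel] * mac.cb[sel] * un).sum()),
        "n_fluid": int(sel.sum()),
    }
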