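"""Pulsatile laminar incompressible Newtonian flow on labeled simplex meshes.

The transient solver is an incremental pressure-correction (projection)
scheme on equal-order P1 elements: semi-implicit viscous step with
Adams-Bashforth convection, a pressure-Poisson update with the outlet
pressure waveform imposed as a Dirichlet value (so reported pressures are
anchored to the outlet signal), and a divergence-free velocity correction.
No-slip walls and the inlet velocity are enforced strongly, so wall-node
velocities are exactly zero.

High-Reynolds arch runs on deliberately coarse meshes are stabilized with a
grid-Peclet-limiting artificial viscosity nu_a = c·h·U_ref per cell, folded
into the (constant) implicit viscous operator; the verification problems
(Poiseuille, oscillatory channel) run with c = 0 because they are smooth and
convection-free.  The steady solver reuses the same scheme as pseudo-time
continuation marched to stationarity, so one validated discretization serves
both modes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import fem
from .meshing import LabeledMesh


class SolverError(RuntimeError):
    """Divergence of the time stepping or of the nonlinear iteration."""

    def __init__(self, message, step=None, residual_history=None):
        super().__init__(message)
        self.step = step
        self.residual_history = residual_history or []


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian blood analog: rho = 1060 kg/m^3, mu = 3.5 mPa·s."""

    density: float = 1060.0
    dynamic_viscosity: float = 0.0035

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be strictly positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class SolverConfig:
    time_step: float = 0.002          # s, fixed
    n_cycles: int = 2                 # simulate n, analyze the last
    save_stride: int = 5              # snapshot every k-th step of final cycle
    inlet_profile: str = "plug"       # plug | parabolic
    nonlinear_tolerance: float = 0.005
    max_step: float = 0.05            # s, hard cap on the step size
    stabilization: float = 0.0        # upwind factor c in nu_a = c h U_ref
    reference_velocity: float = 1.06  # m/s, systolic peak of the inlet signal
    period: float = 1.0               # s

    def __post_init__(self):
        if self.time_step > self.max_step:
            raise ValueError("time_step exceeds max_step")
        if self.n_cycles < 2:
            raise ValueError("need at least two cycles (first is transient)")
        if not (0 < self.nonlinear_tolerance < 1):
            raise ValueError("nonlinear_tolerance must lie in (0, 1)")
        if self.inlet_profile not in ("plug", "parabolic"):
            raise ValueError("inlet_profile must be plug or parabolic")


@dataclass
class FlowField:
    """Velocity/pressure snapshots over (exactly) the analyzed final cycle."""

    times: np.ndarray        # (S,) s, strictly increasing
    velocities: np.ndarray   # (S, N, d) m/s
    pressures: np.ndarray    # (S, N) Pa
    period: float = 1.0
    diagnostics: dict = field(default_factory=dict)


def womersley_number(radius: float, period: float, props: FluidProperties) -> float:
    """alpha = R sqrt(omega rho / mu) with omega = 2 pi / period."""
    if radius < 0 or period <= 0:
        raise ValueError("radius must be >= 0 and period > 0")
    return radius * math.sqrt(2 * math.pi / period
                              * props.density / props.dynamic_viscosity)


# ---------------------------------------------------------------------------
# boundary helpers


def _pressure_in_pa(outlet, t):
    """Outlet waveform value in Pa; mmHg signals are converted."""
    val = float(outlet(t))
    if getattr(outlet, "units", "Pa") == "mmHg":
        from .waveforms import MMHG_TO_PA
        val *= MMHG_TO_PA
    return val


def inlet_profile_vector(mesh: LabeledMesh, profile: str):
    """Unit-mean inlet velocity field (N, d), zero away from the inlet.

    The profile is normalized so its flux equals the inlet area: multiplying
    by a mean velocity v(t) then gives exactly the flux v(t)·A.  Plug keeps a
    blunt core (rim nodes are no-slip); parabolic is 2(1 - r^2/R^2)-shaped.
    """
    idx = mesh.facets_where("inlet")
    if len(idx) == 0:
        return None, np.empty(0, dtype=np.int64)
    facets = mesh.boundary_facets[idx]
    areas = mesh.facet_areas[idx]
    normals = mesh.facet_normals[idx]
    n_in = -(normals * areas[:, None]).sum(axis=0)
    n_in /= np.linalg.norm(n_in)

    nodes_in = np.unique(facets)
    wall_nodes = np.unique(mesh.boundary_facets[mesh.facets_where("wall")])
    rim = np.isin(nodes_in, wall_nodes)

    g = np.ones(len(nodes_in))
    if profile == "parabolic":
        pts = mesh.nodes[nodes_in]
        center = pts.mean(axis=0)
        r = np.linalg.norm(pts - center, axis=1)
        R = r.max() if r.max() > 0 else 1.0
        g = np.clip(1.0 - (r / R) ** 2, 0.0, None)
    g[rim] = 0.0

    u = np.zeros((mesh.nodes.shape[0], mesh.dim))
    u[nodes_in] = g[:, None] * n_in
    flux = -fem.facet_flux(u, facets, areas, normals)  # inward positive
    u *= areas.sum() / flux
    return u, nodes_in


def _outlet_nodes(mesh: LabeledMesh):
    sets = [mesh.nodes_of_tag(f"outlet:{n}") for n in mesh.outlet_names()]
    return np.unique(np.concatenate(sets)) if sets else np.empty(0, dtype=np.int64)


# ---------------------------------------------------------------------------
# projection stepper (shared by the transient and steady drivers)


class _ProjectionStepper:
    """One incremental pressure-correction step; matrices factorized once."""

    def __init__(self, mesh: LabeledMesh, inlet, outlet,
                 props: FluidProperties, cfg: SolverConfig, body_force=None):
        d = mesh.dim
        rho, mu = props.density, props.dynamic_viscosity
        dt = cfg.time_step
        nodes, cells = mesh.nodes, mesh.cells
        vols, grads = fem.cell_geometry(nodes, cells)
        self.geo = (nodes, cells, vols, grads)
        self.ml = fem.lumped_mass(nodes, cells, vols)
        self.h_cell = (vols * math.factorial(d)) ** (1.0 / d)

        coeff = np.full(len(cells), mu)
        if cfg.stabilization > 0:
            coeff = mu + rho * cfg.stabilization * self.h_cell \
                * cfg.reference_velocity
        K = fem.stiffness_matrix(nodes, cells, vols, grads, coeff=coeff)
        A_v = sp.diags(rho * self.ml / dt) + K

        self.profile, inlet_nodes = inlet_profile_vector(mesh, cfg.inlet_profile)
        self.wall_nodes = np.unique(
            mesh.boundary_facets[mesh.facets_where("wall")])
        self.vfixed = np.unique(np.concatenate([self.wall_nodes, inlet_nodes]))
        self._wall_in_fixed = np.isin(self.vfixed, self.wall_nodes)
        self.sys_v = fem.DirichletSystem(A_v.tocsr(), self.vfixed)

        A_p = fem.stiffness_matrix(nodes, cells, vols, grads)
        self.pfixed = _outlet_nodes(mesh)
        if len(self.pfixed) == 0:
            raise SolverError("mesh has no outlet facets to anchor the pressure")
        self.sys_p = fem.DirichletSystem(A_p, self.pfixed)

        self.inlet = inlet
        self.outlet = outlet
        self.body_force = body_force
        self.rho, self.dt, self.d = rho, dt, d
        self.conv_prev = None
        self.p_out_old = _pressure_in_pa(outlet, 0.0)

    def inlet_bc(self, t):
        vals = np.zeros((len(self.vfixed), self.d))
        if self.profile is not None and self.inlet is not None:
            vals += float(self.inlet(t)) * self.profile[self.vfixed]
            vals[self._wall_in_fixed] = 0.0
        return vals

    def step(self, t_new, u, p):
        nodes, cells, vols, grads = self.geo
        rho, dt = self.rho, self.dt
        conv = fem.convection_rhs(nodes, cells, vols, grads, u)
        conv_ab = conv if self.conv_prev is None \
            else 1.5 * conv - 0.5 * self.conv_prev
        self.conv_prev = conv

        b = (rho / dt) * self.ml[:, None] * u - rho * conv_ab \
            - fem.gradient_rhs(nodes, cells, vols, grads, p)
        if self.body_force is not None:
            f = np.asarray(self.body_force(t_new), dtype=float)
            b += self.ml[:, None] * f[None, :]

        u_star = self.sys_v.solve(b, self.inlet_bc(t_new))

        p_out_new = _pressure_in_pa(self.outlet, t_new)
        b_p = -(rho / dt) * fem.divergence_rhs(nodes, cells, vols, grads, u_star)
        phi = self.sys_p.solve(
            b_p, np.full(len(self.pfixed), p_out_new - self.p_out_old))
        self.p_out_old = p_out_new

        u_new = u_star - (dt / rho) * fem.gradient_rhs(
            nodes, cells, vols, grads, phi) / self.ml[:, None]
        u_new[self.vfixed] = self.inlet_bc(t_new)
        return u_new, p + phi

    def cfl(self, u):
        nodes, cells, vols, grads = self.geo
        speed = np.linalg.norm(u[cells].mean(axis=1), axis=1)
        return float((speed * self.dt / self.h_cell).max())


# ---------------------------------------------------------------------------
# transient driver


def solve_pulsatile(mesh: LabeledMesh, inlet, outlet, props: FluidProperties,
                    cfg: SolverConfig, body_force=None) -> FlowField:
    """March ``cfg.n_cycles`` cardiac cycles and return the final one.

    ``inlet`` is the mean-velocity waveform in m/s (may be None for purely
    pressure/body-force driven verification runs); ``outlet`` the pressure
    waveform (mmHg waveforms are converted to Pa); ``body_force`` an optional
    callable t -> (d,) uniform force density in N/m^3.  Earlier cycles are
    discarded as transient; wall-node velocities of the returned field are
    exactly zero.
    """
    dt = cfg.time_step
    stepper = _ProjectionStepper(mesh, inlet, outlet, props, cfg, body_force)
    n = mesh.nodes.shape[0]
    u = np.zeros((n, mesh.dim))
    p = np.full(n, _pressure_in_pa(outlet, 0.0))

    spc = int(round(cfg.period / dt))
    total = spc * cfg.n_cycles
    save_from = spc * (cfg.n_cycles - 1)
    snaps_t, snaps_u, snaps_p = [], [], []
    max_cfl = 0.0

    for step in range(1, total + 1):
        t_new = step * dt
        u, p = stepper.step(t_new, u, p)
        if not np.isfinite(u).all():
            raise SolverError(
                f"time stepping diverged at step {step} (t={t_new:.4f}s)",
                step=step)
        if step % 25 == 0 or step == total:
            max_cfl = max(max_cfl, stepper.cfl(u))
        if step > save_from and (step - save_from) % cfg.save_stride == 0:
            snaps_t.append(t_new - save_from * dt)
            snaps_u.append(u.copy())
            snaps_p.append(p.copy())

    diagnostics = {"max_cfl": max_cfl,
                   "cfl_warning": max_cfl > 5.0,
                   "steps": total,
                   "dofs": n}
    return FlowField(times=np.array(snaps_t), velocities=np.array(snaps_u),
                     pressures=np.array(snaps_p), period=cfg.period,
                     diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# steady solver (pseudo-transient continuation)


def solve_steady(mesh: LabeledMesh, inflow_rate: float, props: FluidProperties,
                 profile: str = "parabolic", tol: float = 1e-8,
                 time_step: float | None = None, max_time: float = 60.0,
                 stabilization: float = 0.0) -> FlowField:
    """Steady Navier-Stokes with a prescribed inflow rate, pressure-anchored
    outlets, by pseudo-time marching of the projection scheme to stationarity.

    The march stops when the per-step relative velocity change
    ||u_{n+1} - u_n|| / ||u_n|| falls below ``tol`` (default 1e-8); failure to
    reach that within ``max_time`` pseudo-seconds raises SolverError with the
    residual trace.  Zero inflow returns the zero field with uniform pressure
    immediately.
    """
    if inflow_rate < 0:
        raise ValueError("inflow_rate must be non-negative")
    d = mesh.dim
    rho = props.density
    inlet_idx = mesh.facets_where("inlet")
    if len(inlet_idx) == 0:
        raise SolverError("steady solve requires an inlet")
    area_in = mesh.facet_areas[inlet_idx].sum()
    u_mean = inflow_rate / area_in

    n = mesh.nodes.shape[0]
    if inflow_rate == 0.0:
        return FlowField(times=np.array([0.0]),
                         velocities=np.zeros((1, n, d)),
                         pressures=np.zeros((1, n)), period=1.0,
                         diagnostics={"steady_residuals": [0.0]})

    vols, _ = fem.cell_geometry(mesh.nodes, mesh.cells)
    if time_step is None:
        h_med = float(np.median((vols * math.factorial(d)) ** (1.0 / d)))
        time_step = min(0.3 * h_med / max(2.5 * u_mean, 1e-12), 0.05)

    cfg = SolverConfig(time_step=time_step, n_cycles=2, save_stride=1,
                       inlet_profile=profile, stabilization=stabilization,
                       reference_velocity=2.5 * u_mean, period=1.0)
    stepper = _ProjectionStepper(mesh, lambda t: u_mean, lambda t: 0.0,
                                 props, cfg)
    u = np.zeros((n, d))
    p = np.zeros(n)
    history = []
    # The slow transients are smooth decaying modes (the fundamental viscous
    # mode and, in branched lumens, inter-branch redistribution), so Aitken
    # extrapolation over fixed windows collapses them; a stall detector stops
    # the march when the per-step change hits its round-off floor, which for
    # very small velocity magnitudes can sit above ``tol``.
    window = 40
    u_mark = u.copy()
    p_mark = p.copy()
    delta_prev = None
    res_best, step_best = np.inf, 0
    max_steps = int(math.ceil(max_time / time_step))
    for step in range(1, max_steps + 1):
        t = step * time_step
        u_new, p = stepper.step(t, u, p)
        norm_u = float(np.linalg.norm(u_new))
        res = float(np.linalg.norm(u_new - u)) / max(norm_u, 1e-300)
        u = u_new
        if step % 10 == 0 or res < tol:
            history.append(res)
        if not np.isfinite(res):
            raise SolverError("steady march diverged", step=step,
                              residual_history=history)
        if res < tol and step > 5:
            break
        if res < 0.8 * res_best:
            res_best, step_best = res, step
        if step - step_best > 200 and res < 100 * tol and step > 200:
            break  # round-off plateau: stationary to working precision
        if step % window == 0:
            delta_u = u - u_mark
            delta_p = p - p_mark
            if delta_prev is not None:
                nd, npv = np.linalg.norm(delta_u), np.linalg.norm(delta_prev)
                ratio = nd / max(npv, 1e-300)
                if 1e-6 < ratio < 0.995:
                    f = min(ratio / (1.0 - ratio), 25.0)
                    u = u + f * delta_u
                    p = p + f * delta_p
                    u[stepper.vfixed] = stepper.inlet_bc(t)
                    stepper.conv_prev = None
                    delta_prev = None
                    u_mark, p_mark = u.copy(), p.copy()
                    continue
            delta_prev = delta_u
            u_mark, p_mark = u.copy(), p.copy()
    else:
        raise SolverError("steady march did not reach stationarity",
                          residual_history=history)
    return FlowField(times=np.array([0.0]), velocities=u[None, :, :],
                     pressures=p[None, :], period=1.0,
                     diagnostics={"steady_residuals": history,
                                  "pseudo_steps": step})

# conservation diagnostics


def outlet_flux_series(field: FlowField, mesh: LabeledMesh) -> dict[str, np.ndarray]:
    """Instantaneous outward flux (m^3/s) per outlet tag and the inlet."""
    out = {}
    names = ["inlet"] + [f"outlet:{n}" for n in mesh.outlet_names()]
    for name in names:
        idx = mesh.facets_where(name)
        if len(idx) == 0:
            out[name] = np.zeros(len(field.times))
            continue
        facets = mesh.boundary_facets[idx]
        areas = mesh.facet_areas[idx]
        normals = mesh.facet_normals[idx]
        out[name] = np.array([fem.facet_flux(u, facets, areas, normals)
                              for u in field.velocities])
    return out


def check_mass_conservation(field: FlowField, mesh: LabeledMesh) -> float:
    """Max over snapshots of |sum of outlet fluxes - inlet flux| / |inlet flux|.

    The inlet flux is inward positive.  A zero-flow field reports 0 by
    convention; for inlet-free (pressure-driven) runs the imbalance is scaled
    by the largest single-outlet flux instead.
    """
    fluxes = outlet_flux_series(field, mesh)
    phi_in = -fluxes["inlet"]
    phi_out = sum(v for k, v in fluxes.items() if k != "inlet")
    num = np.abs(phi_out - phi_in)
    outlet_mag = np.max([np.abs(v) for k, v in fluxes.items() if k != "inlet"],
                        axis=0) if len(fluxes) > 1 else np.zeros_like(phi_in)
    scale = np.maximum(np.abs(phi_in), outlet_mag)
    if scale.max() < 1e-14:
        return 0.0
    return float(np.max(num / np.maximum(scale, scale.max() * 1e-6)))
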