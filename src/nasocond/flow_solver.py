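"""Steady incompressible laminar flow on the structured passage mesh.

A collocated finite-volume discretization with SIMPLE pressure-velocity
coupling and Rhie-Chow face-flux interpolation.  Boundary conditions follow
the nasal-inspiration setup: the nostril is a free inlet (zero-gauge total
pressure, velocity direction free), walls are no-slip, and a uniform outward
normal velocity is prescribed at the pharyngeal outlet.  The laminar
Navier-Stokes equations are iterated with under-relaxation until the scaled
continuity and momentum residuals fall below 1e-4 and 1e-5 respectively.

Momentum convection defaults to deferred-correction central differencing
over a first-order upwind base, which keeps the scheme stable at
the low cell Peclet numbers of resting nasal flow while giving the
second-order spatial accuracy needed for grid-converged velocities;
diffusion uses the over-relaxed decomposition with explicit non-orthogonal
correction.  Axisymmetric meshes add the hoop pressure term and the
−μ v/r² viscous source in the radial momentum equation.

This module also hosts the generic gradient/assembly operators reused by
the scalar (temperature, water) transport solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (
    PATCH_AXIS,
    PATCH_INLET,
    PATCH_OUTLET,
    StructuredMesh,
)

__all__ = [
    "FluidProperties",
    "SolverTolerances",
    "FlowField",
    "ConvergenceError",
    "solve_steady_flow",
    "pressure_drop",
]


class ConvergenceError(RuntimeError):
    """Raised when an iteration fails to meet its residual criteria.

    Carries the residual history as a DataFrame in ``residuals``."""

    def __init__(self, message: str, residuals: pd.DataFrame):
        super().__init__(message)
        self.residuals = residuals


@dataclass(frozen=True)
class FluidProperties:
    """Air properties near room temperature (all config-overridable)."""

    density: float = 1.2  # kg/m³
    dynamic_viscosity: float = 1.8e-5  # Pa s
    specific_heat: float = 1006.0  # J/(kg K)
    thermal_conductivity: float = 0.026  # W/(m K)
    vapor_diffusivity: float = 2.6e-5  # m²/s

    def __post_init__(self) -> None:
        for name in (
            "density",
            "dynamic_viscosity",
            "specific_heat",
            "thermal_conductivity",
            "vapor_diffusivity",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density


@dataclass(frozen=True)
class SolverTolerances:
    """Residual criteria and iteration controls.

    The scaled-residual thresholds mirror the convergence criteria of the
    underlying model: continuity 1e-4, velocity components 1e-5, energy
    1e-7, water 1e-4.
    """

    continuity: float = 1e-4
    momentum: float = 1e-5
    energy: float = 1e-7
    water: float = 1e-4
    max_iterations: int = 6000
    relax_u: float = 0.7
    relax_p: float = 0.3
    relax_wall: float = 0.5
    central_blend: float = 1.0  # deferred-correction weight toward central
    scalar_upwind: bool = True  # bounded first-order convection for T and F
    wall_update_tol: float = 1e-8
    max_outer_scalar: int = 400


@dataclass
class FlowField:
    """Converged velocity-pressure solution with per-face mass fluxes."""

    u: np.ndarray  # (n_cells, 2), m/s
    p: np.ndarray  # (n_cells,), Pa (gauge)
    mdot_internal: np.ndarray  # kg/s per internal face, positive owner->neighbour
    mdot_boundary: np.ndarray  # kg/s per boundary face, positive outward
    p_boundary: np.ndarray  # face pressures for diagnostics/export
    residuals: pd.DataFrame = field(repr=False, default=None)
    converged: bool = False
    outlet_velocity: float = 0.0

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u[:, 0], self.u[:, 1])

    def mass_imbalance(self) -> float:
        """|net boundary mass flux| relative to the throughflow."""
        net = float(np.sum(self.mdot_boundary))
        thru = float(np.sum(np.abs(self.mdot_boundary))) / 2.0
        return abs(net) / max(thru, 1e-300)


# ---------------------------------------------------------------------------
# generic finite-volume operators (shared with transport)
# ---------------------------------------------------------------------------

def gradient(mesh: StructuredMesh, phi: np.ndarray, phi_b: np.ndarray) -> np.ndarray:
    """Green-Gauss cell gradient from cell values and boundary-face values."""
    n = mesh.n_cells
    fphi = mesh.if_lam * phi[mesh.if_owner] + (1.0 - mesh.if_lam) * phi[mesh.if_neigh]
    gx = np.bincount(mesh.if_owner, fphi * mesh.if_sf[:, 0], minlength=n)
    gy = np.bincount(mesh.if_owner, fphi * mesh.if_sf[:, 1], minlength=n)
    gx -= np.bincount(mesh.if_neigh, fphi * mesh.if_sf[:, 0], minlength=n)
    gy -= np.bincount(mesh.if_neigh, fphi * mesh.if_sf[:, 1], minlength=n)
    gx += np.bincount(mesh.bf_owner, phi_b * mesh.bf_sf[:, 0], minlength=n)
    gy += np.bincount(mesh.bf_owner, phi_b * mesh.bf_sf[:, 1], minlength=n)
    gy -= phi * mesh.hoop  # axisymmetric hoop correction (zero for planar)
    return np.stack([gx, gy], axis=1) / mesh.vol[:, None]


def assemble_transport(
    mesh: StructuredMesh,
    gamma: float,
    mdot_if: np.ndarray,
    mdot_bf: np.ndarray,
    phi: np.ndarray,
    grad_phi: np.ndarray,
    dirichlet_mask: np.ndarray,
    phi_b: np.ndarray,
    inflow_value: np.ndarray,
    central_blend: float = 0.0,
):
    """Assemble an implicit upwind convection-diffusion system for one scalar.

    Returns (A, b, diag) for A φ = b.  ``dirichlet_mask``/``phi_b`` select
    boundary faces with a fixed value (diffusive link active); all other
    boundary faces are zero-diffusive-flux.  Boundary convection is upwind:
    outflow takes the cell value implicitly, inflow carries
    ``inflow_value``.  ``central_blend`` adds an explicit deferred
    correction from upwind toward linear (central) interpolation.
    """
    n = mesh.n_cells
    own, nei = mesh.if_owner, mesh.if_neigh

    d_f = gamma * mesh.if_e
    conv_p = np.maximum(mdot_if, 0.0)  # flux out of owner
    conv_n = np.maximum(-mdot_if, 0.0)  # flux out of neighbour

    a_pn = -(d_f + conv_n)  # coefficient of φ_N in owner's row
    a_np = -(d_f + conv_p)  # coefficient of φ_P in neighbour's row

    diag = np.zeros(n)
    np.add.at(diag, own, d_f + conv_p)
    np.add.at(diag, nei, d_f + conv_n)

    b = np.zeros(n)
    # explicit non-orthogonal diffusion correction
    gface = mesh.if_lam[:, None] * grad_phi[own] + (1.0 - mesh.if_lam[:, None]) * grad_phi[nei]
    corr = gamma * np.einsum("ij,ij->i", gface, mesh.if_t)
    np.add.at(b, own, corr)
    np.add.at(b, nei, -corr)

    if central_blend > 0.0:
        phi_up = np.where(mdot_if >= 0.0, phi[own], phi[nei])
        phi_c = mesh.if_lam * phi[own] + (1.0 - mesh.if_lam) * phi[nei]
        dc = central_blend * mdot_if * (phi_c - phi_up)
        np.add.at(b, own, -dc)
        np.add.at(b, nei, dc)

    # boundary faces
    bo = mesh.bf_owner
    dmask = dirichlet_mask
    d_b = gamma * mesh.bf_e
    np.add.at(diag, bo[dmask], d_b[dmask])
    np.add.at(b, bo[dmask], d_b[dmask] * phi_b[dmask])
    bcorr = gamma * np.einsum("ij,ij->i", grad_phi[bo[dmask]], mesh.bf_t[dmask])
    np.add.at(b, bo[dmask], bcorr)

    outflow = mdot_bf > 0.0
    np.add.at(diag, bo[outflow], mdot_bf[outflow])
    inflow = mdot_bf < 0.0
    np.add.at(b, bo[inflow], -mdot_bf[inflow] * inflow_value[inflow])

    rows = np.concatenate([np.arange(n), own, nei])
    cols = np.concatenate([np.arange(n), nei, own])
    vals = np.concatenate([diag, a_pn, a_np])
    a = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return a, b, diag


class _LaggedLU:
    """Sparse LU reused across slowly varying matrices.

    The factorization is refreshed every ``refresh`` calls; in between, the
    stale LU is used with one step of iterative refinement, falling back to
    a fresh factorization whenever the refined residual is not small
    relative to the right-hand side.  Inside an under-relaxed outer
    iteration this is an inexact inner solve with a guaranteed-accurate
    fallback, so the converged fixed point is unchanged.
    """

    def __init__(self, refresh: int = 20, rtol: float = 1e-8):
        self.refresh = refresh
        self.rtol = rtol
        self._lu = None
        self._count = 0

    def solve(self, a: sp.csr_matrix, b: np.ndarray) -> np.ndarray:
        if self._lu is None or self._count % self.refresh == 0:
            self._lu = spla.splu(a.tocsc())
        self._count += 1
        x = self._lu.solve(b)
        r = b - a @ x
        x += self._lu.solve(r)
        bnorm = float(np.linalg.norm(b)) + 1e-300
        if float(np.linalg.norm(b - a @ x)) > self.rtol * bnorm:
            self._lu = spla.splu(a.tocsc())
            x = self._lu.solve(b)
        return x


def prolong_cell_field(
    coarse: StructuredMesh, fine: StructuredMesh, values: np.ndarray
) -> np.ndarray:
    """Bilinear prolongation of a per-cell field between structured meshes
    of the same passage (used to initialize refined solves)."""
    from scipy.interpolate import RegularGridInterpolator

    vals = np.asarray(values, dtype=float).reshape(coarse.ns, coarse.nn, -1)
    si = (np.arange(coarse.ns) + 0.5) / coarse.ns
    ei = (np.arange(coarse.nn) + 0.5) / coarse.nn
    interp = RegularGridInterpolator(
        (si, ei), vals, bounds_error=False, fill_value=None
    )
    sf = np.repeat((np.arange(fine.ns) + 0.5) / fine.ns, fine.nn)
    ef = np.tile((np.arange(fine.nn) + 0.5) / fine.nn, fine.ns)
    out = interp(np.stack([sf, ef], axis=1))
    return out[:, 0] if np.ndim(values) == 1 else out


def _cell_tangents(mesh: StructuredMesh) -> np.ndarray:
    """Unit vectors along increasing i (the passage direction) per cell."""
    xg = mesh.xc.reshape(mesh.ns, mesh.nn, 2)
    t = np.empty_like(xg)
    t[1:-1] = xg[2:] - xg[:-2]
    t[0] = xg[1] - xg[0]
    t[-1] = xg[-1] - xg[-2]
    t = t.reshape(-1, 2)
    return t / np.hypot(t[:, 0], t[:, 1])[:, None]


def solve_steady_flow(
    mesh: StructuredMesh,
    fluid: FluidProperties,
    outlet_velocity: float,
    tolerances: SolverTolerances | None = None,
    init: str = "zero",
    initial: "FlowField | None" = None,
    initial_mesh: StructuredMesh | None = None,
) -> FlowField:
    """SIMPLE iteration for the steady laminar velocity-pressure field.

    ``outlet_velocity`` (m/s) is the uniform outward normal speed on the
    pharyngeal outlet patch; the inlet is a zero-gauge total-pressure
    opening.  ``init`` selects the initial guess ("zero" or "tangent");
    the converged state is independent of it to within solver tolerance.
    Raises ``ConvergenceError`` (with the residual history) if the scaled
    residuals fail to meet the criteria within ``max_iterations``.
    """
    tol = tolerances or SolverTolerances()
    if outlet_velocity < 0.0:
        raise ValueError("outlet velocity must be non-negative")
    n = mesh.n_cells
    rho, mu = fluid.density, fluid.dynamic_viscosity
    own, nei = mesh.if_owner, mesh.if_neigh

    inlet = mesh.patch_faces(PATCH_INLET)
    outlet = mesh.patch_faces(PATCH_OUTLET)
    walls_and_axis = np.flatnonzero(
        (mesh.bf_patch != PATCH_INLET) & (mesh.bf_patch != PATCH_OUTLET)
    )
    axis = mesh.patch_faces(PATCH_AXIS)
    wall_dir = np.ones(len(mesh.bf_patch), dtype=bool)
    wall_dir[inlet] = False
    wall_dir[outlet] = True
    wall_dir[axis] = False  # symmetry axis: no diffusive link (zero face area anyway)

    bf_area = np.hypot(mesh.bf_sf[:, 0], mesh.bf_sf[:, 1])
    nhat_out = mesh.bf_sf[outlet] / bf_area[outlet][:, None]

    u = np.zeros((n, 2))
    p = np.zeros(n)
    if initial is not None:
        src_mesh = initial_mesh or mesh
        if src_mesh is mesh:
            u = initial.u.copy()
            p = initial.p.copy()
        else:
            u = prolong_cell_field(src_mesh, mesh, initial.u)
            p = prolong_cell_field(src_mesh, mesh, initial.p)
    elif init == "tangent":
        u = outlet_velocity * _cell_tangents(mesh)
    elif init != "zero":
        raise ValueError("init must be 'zero' or 'tangent'")

    mdot_if = np.zeros(len(own))
    mdot_bf = np.zeros(len(mesh.bf_patch))
    mdot_bf[outlet] = rho * outlet_velocity * bf_area[outlet]
    mdot_out_total = float(np.sum(mdot_bf[outlet]))
    mdot_scale = max(mdot_out_total, 1e-300)

    # boundary velocity/pressure bookkeeping
    u_b = np.zeros((len(mesh.bf_patch), 2))
    u_b[outlet] = outlet_velocity * nhat_out
    p_b = np.zeros(len(mesh.bf_patch))

    dvol = np.full(n, 1.0)
    history: list[dict] = []
    converged = False

    # dirichlet values for momentum diffusion: walls zero, outlet prescribed
    phi_b_mom = np.zeros((len(mesh.bf_patch), 2))
    phi_b_mom[outlet] = u_b[outlet]

    p_in_face = np.zeros(len(inlet))
    lu_u, lu_v, lu_pc = _LaggedLU(), _LaggedLU(), _LaggedLU()
    lu_mom = (lu_u, lu_v)
    for it in range(tol.max_iterations):
        p_b[:] = p[mesh.bf_owner]
        u_in_mag = np.abs(mdot_bf[inlet]) / (rho * bf_area[inlet])
        # zero-gauge total pressure, damped to stabilize the mdot feedback
        p_in_face += 0.5 * (-0.5 * rho * u_in_mag**2 - p_in_face)
        p_b[inlet] = p_in_face
        grad_p = gradient(mesh, p, p_b)

        u_b[inlet] = u[mesh.bf_owner[inlet]]  # free-inlet: zero-gradient velocity
        inflow_val = np.zeros(len(mesh.bf_patch))

        res_mom = np.zeros(2)
        diag_relaxed = np.zeros(n)
        grad_u = [
            gradient(mesh, u[:, c], u_b[:, c] * (mesh.bf_patch != PATCH_AXIS) + u[mesh.bf_owner, c] * (mesh.bf_patch == PATCH_AXIS))
            for c in (0, 1)
        ]
        for c in (0, 1):
            inflow_val[inlet] = u_b[inlet, c]
            a, b, diag = assemble_transport(
                mesh,
                mu,
                mdot_if,
                mdot_bf,
                u[:, c],
                grad_u[c],
                wall_dir,
                phi_b_mom[:, c],
                inflow_val,
                central_blend=tol.central_blend,
            )
            b = b - grad_p[:, c] * mesh.vol
            if c == 1 and mesh.axisymmetric:
                r2 = np.maximum(mesh.xc[:, 1], 1e-12) ** 2
                extra = mu * mesh.vol / r2
                a = a + sp.diags(extra)
                diag = diag + extra
            # implicit under-relaxation
            a = a + sp.diags(diag * (1.0 - tol.relax_u) / tol.relax_u)
            b = b + diag * (1.0 - tol.relax_u) / tol.relax_u * u[:, c]
            diag_rel = diag / tol.relax_u
            scale = float(np.sum(np.abs(diag_rel * u[:, c]))) + 1e-300
            res_mom[c] = float(np.sum(np.abs(b - a @ u[:, c]))) / scale
            u[:, c] = lu_mom[c].solve(a, b)
            diag_relaxed += 0.5 * diag_rel

        dvol = mesh.vol / diag_relaxed

        # Rhie-Chow face fluxes
        lam = mesh.if_lam
        uf = lam[:, None] * u[own] + (1.0 - lam[:, None]) * u[nei]
        df = lam * dvol[own] + (1.0 - lam) * dvol[nei]
        gpf = lam[:, None] * grad_p[own] + (1.0 - lam[:, None]) * grad_p[nei]
        dp_over = (p[nei] - p[own]) - np.einsum("ij,ij->i", gpf, mesh.if_d)
        mdot_if = rho * (np.einsum("ij,ij->i", uf, mesh.if_sf) - df * mesh.if_e * dp_over)

        io = mesh.bf_owner[inlet]
        dp_in = p_b[inlet] - p[io] - np.einsum(
            "ij,ij->i", grad_p[io], mesh.bf_d[inlet]
        )
        mdot_bf[inlet] = rho * (
            np.einsum("ij,ij->i", u[io], mesh.bf_sf[inlet])
            - dvol[io] * mesh.bf_e[inlet] * dp_in
        )

        # pressure-correction equation
        div = np.bincount(own, mdot_if, minlength=n) - np.bincount(nei, mdot_if, minlength=n)
        div += np.bincount(mesh.bf_owner, mdot_bf, minlength=n)
        res_cont = float(np.sum(np.abs(div))) / mdot_scale

        a_f = rho * df * mesh.if_e
        diag_pc = np.zeros(n)
        np.add.at(diag_pc, own, a_f)
        np.add.at(diag_pc, nei, a_f)
        a_in = rho * dvol[io] * mesh.bf_e[inlet]
        np.add.at(diag_pc, io, a_in)
        rows = np.concatenate([np.arange(n), own, nei])
        cols = np.concatenate([np.arange(n), nei, own])
        vals = np.concatenate([diag_pc, -a_f, -a_f])
        a_pc = sp.csr_matrix((vals, (rows, cols)), shape=(n, n))
        pc = lu_pc.solve(a_pc, -div)

        # corrections
        p += tol.relax_p * pc
        pc_b = pc[mesh.bf_owner].copy()
        pc_b[inlet] = 0.0
        grad_pc = gradient(mesh, pc, pc_b)
        u -= dvol[:, None] * grad_pc
        mdot_if += a_f * (pc[own] - pc[nei])
        mdot_bf[inlet] += a_in * pc[io]

        history.append(
            {"iteration": it, "continuity": res_cont, "u": res_mom[0], "v": res_mom[1]}
        )
        if not np.isfinite(res_cont + res_mom[0] + res_mom[1]):
            raise ConvergenceError(
                f"flow solver diverged at iteration {it}", pd.DataFrame(history)
            )
        if (
            it > 2
            and res_cont < tol.continuity
            and res_mom[0] < tol.momentum
            and res_mom[1] < tol.momentum
        ):
            converged = True
            break

    residuals = pd.DataFrame(history)
    if not converged:
        raise ConvergenceError(
            f"flow solver failed to converge in {tol.max_iterations} iterations "
            f"(continuity {res_cont:.2e}, u {res_mom[0]:.2e}, v {res_mom[1]:.2e})",
            residuals,
        )
    p_b[:] = p[mesh.bf_owner]
    u_in_mag = np.abs(mdot_bf[inlet]) / (rho * bf_area[inlet])
    p_b[inlet] = -0.5 * rho * u_in_mag**2
    return FlowField(
        u=u,
        p=p,
        mdot_internal=mdot_if,
        mdot_boundary=mdot_bf,
        p_boundary=p_b,
        residuals=residuals,
        converged=True,
        outlet_velocity=outlet_velocity,
    )


def pressure_drop(flow: FlowField, mesh: StructuredMesh) -> float:
    """Area-averaged inlet pressure minus outlet pressure (Pa).

    Requires a converged flow; zero velocity everywhere gives zero."""
    if not flow.converged:
        raise RuntimeError("pressure_drop requires a converged flow field")
    area = np.hypot(mesh.bf_sf[:, 0], mesh.bf_sf[:, 1])
    inlet = mesh.patch_faces(PATCH_INLET)
    outlet = mesh.patch_faces(PATCH_OUTLET)
    p_in = float(np.sum(flow.p_boundary[inlet] * area[inlet]) / np.sum(area[inlet]))
    p_out = float(np.sum(flow.p_boundary[outlet] * area[outlet]) / np.sum(area[outlet]))
    return p_in - p_out
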