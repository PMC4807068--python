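"""Temperature and water-vapor transport on the converged flow field.

Convection-diffusion of temperature T (°C) and water mass fraction F (%MF)
is solved on the frozen velocity field (one-way coupling: air properties do
not feed back on the flow, so one flow solve serves all ambient
conditions).  The wall closes the system: on mucosa the water field takes
the two-film surface value F_S as a Dirichlet condition, on epidermis the
water flux is zero, and everywhere the surface temperature T_S balances the
discrete fluid-side conduction against the wall's total flux Q_total
(conduction through the epithelium plus evaporative latent heat).  The
outer iteration alternates scalar solves with damped wall-state updates
until the face states settle below 1e-8 and the scaled residuals fall
below 1e-7 (energy) and 1e-4 (water).

Scalar convection is first-order upwind, which guarantees the discrete
extremum principle: converged T and F lie between the inlet state and the
wall surface values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import scipy.sparse.linalg as spla

from .flow_solver import (
    ConvergenceError,
    FlowField,
    FluidProperties,
    SolverTolerances,
    assemble_transport,
    gradient,
    solve_steady_flow,
)
from .geometry import (
    PATCH_INLET,
    PATCH_OUTLET,
    REGION_EPIDERMIS,
    StructuredMesh,
)
from .psychro import AmbientCondition
from .wall_model import (
    WallProperties,
    solve_surface_temperature_vec,
    surface_water_fraction,
    water_flux,
)

__all__ = ["ScalarFields", "WallState", "solve_scalar_transport", "couple_flow_and_scalars",
           "scalar_conservation"]


@dataclass
class WallState:
    """Per-wall-face converged surface state and fluxes (positive into the air)."""

    faces: np.ndarray  # boundary-face indices
    region: np.ndarray  # REGION_EPIDERMIS / REGION_MUCOSA
    arclength: np.ndarray  # m, along the passage
    surface_temperature: np.ndarray  # °C
    surface_water_fraction: np.ndarray  # %MF
    water_flux: np.ndarray  # kg/(m² s)
    conductive_flux: np.ndarray  # W/m²
    latent_flux: np.ndarray  # W/m²

    @property
    def total_flux(self) -> np.ndarray:
        return self.conductive_flux + self.latent_flux

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "face": self.faces,
                "region": np.where(self.region == REGION_EPIDERMIS, "epidermis", "mucosa"),
                "s_m": self.arclength,
                "T_S": self.surface_temperature,
                "F_S": self.surface_water_fraction,
                "W_bl": self.water_flux,
                "Q_ep": self.conductive_flux,
                "Q_latent": self.latent_flux,
                "Q_total": self.total_flux,
            }
        )


@dataclass
class ScalarFields:
    """Converged temperature / water-fraction fields and the wall state."""

    temperature: np.ndarray  # °C per cell
    water_fraction: np.ndarray  # %MF per cell
    wall: WallState
    residuals: pd.DataFrame = field(repr=False, default=None)
    converged: bool = False
    inlet: AmbientCondition = None


def _solve_one(mesh, gamma, conv_if, conv_bf, phi, phi_b_all, dmask, phi_b, inflow, lu):
    """One scalar solve; the matrix is constant across the outer loop (the
    flow is frozen), so its factorization is computed once and reused."""
    grad = gradient(mesh, phi, phi_b_all)
    a, b, diag = assemble_transport(
        mesh, gamma, conv_if, conv_bf, phi, grad, dmask, phi_b, inflow
    )
    scale = float(np.sum(np.abs(diag * phi))) + 1e-300
    res = float(np.sum(np.abs(b - a @ phi))) / scale
    if lu[0] is None:
        lu[0] = spla.splu(a.tocsc())
    return lu[0].solve(b), res


def solve_scalar_transport(
    mesh: StructuredMesh,
    flow: FlowField,
    fluid: FluidProperties,
    wall: WallProperties,
    inlet: AmbientCondition,
    tolerances: SolverTolerances | None = None,
) -> ScalarFields:
    """Solve coupled T/F transport with the mucosal wall model.

    Requires a converged ``FlowField`` on the same mesh.  Returns converged
    fields plus the per-face ``WallState``; raises ``ConvergenceError`` if
    the outer iteration stalls.
    """
    tol = tolerances or SolverTolerances()
    if not flow.converged:
        raise ValueError("scalar transport requires a converged flow field")
    n = mesh.n_cells
    rho, cp = fluid.density, fluid.specific_heat
    k_fl = fluid.thermal_conductivity
    d_h2o = rho * fluid.vapor_diffusivity

    wfaces = mesh.wall_faces
    epi = mesh.bf_region[wfaces] == REGION_EPIDERMIS
    inlet_f = mesh.patch_faces(PATCH_INLET)
    outlet_f = mesh.patch_faces(PATCH_OUTLET)
    area_w = np.hypot(mesh.bf_sf[wfaces, 0], mesh.bf_sf[wfaces, 1])
    # discrete fluid-side conductance per unit area for the face energy balance
    h_fluid = k_fl * mesh.bf_e[wfaces] / np.maximum(area_w, 1e-300)
    owner_w = mesh.bf_owner[wfaces]

    t_in, f_in = inlet.temperature, inlet.mass_fraction
    t = np.full(n, t_in)
    f = np.full(n, f_in)
    t_s = np.full(len(wfaces), wall.tissue_temperature)
    f_s = np.full(len(wfaces), wall.tissue_water_fraction)

    nbf = len(mesh.bf_patch)
    conv_t = cp * flow.mdot_boundary  # energy convective boundary flux
    conv_f = flow.mdot_boundary.copy()  # water convective boundary flux

    # Dirichlet masks: energy on walls (T_S) and inflow (inlet); water on
    # mucosa walls and inflow.  Epidermis water faces are zero-flux.
    dmask_t = np.zeros(nbf, dtype=bool)
    dmask_t[wfaces] = True
    dmask_t[inlet_f] = True
    dmask_f = np.zeros(nbf, dtype=bool)
    dmask_f[wfaces[~epi]] = True
    dmask_f[inlet_f] = True

    phi_b_t = np.zeros(nbf)
    phi_b_t[inlet_f] = t_in
    phi_b_f = np.zeros(nbf)
    phi_b_f[inlet_f] = f_in
    inflow_t = np.full(nbf, t_in)
    inflow_f = np.full(nbf, f_in)

    history: list[dict] = []
    converged = False
    lu_t, lu_f = [None], [None]
    for it in range(tol.max_outer_scalar):
        phi_b_t[wfaces] = t_s
        phi_b_f[wfaces[~epi]] = f_s[~epi]

        # boundary-face field values for the gradient operator
        tb_all = t[mesh.bf_owner].copy()
        tb_all[dmask_t] = phi_b_t[dmask_t]
        fb_all = f[mesh.bf_owner].copy()
        fb_all[dmask_f] = phi_b_f[dmask_f]

        t, res_t = _solve_one(
            mesh, k_fl, cp * flow.mdot_internal, conv_t, t, tb_all, dmask_t, phi_b_t, inflow_t, lu_t
        )
        f, res_f = _solve_one(
            mesh, d_h2o, flow.mdot_internal, conv_f, f, fb_all, dmask_f, phi_b_f, inflow_f, lu_f
        )
        f = np.maximum(f, 0.0)

        # wall-state update (damped); the non-orthogonal part of the
        # discrete wall flux enters the balance as an offset so the face
        # energy budget matches the assembled flux exactly
        tb_all[wfaces] = t_s
        grad_t = gradient(mesh, t, tb_all)
        nonorth = k_fl * np.einsum(
            "ij,ij->i", grad_t[owner_w], mesh.bf_t[wfaces]
        ) / np.maximum(area_w, 1e-300)
        f_s_new = f_s.copy()
        f_s_new[~epi] = surface_water_fraction(f[owner_w[~epi]], wall)
        w_bl = np.where(
            epi, 0.0, water_flux(f[owner_w], f_s_new, wall, rho)
        )
        t_s_new = solve_surface_temperature_vec(
            h_fluid, t[owner_w], w_bl, wall, epi, flux_offset=-nonorth
        )
        dts = float(np.max(np.abs(t_s_new - t_s))) if len(t_s) else 0.0
        dfs = float(np.max(np.abs(f_s_new - f_s))) if len(f_s) else 0.0
        t_s += tol.relax_wall * (t_s_new - t_s)
        f_s += tol.relax_wall * (f_s_new - f_s)

        history.append({"iteration": it, "energy": res_t, "h2o": res_f,
                        "dT_S": dts, "dF_S": dfs})
        if (
            it > 1
            and res_t < tol.energy
            and res_f < tol.water
            and dts < tol.wall_update_tol
            and dfs < tol.wall_update_tol
        ):
            converged = True
            break

    residuals = pd.DataFrame(history)
    if not converged:
        raise ConvergenceError(
            f"scalar transport failed to converge in {tol.max_outer_scalar} outer "
            f"iterations (energy {res_t:.2e}, h2o {res_f:.2e}, dT_S {dts:.2e})",
            residuals,
        )

    w_bl = np.where(epi, 0.0, water_flux(f[owner_w], f_s, wall, rho))
    delta = np.where(
        epi, wall.epithelial_thickness_epidermis, wall.epithelial_thickness_mucosa
    )
    q_ep = wall.epithelial_conductivity * (wall.tissue_temperature - t_s) / delta
    from .wall_model import _latent_heat_j

    q_lat = -_latent_heat_j(t_s) * w_bl
    wall_state = WallState(
        faces=wfaces,
        region=mesh.bf_region[wfaces],
        arclength=mesh.bf_s[wfaces],
        surface_temperature=t_s,
        surface_water_fraction=np.where(epi, wall.tissue_water_fraction, f_s),
        water_flux=w_bl,
        conductive_flux=q_ep,
        latent_flux=q_lat,
    )
    return ScalarFields(
        temperature=t,
        water_fraction=f,
        wall=wall_state,
        residuals=residuals,
        converged=True,
        inlet=inlet,
    )


def scalar_conservation(
    mesh: StructuredMesh,
    flow: FlowField,
    fields: ScalarFields,
    fluid: FluidProperties,
) -> dict:
    """Global energy and water balances (inlet + wall − outlet, relative).

    The advective fluxes use the upwinded boundary values consistent with
    the discretization; the wall contribution is the discrete diffusive
    flux through each wall face.  Returns relative imbalances for both
    scalars (should be well below 0.5% at convergence).
    """
    t, f = fields.temperature, fields.water_fraction
    rho, cp, k_fl = fluid.density, fluid.specific_heat, fluid.thermal_conductivity
    d_h2o = rho * fluid.vapor_diffusivity
    inlet_f = mesh.patch_faces(PATCH_INLET)
    outlet_f = mesh.patch_faces(PATCH_OUTLET)
    wf = fields.wall.faces
    ow = mesh.bf_owner

    t_in = fields.inlet.temperature
    f_in = fields.inlet.mass_fraction

    # boundary-face values as used by the discretization
    tb = t[ow].copy()
    tb[inlet_f] = t_in
    tb[wf] = fields.wall.surface_temperature
    fb = f[ow].copy()
    fb[inlet_f] = f_in
    epi = fields.wall.region == REGION_EPIDERMIS
    fb[wf[~epi]] = fields.wall.surface_water_fraction[~epi]
    grad_t = gradient(mesh, t, tb)
    grad_f = gradient(mesh, f, fb)

    def diff_in(gamma, phi, phi_bv, grad, faces):
        """Discrete diffusive flux into the domain through Dirichlet faces."""
        e = gamma * mesh.bf_e[faces]
        corr = gamma * np.einsum("ij,ij->i", grad[ow[faces]], mesh.bf_t[faces])
        return e * (phi_bv[faces] - phi[ow[faces]]) + corr

    # advection (outward positive); inflow carries the boundary value
    md = flow.mdot_boundary
    adv_t = np.where(md < 0, md * tb, md * t[ow])
    adv_f = np.where(md < 0, md * fb, md * f[ow])
    energy_in = -cp * float(np.sum(adv_t[inlet_f])) + float(
        np.sum(diff_in(k_fl, t, tb, grad_t, inlet_f))
    )
    energy_out = cp * float(np.sum(adv_t[outlet_f]))
    water_in = -float(np.sum(adv_f[inlet_f])) + float(
        np.sum(diff_in(d_h2o, f, fb, grad_f, inlet_f))
    )
    water_out = float(np.sum(adv_f[outlet_f]))

    # discrete wall fluxes into the fluid
    q_wall = float(np.sum(diff_in(k_fl, t, tb, grad_t, wf)))
    w_wall = float(np.sum(diff_in(d_h2o, f, fb, grad_f, wf[~epi])))

    scale_e = max(abs(energy_in), abs(energy_out), abs(q_wall), 1e-300)
    scale_w = max(abs(water_in), abs(water_out), abs(w_wall), 1e-300)
    return {
        "energy_in": energy_in,
        "energy_wall": q_wall,
        "energy_out": energy_out,
        "energy_imbalance": (energy_in + q_wall - energy_out) / scale_e,
        "water_in": water_in,
        "water_wall": w_wall,
        "water_out": water_out,
        "water_imbalance": (water_in + w_wall - water_out) / scale_w,
    }


def couple_flow_and_scalars(
    mesh: StructuredMesh,
    fluid: FluidProperties,
    wall: WallProperties,
    inlet: AmbientCondition,
    outlet_velocity: float,
    tolerances: SolverTolerances | None = None,
    flow: FlowField | None = None,
) -> tuple[FlowField, ScalarFields]:
    """One-way coupled solve: flow once, then scalars with wall exchange.

    Buoyancy and property variation with T/F are neglected, so the flow
    field is independent of the ambient condition; pass a previously
    converged ``flow`` to reuse it across conditions.
    """
    if flow is None:
        flow = solve_steady_flow(mesh, fluid, outlet_velocity, tolerances)
    fields = solve_scalar_transport(mesh, flow, fluid, wall, inlet, tolerances)
    return flow, fields
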