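"""Mucosal wall exchange: conductive heat, evaporative latent heat, two-film water.

The airway wall is a tissue layer at fixed temperature T_Tis = 34 °C and
water fraction F_Tis = 3.34 %MF, separated from the air by an epithelial
layer (thickness 0.2 mm in the epidermis-lined vestibule, 0.5 mm in the
mucosa-lined remainder) and, for water, a stagnant boundary-layer film of
0.5 mm.  Per wall face:

    Q_ep     = K_ep (T_Tis − T_S)/δ_ep          conduction from the tissue
    W_bl     = ρ D_bl (F_S − F)/δ_bl            two-film water flux (mucosa)
    Q_latent = −L(T_S) W_bl                     evaporative cooling
    Q_total  = Q_ep + Q_latent                  flux delivered to the air

Fluxes are positive *into the air*.  Requiring the water flux through the
epithelial film to match the boundary-layer film (two-film continuity of
Fick diffusion) fixes the surface water fraction

    F_S = (a F_Tis + b F) / (a + b),   a = D_ep/δ_ep,  b = D_bl/δ_bl,

which always lies between the cell fraction F and F_Tis and reduces to
F_Tis at equilibrium.  Vestibule (epidermis) faces exchange heat only:
W_bl = Q_latent = 0 there.

The surface temperature T_S of each face balances the fluid-side diffusive
flux against Q_total; the balance is mildly nonlinear through L(T_S) and is
solved with a bracketed bisection to 1e-10 °C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .psychro import latent_heat

__all__ = [
    "WallProperties",
    "WallFaceState",
    "surface_water_fraction",
    "water_flux",
    "conductive_flux",
    "latent_flux",
    "solve_surface_state",
    "solve_surface_temperature_vec",
]

EPIDERMIS = "epidermis"
MUCOSA = "mucosa"

T_BRACKET = (-20.0, 60.0)


@dataclass(frozen=True)
class WallProperties:
    """Mucosal-wall model constants (defaults are the model's printed values)."""

    epithelial_conductivity: float = 0.6  # W/(m K), thermal conductivity of water
    epithelial_thickness_mucosa: float = 0.5e-3  # m
    epithelial_thickness_epidermis: float = 0.2e-3  # m
    boundary_layer_thickness: float = 0.5e-3  # m
    boundary_layer_diffusivity: float = 3.0e-5  # m²/s
    epithelial_diffusivity: float = 2.6e-5  # m²/s
    tissue_temperature: float = 34.0  # °C
    tissue_water_fraction: float = 3.34  # %MF

    def __post_init__(self) -> None:
        for name in (
            "epithelial_conductivity",
            "epithelial_thickness_mucosa",
            "epithelial_thickness_epidermis",
            "boundary_layer_thickness",
            "boundary_layer_diffusivity",
            "epithelial_diffusivity",
        ):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    def epithelial_thickness(self, region: str) -> float:
        return (
            self.epithelial_thickness_epidermis
            if region == EPIDERMIS
            else self.epithelial_thickness_mucosa
        )


@dataclass(frozen=True)
class WallFaceState:
    """Converged per-face surface state and fluxes (positive into the air)."""

    region: str
    surface_temperature: float  # °C
    surface_water_fraction: float  # %MF (tissue value on epidermis, unused there)
    water_flux: float  # kg/(m² s)
    conductive_flux: float  # W/m²
    latent_flux: float  # W/m²

    @property
    def total_flux(self) -> float:
        return self.conductive_flux + self.latent_flux


def surface_water_fraction(cell_fraction, props: WallProperties, region: str = MUCOSA):
    """Two-film surface water fraction F_S (%MF) given the near-wall cell F.

    F_S = (a F_Tis + b F)/(a + b) with a = D_ep/δ_ep, b = D_bl/δ_bl; lies
    between F and F_Tis.  On epidermis no water boundary applies and the
    tissue value is returned for bookkeeping.
    """
    f = np.asarray(cell_fraction, dtype=float)
    if np.any(f < 0.0):
        raise ValueError("water mass fraction must be non-negative")
    if region == EPIDERMIS:
        return np.broadcast_to(props.tissue_water_fraction, f.shape).copy() if f.ndim else props.tissue_water_fraction
    a = props.epithelial_diffusivity / props.epithelial_thickness_mucosa
    b = props.boundary_layer_diffusivity / props.boundary_layer_thickness
    fs = (a * props.tissue_water_fraction + b * f) / (a + b)
    return fs if f.ndim else float(fs)


def water_flux(cell_fraction, surface_fraction, props: WallProperties, air_density: float, region: str = MUCOSA):
    """Boundary-layer water flux W_bl in kg/(m² s), positive = evaporation.

    W_bl = ρ D_bl (F_S − F)/δ_bl with the %MF values converted to pure mass
    fractions.  Zero on epidermis, where water is not exchanged.
    """
    f = np.asarray(cell_fraction, dtype=float)
    fs = np.asarray(surface_fraction, dtype=float)
    if region == EPIDERMIS:
        out = np.zeros(np.broadcast(f, fs).shape)
        return out if out.ndim else 0.0
    w = (
        air_density
        * props.boundary_layer_diffusivity
        * (fs - f)
        / 100.0
        / props.boundary_layer_thickness
    )
    return w if np.ndim(w) else float(w)


def conductive_flux(surface_temperature, props: WallProperties, region: str = MUCOSA):
    """Epithelial conduction Q_ep = K_ep (T_Tis − T_S)/δ_ep in W/m².

    Positive when the tissue warms the surface; the epidermis uses the
    thinner 0.2 mm layer."""
    ts = np.asarray(surface_temperature, dtype=float)
    q = (
        props.epithelial_conductivity
        * (props.tissue_temperature - ts)
        / props.epithelial_thickness(region)
    )
    return q if ts.ndim else float(q)


def _latent_heat_j(ts):
    """Latent heat in J/kg, vectorized polynomial (no range warning; the
    surface solve brackets within the physical range)."""
    t = np.asarray(ts, dtype=float)
    return 1e3 * (2500.79 - 0.00000614342 * t**3 + 0.00158927 * t**2 - 2.36418 * t)


def latent_flux(water_flux_value, surface_temperature):
    """Evaporative heat flux Q_latent = −L(T_S)·W_bl in W/m².

    Negative (cooling) while water evaporates; positive under condensation.
    """
    q = -_latent_heat_j(surface_temperature) * np.asarray(water_flux_value, dtype=float)
    return q if np.ndim(q) else float(q)


def solve_surface_temperature_vec(
    h_fluid: np.ndarray,
    t_fluid: np.ndarray,
    w_bl: np.ndarray,
    props: WallProperties,
    region_is_epidermis: np.ndarray,
    tol: float = 1e-10,
    flux_offset: np.ndarray | float = 0.0,
) -> np.ndarray:
    """Vectorized bisection for the per-face energy balance.

    Solves h_fluid (T_S − T_fluid) − q_off = K_ep (T_Tis − T_S)/δ_ep − L(T_S) W_bl
    for each face, with ``h_fluid`` the discrete fluid-side conductance per
    unit area (W/(m² K)), W_bl held fixed, and ``flux_offset`` an additive
    fluid-side flux term (the transport solver passes its non-orthogonal
    diffusion correction here so the face balance matches the discrete flux
    exactly).  Brackets T_S in [−20, 60] °C and raises if the balance has
    no root there.
    """
    h = np.asarray(h_fluid, dtype=float)
    tf = np.asarray(t_fluid, dtype=float)
    w = np.asarray(w_bl, dtype=float)
    q_off = np.asarray(flux_offset, dtype=float)
    epi = np.asarray(region_is_epidermis, dtype=bool)
    k = props.epithelial_conductivity
    delta = np.where(
        epi, props.epithelial_thickness_epidermis, props.epithelial_thickness_mucosa
    )
    w = np.where(epi, 0.0, w)

    def residual(ts):
        return h * (ts - tf) - q_off - (
            k * (props.tissue_temperature - ts) / delta - _latent_heat_j(ts) * w
        )

    lo = np.full(h.shape, T_BRACKET[0])
    hi = np.full(h.shape, T_BRACKET[1])
    rlo, rhi = residual(lo), residual(hi)
    if np.any(rlo * rhi > 0.0):
        raise RuntimeError(
            "wall energy balance has no root in the physical bracket [-20, 60] °C"
        )
    # 80 K bracket / 2^53 is far below tol; iterate until below tol
    n_iter = int(np.ceil(np.log2((T_BRACKET[1] - T_BRACKET[0]) / tol))) + 2
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        rm = residual(mid)
        neg = rlo * rm <= 0.0
        hi = np.where(neg, mid, hi)
        rhi = np.where(neg, rm, rhi)
        lo = np.where(neg, lo, mid)
        rlo = np.where(neg, rlo, rm)
    return 0.5 * (lo + hi)


def solve_surface_state(
    fluid_side_heat_coefficient: float,
    fluid_side_temperature: float,
    cell_fraction: float,
    props: WallProperties,
    region: str = MUCOSA,
    air_density: float = 1.2,
) -> WallFaceState:
    """Solve one face's surface state from the fluid-side linear flux law.

    The fluid side delivers h (T_S − T_fluid) to the wall; the wall delivers
    Q_total to the air.  Their balance fixes T_S; F_S and W_bl follow from
    the two-film closure at the given near-wall water fraction.
    """
    if fluid_side_heat_coefficient <= 0.0:
        raise ValueError("fluid-side heat-transfer coefficient must be positive")
    fs = surface_water_fraction(cell_fraction, props, region)
    wb = water_flux(cell_fraction, fs, props, air_density, region)
    ts = float(
        solve_surface_temperature_vec(
            np.array([fluid_side_heat_coefficient]),
            np.array([fluid_side_temperature]),
            np.array([wb]),
            props,
            np.array([region == EPIDERMIS]),
        )[0]
    )
    return WallFaceState(
        region=region,
        surface_temperature=ts,
        surface_water_fraction=float(fs),
        water_flux=float(wb),
        conductive_flux=conductive_flux(ts, props, region),
        latent_flux=latent_flux(wb, ts),
    )
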