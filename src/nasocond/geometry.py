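"""Synthetic nasal-passage geometries, virtual variants, and structured meshes.

The passage is a planar channel strip described by a centerline heading
``theta(s)`` and a local width ``w(s)`` over arclength ``s`` (mm).  Its
segments emulate the essential airway structure: an inlet vestibule duct
(vertical in the human-like preset, horizontal in the chimpanzee-like one), a
narrow valve constriction at the vestibule-cavity junction, an expanded
cavity whose centerline arches over the cavity floor, a bend, and a
pharyngeal outlet duct.  Vestibule walls are epidermis (heat exchange only);
all other walls are mucosa.

Two virtual modifications mirror the anatomy-editing experiment: ``no_valve``
replaces the vestibule and valve by a straight duct lofted from the nostril
to the basal plane (the valve cross-section), removing the constriction, and
``horizontal`` additionally tilts that straight duct about the basal plane so
its lower surface lies parallel to the cavity floor.

``mesh_passage`` discretizes the strip into a structured quadrilateral mesh
(planar unit depth, or axisymmetric for straight ducts) and precomputes the
finite-volume metadata (cell volumes, face area vectors, owner/neighbour
connectivity, boundary patches) consumed by the flow and transport solvers.
All mesh quantities are in SI metres; geometry parameters are in mm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Polygon

__all__ = [
    "ParameterError",
    "StructuralError",
    "GeometryError",
    "ResolutionError",
    "PassageParams",
    "PassageGeometry",
    "StructuredMesh",
    "PASSAGE_PRESETS",
    "build_passage",
    "apply_no_valve",
    "apply_horizontal",
    "mesh_passage",
    "random_params",
]


class ParameterError(ValueError):
    """Passage parameters violate their invariants."""


class StructuralError(ValueError):
    """A variant operation was applied to a geometry lacking the required structure."""


class GeometryError(ValueError):
    """The requested modification produces an invalid (self-intersecting) domain."""


class ResolutionError(ValueError):
    """Mesh spacing too coarse to resolve the valve constriction."""


# patch codes used on boundary faces
PATCH_INLET = 0
PATCH_OUTLET = 1
PATCH_WALL_LOWER = 2
PATCH_WALL_UPPER = 3
PATCH_AXIS = 4

REGION_EPIDERMIS = 0
REGION_MUCOSA = 1
REGION_NONE = -1

#: fine sampling step (mm) for the parametric description
_DS_FINE = 0.05


@dataclass(frozen=True)
class PassageParams:
    """Parameters of the synthetic passage (lengths and widths in mm).

    ``vestibule_angle`` is the inclination of the vestibule axis above the
    cavity floor: 90 is the human-like vertical duct, 0 the chimpanzee-like
    horizontal one.  ``valve_gap`` is the minimum opening at the
    vestibule-cavity junction.  ``cavity_arch`` (degrees) is the upward
    heading the cavity centerline reaches after the valve, giving the arched
    path over the cavity floor; ``pharynx_angle`` is the outlet duct heading
    (-90 = straight down, 0 = no bend).
    """

    dimensionality: str = "planar"  # "planar" | "axisymmetric"
    vestibule_angle: float = 90.0
    vestibule_length: float = 15.0
    vestibule_width: float = 8.0
    valve_gap: float = 3.0
    valve_length: float = 10.0
    cavity_length: float = 50.0
    cavity_height: float = 6.0
    cavity_arch: float = 25.0
    entry_length: float = 15.0
    bend_length: float = 18.0
    pharynx_length: float = 15.0
    pharynx_width: float = 8.0
    pharynx_angle: float = -90.0

    def validate(self) -> None:
        lengths = {
            "vestibule_length": self.vestibule_length,
            "vestibule_width": self.vestibule_width,
            "valve_gap": self.valve_gap,
            "valve_length": self.valve_length,
            "cavity_length": self.cavity_length,
            "cavity_height": self.cavity_height,
            "bend_length": self.bend_length,
            "pharynx_length": self.pharynx_length,
            "pharynx_width": self.pharynx_width,
        }
        for name, value in lengths.items():
            if not value > 0.0:
                raise ParameterError(f"{name} must be positive, got {value}")
        if not 0.0 <= self.vestibule_angle <= 90.0:
            raise ParameterError("vestibule_angle must lie in [0, 90] degrees")
        if self.valve_gap > self.vestibule_width:
            raise ParameterError("valve_gap must not exceed vestibule_width")
        if not 0.0 <= self.cavity_arch <= 45.0:
            raise ParameterError("cavity_arch must lie in [0, 45] degrees")
        if not self.entry_length > 0.0:
            raise ParameterError("entry_length must be positive")
        if not -90.0 <= self.pharynx_angle <= 0.0:
            raise ParameterError("pharynx_angle must lie in [-90, 0] degrees")
        if self.dimensionality not in ("planar", "axisymmetric"):
            raise ParameterError("dimensionality must be planar or axisymmetric")


#: Named presets.  ``human_like`` has the vertical vestibule and a marked
#: valve constriction; ``chimp_like`` a horizontal vestibule, a milder
#: constriction, and a long low cavity with no arch.  Widths are chosen so
#: the pharyngeal Reynolds number at the default outlet velocity sits inside
#: the laminar resting-breathing range (roughly 135-1264).
PASSAGE_PRESETS: dict[str, PassageParams] = {
    "human_like": PassageParams(),
    "chimp_like": PassageParams(
        vestibule_angle=0.0,
        vestibule_length=15.0,
        vestibule_width=8.0,
        valve_gap=4.5,
        valve_length=12.0,
        cavity_length=55.0,
        cavity_height=6.0,
        cavity_arch=0.0,
        bend_length=15.0,
        pharynx_length=15.0,
        pharynx_width=8.0,
    ),
}


def _cosblend(t: np.ndarray) -> np.ndarray:
    """C1 blend from 0 to 1 on t in [0, 1]."""
    return 0.5 - 0.5 * np.cos(np.pi * np.clip(t, 0.0, 1.0))


@dataclass
class PassageGeometry:
    """A sampled passage description plus derived boundary polylines.

    ``s`` is arclength (mm) from the nostril plane; ``theta`` the centerline
    heading (radians, measured from the cavity-floor horizontal); ``width``
    the local channel width (mm); ``region`` the wall label per sample
    (0 = epidermis, 1 = mucosa).  ``markers`` holds segment boundaries,
    including ``basal`` — the basal plane at the downstream end of the valve.
    """

    params: PassageParams
    variant: str
    s: np.ndarray
    theta: np.ndarray
    width: np.ndarray
    region: np.ndarray
    centerline: np.ndarray
    markers: dict = field(default_factory=dict)
    n_stations: int = 12

    @property
    def total_length(self) -> float:
        return float(self.s[-1])

    @property
    def s_basal(self) -> float:
        return float(self.markers["basal"])

    @property
    def section_stations(self) -> np.ndarray:
        """Equally spaced cross-section stations, nares to nasopharynx (mm)."""
        return np.linspace(0.0, self.total_length, self.n_stations)

    def normals(self) -> np.ndarray:
        return np.stack([-np.sin(self.theta), np.cos(self.theta)], axis=1)

    def boundary_polylines(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) wall polylines; 'lower' is the cavity-floor side."""
        n = self.normals()
        half = 0.5 * self.width[:, None]
        return self.centerline - n * half, self.centerline + n * half

    def polygon(self) -> Polygon:
        lower, upper = self.boundary_polylines()
        return Polygon(np.vstack([lower, upper[::-1]]))

    def cross_section_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(s, width) samples of the cross-sectional extent along the passage."""
        return self.s.copy(), self.width.copy()

    def vestibule_inclination(self) -> float:
        """Inclination (degrees) of the lower wall of the straight vestibule
        portion above the cavity-floor horizontal (no-valve variants)."""
        if self.variant not in ("no_valve", "horizontal"):
            raise StructuralError(
                "vestibule_inclination is defined for no-valve/horizontal variants"
            )
        phi = float(self.markers["vestibule_heading"])
        wprime = float(self.markers["vestibule_taper"])
        return math.degrees(phi - math.atan(0.5 * wprime))

    def _validate_shape(self) -> None:
        if np.any(self.width <= 0.0):
            raise ParameterError("cross-sectional extent must stay positive")
        kappa = np.gradient(self.theta, self.s)
        if np.max(np.abs(kappa) * self.width / 2.0) >= 0.99:
            raise ParameterError(
                "centerline curvature too strong for the local width "
                "(inner wall would fold)"
            )
        poly = self.polygon()
        if not poly.is_valid:
            raise GeometryError("passage boundary is self-intersecting")


def _segment_profiles(params: PassageParams):
    """Per-fine-sample (s, theta, width, region, markers) for a normal build."""
    p = params
    a = math.radians(p.vestibule_angle)
    arch = math.radians(p.cavity_arch)
    ph = math.radians(p.pharynx_angle)
    # the cavity-entry expansion has its own length so that shortening the
    # cavity does not steepen the diffuser behind the valve
    l_entry = min(p.entry_length, 0.6 * p.cavity_length)
    l_main = p.cavity_length - l_entry

    s1 = p.vestibule_length
    s2 = s1 + p.valve_length  # basal plane
    s3 = s2 + l_entry
    s4 = s3 + l_main
    s5 = s4 + p.bend_length
    s6 = s5 + p.pharynx_length

    n = max(512, int(math.ceil(s6 / _DS_FINE)))
    s = np.linspace(0.0, s6, n + 1)
    theta = np.empty_like(s)
    width = np.empty_like(s)

    # the valve is a narrow slit-like channel: the width tapers over the
    # first half of the valve segment and holds the gap over the rest, while
    # the heading turns toward the cavity floor across the whole segment
    s_taper = s1 + 0.5 * p.valve_length
    seg_theta = [
        (0.0, s1, a, a),
        (s1, s2, a, 0.0),
        (s2, s3, 0.0, arch),
        (s3, s4, arch, 0.0),
        (s4, s5, 0.0, ph),
        (s5, s6, ph, ph),
    ]
    seg_width = [
        (0.0, s1, p.vestibule_width, p.vestibule_width),
        (s1, s_taper, p.vestibule_width, p.valve_gap),
        (s_taper, s2, p.valve_gap, p.valve_gap),
        (s2, s3, p.valve_gap, p.cavity_height),
        (s3, s4, p.cavity_height, p.cavity_height),
        (s4, s5, p.cavity_height, p.pharynx_width),
        (s5, s6, p.pharynx_width, p.pharynx_width),
    ]
    for lo, hi, th0, th1 in seg_theta:
        m = (s >= lo - 1e-12) & (s <= hi + 1e-12)
        t = _cosblend((s[m] - lo) / max(hi - lo, 1e-12))
        theta[m] = th0 + (th1 - th0) * t
    for lo, hi, w0, w1 in seg_width:
        m = (s >= lo - 1e-12) & (s <= hi + 1e-12)
        t = _cosblend((s[m] - lo) / max(hi - lo, 1e-12))
        width[m] = w0 + (w1 - w0) * t

    region = np.where(s < s1, REGION_EPIDERMIS, REGION_MUCOSA)
    markers = {
        "vestibule_end": s1,
        "basal": s2,
        "entry_end": s3,
        "cavity_end": s4,
        "bend_end": s5,
        "total": s6,
    }
    return s, theta, width, region, markers


def _integrate_centerline(s: np.ndarray, theta: np.ndarray, anchor_end=None) -> np.ndarray:
    """Integrate the unit tangent along s.  If ``anchor_end`` is given the
    curve is anchored so its *last* point equals it; otherwise it starts at 0."""
    t = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    ds = np.diff(s)[:, None]
    steps = 0.5 * (t[1:] + t[:-1]) * ds
    c = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)])
    if anchor_end is not None:
        c += np.asarray(anchor_end) - c[-1]
    return c


def build_passage(params: PassageParams) -> PassageGeometry:
    """Construct the normal (unmodified) passage geometry.

    The minimum cross-section lies in the valve segment whenever
    ``valve_gap`` is smaller than the other widths; the vestibule walls are
    labelled epidermis, everything downstream mucosa.
    """
    params.validate()
    s, theta, width, region, markers = _segment_profiles(params)
    centerline = _integrate_centerline(s, theta)
    geom = PassageGeometry(
        params=params,
        variant="normal",
        s=s,
        theta=theta,
        width=width,
        region=region,
        centerline=centerline,
        markers=markers,
    )
    geom._validate_shape()
    return geom


def apply_no_valve(geometry: PassageGeometry, params: PassageParams | None = None) -> PassageGeometry:
    """Replace vestibule and valve with a straight duct, removing the constriction.

    The new duct joins the original nostril center to the basal-plane center
    with a linearly tapering width (nostril width down to the basal width),
    so the cross-section profile is monotone between nostril and basal plane
    and its minimum equals the original ``valve_gap`` (at the basal plane
    itself, no longer an interior constriction).  Cavity, bend, and pharynx
    samples are reused bit-identically.  A short cosine heading blend of
    length ``markers['junction_blend']`` immediately upstream of the basal
    plane keeps the junction mesh-able; the straight (epidermis) portion ends
    where the blend begins.
    """
    if geometry.variant != "normal":
        raise StructuralError("apply_no_valve expects a normal geometry with a valve segment")
    if "basal" not in geometry.markers:
        raise StructuralError("geometry lacks a valve segment")
    p = params or geometry.params

    s = geometry.s
    i_basal = int(np.searchsorted(s, geometry.s_basal - 1e-12))
    down_s = s[i_basal:]
    p0 = geometry.centerline[0]
    pb = geometry.centerline[i_basal]
    chord = pb - p0
    dist = float(np.hypot(*chord))
    phi = float(math.atan2(chord[1], chord[0]))
    w_nostril = float(geometry.width[0])
    w_basal = float(geometry.width[i_basal])
    theta_down0 = float(geometry.theta[i_basal])
    l_blend = min(2.0 * w_basal, 0.3 * dist)

    n_up = max(32, int(math.ceil(dist / _DS_FINE)))
    up_s = np.linspace(0.0, dist, n_up + 1)[:-1]
    up_theta = np.full_like(up_s, phi)
    in_blend = up_s > dist - l_blend
    tb = (up_s[in_blend] - (dist - l_blend)) / l_blend
    up_theta[in_blend] = phi + (theta_down0 - phi) * _cosblend(tb)
    up_width = w_nostril + (w_basal - w_nostril) * up_s / dist
    up_region = np.where(up_s < dist - l_blend, REGION_EPIDERMIS, REGION_MUCOSA)

    new_s = np.concatenate([up_s, down_s - geometry.s_basal + dist])
    new_theta = np.concatenate([up_theta, geometry.theta[i_basal:]])
    new_width = np.concatenate([up_width, geometry.width[i_basal:]])
    new_region = np.concatenate([up_region, geometry.region[i_basal:]])

    up_cl = _integrate_centerline(
        np.append(up_s, dist), np.append(up_theta, theta_down0), anchor_end=pb
    )[:-1]
    new_cl = np.vstack([up_cl, geometry.centerline[i_basal:]])

    shift = dist - geometry.s_basal
    markers = {
        k: (v + shift if k not in ("vestibule_end",) else dist - l_blend)
        for k, v in geometry.markers.items()
    }
    markers["basal"] = dist
    markers["junction_blend"] = l_blend
    markers["vestibule_heading"] = phi
    markers["vestibule_taper"] = (w_basal - w_nostril) / dist

    geom = PassageGeometry(
        params=p,
        variant="no_valve",
        s=new_s,
        theta=new_theta,
        width=new_width,
        region=new_region,
        centerline=new_cl,
        markers=markers,
        n_stations=geometry.n_stations,
    )
    geom._validate_shape()
    return geom


def apply_horizontal(geometry: PassageGeometry, tilt: float) -> PassageGeometry:
    """Tilt the straightened vestibule about the basal plane by ``tilt`` degrees.

    With ``tilt`` equal to the vestibule inclination, the lower vestibule
    surface becomes parallel to the cavity floor (the chimpanzee-like
    configuration).  Downstream samples are untouched.  Raises
    ``GeometryError`` if the rotated duct would cross the basal plane into
    the cavity or self-intersect the domain.
    """
    if geometry.variant != "no_valve":
        raise StructuralError("apply_horizontal expects a no-valve geometry")
    if not 0.0 <= tilt <= 180.0:
        raise GeometryError("tilt must lie in [0, 180] degrees")
    if tilt > geometry.vestibule_inclination() + 1e-9:
        raise GeometryError(
            "tilt exceeds the vestibule inclination: the lower vestibule "
            "surface would dip below the cavity floor"
        )
    if tilt == 0.0:
        return replace(geometry)

    s = geometry.s
    dist = geometry.s_basal
    i_basal = int(np.searchsorted(s, dist - 1e-12))
    pb = geometry.centerline[i_basal]
    phi = float(geometry.markers["vestibule_heading"]) - math.radians(tilt)
    l_blend = float(geometry.markers["junction_blend"])
    theta_down0 = float(geometry.theta[i_basal])

    up_s = s[:i_basal]
    up_theta = np.full_like(up_s, phi)
    in_blend = up_s > dist - l_blend
    tb = (up_s[in_blend] - (dist - l_blend)) / l_blend
    up_theta[in_blend] = phi + (theta_down0 - phi) * _cosblend(tb)
    up_cl = _integrate_centerline(
        np.append(up_s, dist), np.append(up_theta, theta_down0), anchor_end=pb
    )[:-1]

    # the nostril must stay on the upstream side of the basal plane
    t_basal = np.array([math.cos(theta_down0), math.sin(theta_down0)])
    if float(np.dot(up_cl[0] - pb, t_basal)) >= 0.0:
        raise GeometryError("tilt moves the vestibule across the basal plane")

    markers = dict(geometry.markers)
    markers["vestibule_heading"] = phi

    geom = PassageGeometry(
        params=geometry.params,
        variant="horizontal",
        s=s.copy(),
        theta=np.concatenate([up_theta, geometry.theta[i_basal:]]),
        width=geometry.width.copy(),
        region=geometry.region.copy(),
        centerline=np.vstack([up_cl, geometry.centerline[i_basal:]]),
        markers=markers,
        n_stations=geometry.n_stations,
    )
    geom._validate_shape()
    return geom


# ---------------------------------------------------------------------------
# structured meshing
# ---------------------------------------------------------------------------

@dataclass
class StructuredMesh:
    """Structured quadrilateral finite-volume mesh of the passage (SI metres).

    Cells are indexed (i, j) -> i * nn + j with i along the passage and j
    across it.  ``vol`` holds the cell measure (area for planar unit depth,
    radius-weighted area for axisymmetric, omitting the common 2π).  Faces
    are split into internal (owner/neighbour) and boundary (owner/patch)
    sets with precomputed geometric factors for the finite-volume operators:
    ``E`` the over-relaxed orthogonal diffusion factor |S|²/(S·d) and ``T``
    the non-orthogonal remainder S − E·d.
    """

    nodes: np.ndarray  # (ns+1, nn+1, 2)
    ns: int
    nn: int
    spacing: float  # actual streamwise step, m
    axisymmetric: bool
    cell_s: np.ndarray  # arclength of cell centers, m
    xc: np.ndarray
    vol: np.ndarray
    hoop: np.ndarray  # per-cell planar area for the axisymmetric hoop term (0 if planar)
    # internal faces
    if_owner: np.ndarray
    if_neigh: np.ndarray
    if_sf: np.ndarray
    if_cf: np.ndarray
    if_d: np.ndarray
    if_e: np.ndarray
    if_t: np.ndarray
    if_lam: np.ndarray  # owner weight for face interpolation
    # boundary faces
    bf_owner: np.ndarray
    bf_sf: np.ndarray  # outward
    bf_cf: np.ndarray
    bf_d: np.ndarray
    bf_e: np.ndarray
    bf_t: np.ndarray
    bf_patch: np.ndarray
    bf_region: np.ndarray
    bf_s: np.ndarray  # arclength of wall faces, m

    @property
    def n_cells(self) -> int:
        return self.ns * self.nn

    @property
    def total_length(self) -> float:
        return float(self.cell_s.max() + 0.5 * self.spacing)

    def patch_faces(self, patch: int) -> np.ndarray:
        return np.flatnonzero(self.bf_patch == patch)

    @property
    def wall_faces(self) -> np.ndarray:
        return np.flatnonzero(
            (self.bf_patch == PATCH_WALL_LOWER) | (self.bf_patch == PATCH_WALL_UPPER)
        )

    def closure_error(self) -> float:
        """Max per-cell |Σ outward face area vectors| — watertightness check.

        For axisymmetric meshes the radius-weighted face areas of a closed
        cell sum to the hoop area in the radial direction, which is
        subtracted before testing closure.
        """
        acc = np.zeros((self.n_cells, 2))
        np.add.at(acc, self.if_owner, self.if_sf)
        np.add.at(acc, self.if_neigh, -self.if_sf)
        np.add.at(acc, self.bf_owner, self.bf_sf)
        acc[:, 1] -= self.hoop
        return float(np.max(np.hypot(acc[:, 0], acc[:, 1])))

    def cell_field_grid(self, values: np.ndarray) -> np.ndarray:
        """Reshape a flat per-cell array to (ns, nn)."""
        return np.asarray(values).reshape(self.ns, self.nn)


def _face_geometry(a: np.ndarray, b: np.ndarray, x_from: np.ndarray, x_to: np.ndarray):
    """Area vector (oriented from->to), centroid for faces with node rows a, b."""
    e = b - a
    sf = np.stack([e[:, 1], -e[:, 0]], axis=1)
    flip = np.einsum("ij,ij->i", sf, x_to - x_from) < 0.0
    sf[flip] *= -1.0
    cf = 0.5 * (a + b)
    return sf, cf


def mesh_passage(geometry: PassageGeometry, spacing: float) -> StructuredMesh:
    """Discretize the passage with nominal spacing (mm).

    The spacing must resolve the narrowest opening with at least four cells
    (spacing < min width / 4), mirroring the resolution-independence contract
    of the underlying model; otherwise ``ResolutionError`` is raised.
    """
    w_min = float(np.min(geometry.width))
    if not spacing > 0.0:
        raise ResolutionError("spacing must be positive")
    if spacing >= w_min / 4.0:
        raise ResolutionError(
            f"spacing {spacing} mm too coarse for the narrowest opening "
            f"{w_min} mm (need spacing < {w_min / 4.0:.3f} mm)"
        )
    axisym = geometry.params.dimensionality == "axisymmetric"
    if axisym:
        if np.max(np.abs(geometry.theta)) > 1e-12:
            raise ParameterError("axisymmetric meshing requires a straight passage")

    total = geometry.total_length
    ns = max(2, int(round(total / spacing)))
    nn = max(4, int(math.ceil(np.max(geometry.width) / spacing)))
    s_nodes = np.linspace(0.0, total, ns + 1)

    cx = np.interp(s_nodes, geometry.s, geometry.centerline[:, 0])
    cy = np.interp(s_nodes, geometry.s, geometry.centerline[:, 1])
    th = np.interp(s_nodes, geometry.s, geometry.theta)
    w = np.interp(s_nodes, geometry.s, geometry.width)

    eta = np.linspace(0.0, 1.0, nn + 1)
    if axisym:
        # transverse coordinate is radius 0..w/2; width is the duct diameter
        x = cx[:, None] + np.zeros_like(eta)[None, :]
        y = eta[None, :] * (0.5 * w)[:, None]
    else:
        nx, ny = -np.sin(th), np.cos(th)
        off = (eta - 0.5)[None, :] * w[:, None]
        x = cx[:, None] + nx[:, None] * off
        y = cy[:, None] + ny[:, None] * off
    nodes = np.stack([x, y], axis=2) * 1e-3  # mm -> m

    # cell centroids and areas (shoelace on each quad)
    p00 = nodes[:-1, :-1]
    p10 = nodes[1:, :-1]
    p11 = nodes[1:, 1:]
    p01 = nodes[:-1, 1:]
    cross = lambda u, v: u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    area = 0.5 * (cross(p10 - p00, p11 - p00) + cross(p11 - p00, p01 - p00))
    if np.any(area <= 0.0):
        raise GeometryError("mesh contains non-positive cell areas")
    xc = 0.25 * (p00 + p10 + p11 + p01)
    vol = area.copy()
    hoop = np.zeros_like(area)
    if axisym:
        vol *= np.abs(xc[..., 1])
        hoop = area.copy()

    cell_s = np.interp(
        0.5 * (s_nodes[:-1] + s_nodes[1:]), geometry.s, geometry.s
    )  # midpoint arclength, mm
    cell_s = np.repeat(cell_s[:, None], nn, axis=1) * 1e-3

    cid = np.arange(ns * nn).reshape(ns, nn)
    xc_flat = xc.reshape(-1, 2)
    vol_flat = vol.reshape(-1)

    # --- internal faces ---
    # i-faces between (i-1, j) and (i, j): nodes (i, j) - (i, j+1)
    ia = nodes[1:-1, :-1].reshape(-1, 2)
    ib = nodes[1:-1, 1:].reshape(-1, 2)
    iow = cid[:-1, :].reshape(-1)
    ine = cid[1:, :].reshape(-1)
    # j-faces between (i, j-1) and (i, j): nodes (i, j) - (i+1, j)
    ja = nodes[:-1, 1:-1].transpose(0, 1, 2).reshape(-1, 2)
    jb = nodes[1:, 1:-1].reshape(-1, 2)
    jow = cid[:, :-1].reshape(-1)
    jne = cid[:, 1:].reshape(-1)

    own = np.concatenate([iow, jow])
    nei = np.concatenate([ine, jne])
    fa = np.vstack([ia, ja])
    fb = np.vstack([ib, jb])
    sf, cf = _face_geometry(fa, fb, xc_flat[own], xc_flat[nei])
    if axisym:
        sf = sf * np.abs(cf[:, 1:2])
    d = xc_flat[nei] - xc_flat[own]
    sd = np.einsum("ij,ij->i", sf, d)
    e = np.einsum("ij,ij->i", sf, sf) / np.where(np.abs(sd) > 1e-300, sd, 1e-300)
    tvec = sf - e[:, None] * d
    dpf = np.hypot(*(cf - xc_flat[own]).T)
    dnf = np.hypot(*(cf - xc_flat[nei]).T)
    lam = dnf / (dpf + dnf)

    # --- boundary faces ---
    b_nodes_a, b_nodes_b, b_owner, b_patch, b_sidx = [], [], [], [], []

    def add_patch(a, b, owner, patch, sidx):
        b_nodes_a.append(a)
        b_nodes_b.append(b)
        b_owner.append(owner)
        b_patch.append(np.full(owner.shape, patch))
        b_sidx.append(sidx)

    smid = 0.5 * (s_nodes[:-1] + s_nodes[1:]) * 1e-3  # m
    add_patch(nodes[0, :-1], nodes[0, 1:], cid[0, :], PATCH_INLET,
              np.zeros(nn))
    add_patch(nodes[-1, :-1], nodes[-1, 1:], cid[-1, :], PATCH_OUTLET,
              np.full(nn, total * 1e-3))
    lower_patch = PATCH_AXIS if axisym else PATCH_WALL_LOWER
    add_patch(nodes[:-1, 0], nodes[1:, 0], cid[:, 0], lower_patch, smid)
    add_patch(nodes[:-1, -1], nodes[1:, -1], cid[:, -1], PATCH_WALL_UPPER, smid)

    ba = np.vstack(b_nodes_a)
    bb = np.vstack(b_nodes_b)
    bow = np.concatenate(b_owner)
    bpatch = np.concatenate(b_patch).astype(int)
    bs = np.concatenate(b_sidx)
    bsf, bcf = _face_geometry(ba, bb, xc_flat[bow], 2.0 * 0.5 * (ba + bb) - xc_flat[bow])
    if axisym:
        bsf = bsf * np.abs(bcf[:, 1:2])
    bd = bcf - xc_flat[bow]
    bsd = np.einsum("ij,ij->i", bsf, bd)
    be = np.einsum("ij,ij->i", bsf, bsf) / np.where(np.abs(bsd) > 1e-300, bsd, 1e-300)
    bt = bsf - be[:, None] * bd

    # wall region labels by arclength
    region_at = lambda sm: np.interp(sm * 1e3, geometry.s, geometry.region.astype(float))
    bregion = np.full(bow.shape, REGION_NONE)
    is_wall = (bpatch == PATCH_WALL_LOWER) | (bpatch == PATCH_WALL_UPPER)
    bregion[is_wall] = np.where(region_at(bs[is_wall]) < 0.5, REGION_EPIDERMIS, REGION_MUCOSA)

    return StructuredMesh(
        nodes=nodes,
        ns=ns,
        nn=nn,
        spacing=total / ns * 1e-3,
        axisymmetric=axisym,
        cell_s=cell_s.reshape(-1),
        xc=xc_flat,
        vol=vol_flat,
        hoop=hoop.reshape(-1),
        # note: stored spacing is the ACTUAL streamwise step (total/ns)
        if_owner=own,
        if_neigh=nei,
        if_sf=sf,
        if_cf=cf,
        if_d=d,
        if_e=e,
        if_t=tvec,
        if_lam=lam,
        bf_owner=bow,
        bf_sf=bsf,
        bf_cf=bcf,
        bf_d=bd,
        bf_e=be,
        bf_t=bt,
        bf_patch=bpatch,
        bf_region=bregion,
        bf_s=bs,
    )


def random_params(seed: int | np.random.Generator, max_tries: int = 200) -> PassageParams:
    """Draw a random valid parameter set (planar), rejecting draws whose
    curvature/width combination would fold the inner wall."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    for _ in range(max_tries):
        w_v = rng.uniform(5.0, 8.0)
        params = PassageParams(
            vestibule_angle=rng.uniform(0.0, 90.0),
            vestibule_length=rng.uniform(10.0, 20.0),
            vestibule_width=w_v,
            valve_gap=rng.uniform(2.5, 0.8 * w_v),
            valve_length=rng.uniform(8.0, 12.0),
            cavity_length=rng.uniform(35.0, 60.0),
            cavity_height=rng.uniform(10.0, 16.0),
            cavity_arch=rng.uniform(0.0, 30.0),
            bend_length=rng.uniform(16.0, 22.0),
            pharynx_length=rng.uniform(10.0, 18.0),
            pharynx_width=rng.uniform(6.0, 9.0),
        )
        try:
            build_passage(params)
        except (ParameterError, GeometryError):
            continue
        return params
    raise RuntimeError("could not draw valid passage parameters")
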