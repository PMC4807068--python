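"""Conditioning-performance metrics: station profiles, summaries, cohorts.

Air-conditioning performance is read off the converged fields at ordered
cross-section stations from the nares to the nasopharynx: per station the
extremum of temperature and water mass fraction over the cross-section, and
at the final (nasopharyngeal) station the summary triple (T, MF, RH34) that
the cohort tables aggregate.  For the warm-wet and cold-dry conditions the
reported temperature is the station minimum (approach to 34 °C from below);
for hot-dry it is the maximum (approach from above).  RH34 expresses the
lowest water mass fraction as a percentage of 3.34%, the saturation value
at 34 °C.

Cohort averages are arithmetic means of the unrounded per-subject values;
RH34 of the average is derived from the unrounded mean MF.  Presentation
rounding (one decimal for T and RH34, two for MF) uses decimal half-even
and is applied only at formatting time.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.interpolate import LinearNDInterpolator

from .flow_solver import FlowField
from .geometry import PATCH_INLET, PATCH_OUTLET, PassageGeometry, StructuredMesh
from .psychro import SATURATION_MF_34C, rh34
from .transport import ScalarFields

__all__ = [
    "ConditioningProfile",
    "CohortSummary",
    "extract_profile",
    "nasopharyngeal_summary",
    "cohort_average",
    "present",
    "seed_streamlines",
    "mean_path",
    "curvature_sign_changes",
    "initial_heading",
    "station_max_speed",
]


@dataclass
class ConditioningProfile:
    """Per-station extrema along the passage (stations in mm from the nares)."""

    stations: np.ndarray
    lowest_temperature: np.ndarray
    highest_temperature: np.ndarray
    lowest_mass_fraction: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        if len(self.stations) < 2:
            raise ValueError("a profile needs at least two stations")

    @property
    def rh34(self) -> np.ndarray:
        return 100.0 * self.lowest_mass_fraction / SATURATION_MF_34C

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "station_mm": self.stations,
                "lowest_T": self.lowest_temperature,
                "highest_T": self.highest_temperature,
                "lowest_MF": self.lowest_mass_fraction,
                "RH34": self.rh34,
            }
        )


def extract_profile(
    fields: ScalarFields,
    mesh: StructuredMesh,
    geometry: PassageGeometry,
    condition: str = "",
) -> ConditioningProfile:
    """Per-station extrema of T and F over cross-section bands of one cell width.

    Stations are the geometry's ordered cross-section stations (the last one
    is the nasopharyngeal level).  Cells whose center arclength falls within
    half a nominal spacing of a station contribute to it."""
    stations = geometry.section_stations  # mm
    s_cells = mesh.cell_s * 1e3  # mm
    half = 0.5 * mesh.spacing * 1e3 + 1e-9
    lo_t, hi_t, lo_f = [], [], []
    for s_k in stations:
        if s_k < -1e-9 or s_k > geometry.total_length + 1e-9:
            raise ValueError(f"station {s_k} mm outside the passage")
        band = np.abs(s_cells - np.clip(s_k, s_cells.min(), s_cells.max())) <= half
        if not np.any(band):
            raise ValueError(f"no cells intersect station {s_k} mm")
        lo_t.append(float(fields.temperature[band].min()))
        hi_t.append(float(fields.temperature[band].max()))
        lo_f.append(float(fields.water_fraction[band].min()))
    return ConditioningProfile(
        stations=np.asarray(stations),
        lowest_temperature=np.asarray(lo_t),
        highest_temperature=np.asarray(hi_t),
        lowest_mass_fraction=np.asarray(lo_f),
        condition=condition or (fields.inlet.label if fields.inlet else ""),
    )


def nasopharyngeal_summary(profile: ConditioningProfile) -> tuple[float, float, float]:
    """(T, MF, RH34) at the nasopharyngeal (last) station.

    T is the station minimum except under the hot-dry condition, where the
    extremum approaching 34 °C is the maximum."""
    if len(profile.stations) == 0:
        raise ValueError("empty profile")
    if profile.condition == "hot_dry":
        t = float(profile.highest_temperature[-1])
    else:
        t = float(profile.lowest_temperature[-1])
    mf = float(profile.lowest_mass_fraction[-1])
    return t, mf, rh34(mf)


def present(value: float, decimals: int) -> float:
    """Decimal half-even presentation rounding (applied only at formatting)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(str(value)).quantize(q, rounding=ROUND_HALF_EVEN))


@dataclass
class CohortSummary:
    """Per-subject nasopharyngeal triples plus their arithmetic mean.

    The mean RH34 is recomputed from the unrounded mean MF (not averaged
    from the per-subject RH34 values)."""

    subjects: list[tuple[float, float, float]]
    mean_temperature: float
    mean_mass_fraction: float
    mean_rh34: float

    def formatted(self) -> tuple[float, float, float]:
        return (
            present(self.mean_temperature, 1),
            present(self.mean_mass_fraction, 2),
            present(self.mean_rh34, 1),
        )

    def to_frame(self, labels: list[str] | None = None) -> pd.DataFrame:
        labels = labels or [f"subject {i + 1}" for i in range(len(self.subjects))]
        rows = [
            {
                "subject": lab,
                "T": present(t, 1),
                "MF": present(mf, 2),
                "RH34": present(r, 1),
            }
            for lab, (t, mf, r) in zip(labels, self.subjects)
        ]
        ft, fmf, fr = self.formatted()
        rows.append({"subject": "Average", "T": ft, "MF": fmf, "RH34": fr})
        return pd.DataFrame(rows)


def cohort_average(summaries: list[tuple[float, float, float]]) -> CohortSummary:
    """Arithmetic cohort mean of per-subject (T, MF, RH34) triples.

    Means are taken in exact decimal arithmetic of the given values; RH34 of
    the average is derived from the unrounded mean MF."""
    if not summaries:
        raise ValueError("cohort_average needs at least one subject")
    n = len(summaries)
    mean_t = float(sum(Decimal(str(t)) for t, _, _ in summaries) / n)
    mean_mf = float(sum(Decimal(str(mf)) for _, mf, _ in summaries) / n)
    return CohortSummary(
        subjects=list(summaries),
        mean_temperature=mean_t,
        mean_mass_fraction=mean_mf,
        mean_rh34=rh34(mean_mf),
    )


# ---------------------------------------------------------------------------
# streamlines
# ---------------------------------------------------------------------------

def _velocity_interpolator(flow: FlowField, mesh: StructuredMesh):
    """Linear interpolant of the velocity over cell centers and boundary faces."""
    u_b = np.zeros((len(mesh.bf_patch), 2))
    free = (mesh.bf_patch == PATCH_INLET) | (mesh.bf_patch == PATCH_OUTLET)
    u_b[free] = flow.u[mesh.bf_owner[free]]
    pts = np.vstack([mesh.xc, mesh.bf_cf])
    vals = np.vstack([flow.u, u_b])
    return LinearNDInterpolator(pts, vals, fill_value=np.nan)


def seed_streamlines(
    flow: FlowField,
    mesh: StructuredMesh,
    geometry: PassageGeometry,
    density_constant: float = 5.0,
    max_steps: int = 4000,
) -> list[np.ndarray]:
    """Integrate streamlines from seeds distributed over the nostril plane.

    The streamline count is ``round(density_constant × inlet area)`` with
    the inlet area in mm² per unit depth (i.e. the nostril width in mm for
    the planar model), so the bundle size reflects the relative airflow
    volume.  Seeds are uniform across the inlet patch; each line is
    integrated with an adaptive Runge-Kutta scheme until it leaves the
    domain or the step limit is reached.  A zero velocity field yields an
    empty list with a warning.
    """
    if not flow.converged:
        raise ValueError("seed_streamlines requires a converged flow")
    inlet = mesh.patch_faces(PATCH_INLET)
    area_mm = float(np.sum(np.hypot(mesh.bf_sf[inlet, 0], mesh.bf_sf[inlet, 1]))) * 1e3
    count = int(round(density_constant * area_mm))
    if np.max(np.abs(flow.u)) == 0.0 or count == 0:
        import warnings

        warnings.warn("zero velocity field: no streamlines seeded", stacklevel=2)
        return []

    # seed positions: uniform between the inlet line endpoints, nudged inside
    ends = mesh.nodes[0, [0, -1]]
    frac = (np.arange(count) + 0.5) / count
    seeds = ends[0] + frac[:, None] * (ends[1] - ends[0])
    interp = _velocity_interpolator(flow, mesh)
    inward = mesh.xc[mesh.bf_owner[inlet][len(inlet) // 2]] - mesh.bf_cf[inlet][len(inlet) // 2]
    inward = inward / np.hypot(*inward)
    seeds = seeds + 0.25 * mesh.spacing * inward

    u_ref = max(float(np.median(np.hypot(*flow.u.T))), 1e-12)
    length = geometry.total_length * 1e-3
    t_max = 10.0 * length / u_ref

    def rhs(_t, xy):
        v = np.asarray(interp(xy[0], xy[1])).reshape(-1)
        return np.zeros(2) if np.any(np.isnan(v)) else v

    def leaving(_t, xy):
        v = np.asarray(interp(xy[0], xy[1])).reshape(-1)
        if np.any(np.isnan(v)):
            return 0.0
        return float(np.hypot(v[0], v[1]) - 1e-6 * u_ref)

    leaving.terminal = True
    lines = []
    for s0 in seeds:
        sol = solve_ivp(
            rhs,
            (0.0, t_max),
            s0,
            events=leaving,
            max_step=t_max / max_steps,
            rtol=1e-6,
            atol=1e-9 * length,
        )
        if sol.y.shape[1] >= 2:
            lines.append(sol.y.T.copy())
    return lines


def station_max_speed(
    flow: FlowField,
    mesh: StructuredMesh,
    geometry: PassageGeometry,
    fractions: tuple = (0.3, 0.5, 0.8),
    n_samples: int = 64,
) -> np.ndarray:
    """Maximum flow speed over fixed cross-section sample points.

    Samples are placed on the geometric cross-section lines (independent of
    the mesh), so values from solutions on different grids are directly
    comparable — the basis of the mesh-independence check."""
    interp = _velocity_interpolator(flow, mesh)
    out = []
    span = np.linspace(-0.49, 0.49, n_samples)
    for fr in fractions:
        s_k = fr * geometry.total_length
        i = min(int(np.searchsorted(geometry.s, s_k)), len(geometry.s) - 1)
        c, th, w = geometry.centerline[i], geometry.theta[i], geometry.width[i]
        nvec = np.array([-np.sin(th), np.cos(th)])
        pts = (c[None, :] + nvec[None, :] * (span * w)[:, None]) * 1e-3
        v = interp(pts[:, 0], pts[:, 1])
        out.append(float(np.nanmax(np.hypot(v[:, 0], v[:, 1]))))
    return np.array(out)


def mean_path(streamlines: list[np.ndarray], n_samples: int = 200) -> np.ndarray:
    """Average of the bundle, resampled by normalized arclength."""
    if not streamlines:
        raise ValueError("no streamlines to average")
    resampled = []
    for line in streamlines:
        seg = np.hypot(*np.diff(line, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        if s[-1] <= 0.0:
            continue
        tgrid = np.linspace(0.0, s[-1], n_samples)
        resampled.append(
            np.stack([np.interp(tgrid, s, line[:, 0]), np.interp(tgrid, s, line[:, 1])], axis=1)
        )
    return np.mean(resampled, axis=0)


def _turn_events(path: np.ndarray, min_turn_deg: float = 8.0, trim_tail: float = 0.05) -> list[float]:
    """Net signed turns (deg) of consecutive same-sign curvature stretches.

    The last ``trim_tail`` fraction of the path is dropped: bundle averaging
    near the outlet (where lines terminate at slightly different lengths)
    produces spurious wiggles there."""
    if trim_tail > 0.0:
        path = path[: max(3, int(len(path) * (1.0 - trim_tail)))]
    d = np.diff(path, axis=0)
    keep = np.hypot(*d.T) > 1e-12
    heading = np.unwrap(np.arctan2(d[keep, 1], d[keep, 0]))
    turns = np.degrees(np.diff(heading))
    events, acc = [], 0.0
    for t in turns:
        if acc == 0.0 or np.sign(t) == np.sign(acc) or t == 0.0:
            acc += t
        else:
            if abs(acc) >= min_turn_deg:
                events.append(acc)
            acc = t
    if abs(acc) >= min_turn_deg:
        events.append(acc)
    # merge consecutive same-sign events left after thresholding
    merged: list[float] = []
    for e in events:
        if merged and np.sign(merged[-1]) == np.sign(e):
            merged[-1] += e
        else:
            merged.append(e)
    return merged


def curvature_sign_changes(path: np.ndarray, min_turn_deg: float = 8.0) -> int:
    """Number of sign alternations of the path's signed curvature.

    Small wiggles (net turn below ``min_turn_deg``) are ignored.  The
    human-like passage gives two alternations (backward over the valve,
    arching up into the cavity, down to the pharynx); a horizontal
    chimpanzee-like duct gives none or one.
    """
    events = _turn_events(path, min_turn_deg)
    return max(0, len(events) - 1)


def initial_heading(path: np.ndarray, fraction: float = 0.2) -> float:
    """Mean heading (degrees) over the first ``fraction`` of the path —
    the vestibular flow direction."""
    n = max(2, int(len(path) * fraction))
    d = path[n - 1] - path[0]
    return float(np.degrees(np.arctan2(d[1], d[0])))
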