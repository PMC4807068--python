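"""Passage construction, virtual variants, and structured meshing."""

import dataclasses

import numpy as np
import pytest
from shapely.geometry import LineString

from nasocond import geometry as G
from tests.conftest import straight_channel_params


def section_widths_from_boundary(geom, n=200):
    """Independent cross-section sweep: measure the channel opening by
    intersecting wall-normal lines with the boundary polygon."""
    lower, upper = geom.boundary_polylines()
    idx = np.linspace(5, len(geom.s) - 6, n).astype(int)
    widths = []
    for i in idx:
        widths.append(float(np.hypot(*(upper[i] - lower[i]))))
    return geom.s[idx], np.array(widths)


class TestBuildPassage:
    def test_uniform_channel_has_constant_section(self):
        geom = G.build_passage(straight_channel_params(6.0))
        s, w = section_widths_from_boundary(geom)
        assert np.allclose(w, 6.0, atol=1e-9)

    def test_human_like_minimum_lies_in_valve_segment(self, human_geom):
        s, w = section_widths_from_boundary(human_geom, n=500)
        s_min = s[np.argmin(w)]
        step = s[1] - s[0]
        assert human_geom.markers["vestibule_end"] - step <= s_min <= human_geom.s_basal + step
        assert np.min(w) == pytest.approx(human_geom.params.valve_gap, rel=0.01)

    def test_zero_valve_gap_rejected(self):
        with pytest.raises(G.ParameterError):
            G.build_passage(dataclasses.replace(G.PASSAGE_PRESETS["human_like"], valve_gap=0.0))

    def test_gap_wider_than_vestibule_rejected(self):
        with pytest.raises(G.ParameterError):
            G.build_passage(
                dataclasses.replace(G.PASSAGE_PRESETS["human_like"], valve_gap=20.0)
            )

    def test_boundary_is_simple_polygon(self, human_geom, chimp_geom):
        for geom in (human_geom, chimp_geom):
            assert geom.polygon().is_valid

    def test_epidermis_length_equals_vestibule_length(self, human_geom):
        s = human_geom.s
        epi = human_geom.region == G.REGION_EPIDERMIS
        ds = np.diff(s)
        epi_len = float(np.sum(ds[epi[:-1]]))
        assert epi_len == pytest.approx(human_geom.params.vestibule_length, abs=2 * (s[1] - s[0]))


class TestNoValve:
    def test_profile_linear_between_nostril_and_basal_plane(self, human_geom):
        nv = G.apply_no_valve(human_geom)
        mask = nv.s <= nv.s_basal + 1e-9
        s, w = nv.s[mask], nv.width[mask]
        w_lin = np.interp(s, [0.0, nv.s_basal], [w[0], nv.params.valve_gap])
        assert np.allclose(w, w_lin, atol=1e-9)
        assert np.all(np.diff(w) <= 1e-12)  # monotone taper
        assert w.min() >= nv.params.valve_gap - 1e-9  # constriction removed

    def test_downstream_boundaries_bit_identical(self, human_geom):
        nv = G.apply_no_valve(human_geom)
        i0 = int(np.searchsorted(human_geom.s, human_geom.s_basal - 1e-12))
        i1 = int(np.searchsorted(nv.s, nv.s_basal - 1e-12))
        assert np.array_equal(human_geom.centerline[i0:], nv.centerline[i1:])
        assert np.array_equal(human_geom.width[i0:], nv.width[i1:])
        assert np.array_equal(human_geom.theta[i0:], nv.theta[i1:])

    def test_straight_geometry_is_fixed_point(self):
        geom = G.build_passage(straight_channel_params(6.0))
        nv = G.apply_no_valve(geom)
        assert nv.total_length == pytest.approx(geom.total_length, rel=1e-6)
        np.testing.assert_allclose(
            np.interp(geom.s, nv.s, nv.width), geom.width, atol=1e-9
        )

    def test_requires_normal_geometry(self, human_geom):
        nv = G.apply_no_valve(human_geom)
        with pytest.raises(G.StructuralError):
            G.apply_no_valve(nv)


class TestHorizontal:
    def test_full_tilt_levels_the_lower_surface(self, human_geom):
        nv = G.apply_no_valve(human_geom)
        hz = G.apply_horizontal(nv, nv.vestibule_inclination())
        lower, _ = hz.boundary_polylines()
        i_end = int(np.searchsorted(hz.s, hz.markers["vestibule_end"] - 1e-9))
        seg = lower[5:i_end - 5]
        angles = np.arctan2(*np.diff(seg, axis=0).T[::-1])
        assert np.max(np.abs(angles)) < 1e-6  # parallel to the cavity floor

    def test_zero_tilt_is_identity(self, human_geom):
        nv = G.apply_no_valve(human_geom)
        hz = G.apply_horizontal(nv, 0.0)
        np.testing.assert_array_equal(hz.centerline, nv.centerline)
        assert hz.variant == nv.variant

    def test_excess_tilt_rejected(self, human_geom):
        nv = G.apply_no_valve(human_geom)
        with pytest.raises(G.GeometryError):
            G.apply_horizontal(nv, nv.vestibule_inclination() + 90.0)

    def test_requires_no_valve_geometry(self, human_geom):
        with pytest.raises(G.StructuralError):
            G.apply_horizontal(human_geom, 30.0)

    def test_horizontal_after_no_valve_keeps_downstream(self, human_geom):
        nv = G.apply_no_valve(human_geom)
        hz = G.apply_horizontal(nv, nv.vestibule_inclination())
        i = int(np.searchsorted(nv.s, nv.s_basal - 1e-12))
        assert np.array_equal(nv.centerline[i:], hz.centerline[i:])


class TestMeshing:
    def test_uniform_channel_cell_count(self):
        geom = G.build_passage(straight_channel_params(6.0, length_mm=100.0))
        mesh = G.mesh_passage(geom, 1.0)
        assert abs(mesh.ns - 100) <= 1
        assert abs(mesh.nn - 6) <= 1

    def test_too_coarse_spacing_rejected(self, human_geom):
        gap = human_geom.params.valve_gap
        with pytest.raises(G.ResolutionError):
            G.mesh_passage(human_geom, gap)
        with pytest.raises(G.ResolutionError):
            G.mesh_passage(human_geom, gap / 4.0)

    def test_watertight_and_positive_measure(self, human_mesh):
        assert human_mesh.vol.min() > 0.0
        assert human_mesh.closure_error() < 1e-12

    def test_boundary_faces_carry_exactly_one_patch_label(self, human_mesh):
        patches = {G.PATCH_INLET, G.PATCH_OUTLET, G.PATCH_WALL_LOWER, G.PATCH_WALL_UPPER, G.PATCH_AXIS}
        assert set(np.unique(human_mesh.bf_patch)) <= patches
        walls = human_mesh.wall_faces
        assert set(np.unique(human_mesh.bf_region[walls])) == {
            G.REGION_EPIDERMIS,
            G.REGION_MUCOSA,
        }
        non_walls = np.setdiff1d(np.arange(len(human_mesh.bf_patch)), walls)
        assert np.all(human_mesh.bf_region[non_walls] == G.REGION_NONE)

    def test_wall_region_split_matches_geometry(self, human_geom, human_mesh):
        walls = human_mesh.wall_faces
        epi = human_mesh.bf_region[walls] == G.REGION_EPIDERMIS
        s_mm = human_mesh.bf_s[walls] * 1e3
        cut = human_geom.markers["vestibule_end"]
        assert np.all(s_mm[epi] <= cut + 1e-6)
        assert np.all(s_mm[~epi] >= cut - 1e-6)

    def test_axisymmetric_mesh_has_axis_patch(self):
        geom = G.build_passage(straight_channel_params(6.0, axisymmetric=True))
        mesh = G.mesh_passage(geom, 0.7)
        assert mesh.axisymmetric
        assert len(mesh.patch_faces(G.PATCH_AXIS)) == mesh.ns
        assert mesh.closure_error() < 1e-12

    def test_random_draws_all_mesh_watertight(self, rng):
        """1,000 random valid parameter draws build positive, watertight meshes."""
        for _ in range(1000):
            params = G.random_params(rng)
            geom = G.build_passage(params)
            mesh = G.mesh_passage(geom, min(0.9 * params.valve_gap / 4.0, 1.0))
            assert mesh.vol.min() > 0.0
            assert mesh.closure_error() < 1e-12
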