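"""Shared fixtures: geometries, meshes, and cached flow/transport solves.

Flow solves are session-scoped because several test modules interrogate the
same converged fields; the meshes are kept deliberately coarse (0.7 mm
nominal spacing) so the whole suite runs on one CPU in a few minutes.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from nasocond.flow_solver import FluidProperties, SolverTolerances, solve_steady_flow
from nasocond.geometry import (
    PASSAGE_PRESETS,
    PassageParams,
    apply_horizontal,
    apply_no_valve,
    build_passage,
    mesh_passage,
)
from nasocond.psychro import AMBIENT_PRESETS
from nasocond.transport import solve_scalar_transport
from nasocond.wall_model import WallProperties

SPACING = 0.7  # mm, test-suite default


def straight_channel_params(height_mm: float, length_mm: float = 100.0, axisymmetric=False):
    """Uniform straight channel (or pipe, where height is the diameter)."""
    seg = length_mm / 5.0
    return PassageParams(
        dimensionality="axisymmetric" if axisymmetric else "planar",
        vestibule_angle=0.0,
        vestibule_length=seg,
        vestibule_width=height_mm,
        valve_gap=height_mm,
        valve_length=seg,
        cavity_length=2.0 * seg,
        cavity_height=height_mm,
        cavity_arch=0.0,
        bend_length=0.5 * seg,
        pharynx_length=0.5 * seg,
        pharynx_width=height_mm,
        pharynx_angle=0.0,
    )


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def wallprops():
    return WallProperties()


@pytest.fixture(scope="session")
def human_geom():
    return build_passage(PASSAGE_PRESETS["human_like"])


@pytest.fixture(scope="session")
def chimp_geom():
    return build_passage(PASSAGE_PRESETS["chimp_like"])


@pytest.fixture(scope="session")
def human_mesh(human_geom):
    return mesh_passage(human_geom, SPACING)


@pytest.fixture(scope="session")
def chimp_mesh(chimp_geom):
    return mesh_passage(chimp_geom, SPACING)


@pytest.fixture(scope="session")
def human_flow(human_mesh, fluid):
    return solve_steady_flow(human_mesh, fluid, 0.2)


@pytest.fixture(scope="session")
def chimp_flow(chimp_mesh, fluid):
    return solve_steady_flow(chimp_mesh, fluid, 0.2)


@pytest.fixture(scope="session")
def no_valve_case(human_geom, fluid):
    geom = apply_no_valve(human_geom)
    mesh = mesh_passage(geom, SPACING)
    return geom, mesh, solve_steady_flow(mesh, fluid, 0.2)


@pytest.fixture(scope="session")
def horizontal_case(human_geom, fluid):
    nv = apply_no_valve(human_geom)
    geom = apply_horizontal(nv, nv.vestibule_inclination())
    mesh = mesh_passage(geom, SPACING)
    return geom, mesh, solve_steady_flow(mesh, fluid, 0.2)


@pytest.fixture(scope="session")
def half_cavity_case(fluid):
    base = PASSAGE_PRESETS["human_like"]
    params = dataclasses.replace(base, cavity_length=base.cavity_length / 2.0)
    geom = build_passage(params)
    mesh = mesh_passage(geom, SPACING)
    return geom, mesh, solve_steady_flow(mesh, fluid, 0.2)


@pytest.fixture(scope="session")
def human_cold_dry(human_mesh, human_flow, fluid, wallprops):
    return solve_scalar_transport(
        human_mesh, human_flow, fluid, wallprops, AMBIENT_PRESETS["cold_dry"]
    )


@pytest.fixture(scope="session")
def human_equilibrium(human_mesh, human_flow, fluid, wallprops):
    return solve_scalar_transport(
        human_mesh, human_flow, fluid, wallprops, AMBIENT_PRESETS["equilibrium"]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20160324)
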