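"""Shared fixtures: a small, fast gyrus for unit tests and the full-size
reference fixture (computed once per session) for the headline checks."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

import gyrusim as gs
from gyrusim import activation as act
from gyrusim.fem import MaterialField
from gyrusim.flattening import flatten
from gyrusim.geometry import Mesh

warnings.filterwarnings("ignore", message="target_edge")


SMALL = dict(domain_width=6.0, domain_height=8.0, cortical_thickness=1.2,
             fold_amplitude=2.0, fold_wavelength=4.8, base_height=2.0,
             n_segments_per_layer=8, seed=1)


@pytest.fixture(scope="session")
def small_geometry():
    geom = gs.generate_gyrus(gs.GyrusConfig(**SMALL))
    geom.validate()
    return geom


@pytest.fixture(scope="session")
def small_mesh(small_geometry):
    return gs.triangulate(small_geometry, 0.25)


@pytest.fixture(scope="session")
def small_materials(small_mesh):
    return MaterialField.from_regions(small_mesh)


@pytest.fixture(scope="session")
def small_flattening(small_mesh, small_materials):
    return flatten(small_mesh, small_materials, n_steps=12)


@pytest.fixture(scope="session")
def small_runs(small_mesh, small_materials, small_flattening):
    """The three 10% scenarios on the small fixture, shared prestress."""
    prestress = small_flattening.prestress
    fixture = act.solve_baseline(small_mesh, small_materials, prestress, 2)
    runs = {}
    for scenario in ("stiffness", "volume", "combined"):
        spec = act._scenario_spec(scenario, 0.10)
        spec.use_prestress = True
        runs[scenario] = act.run_scenario(
            small_mesh, small_materials, prestress, spec,
            n_increments=2, fixture=fixture)
    return runs


def rect_mesh(n: int, lx: float = 1.0, ly: float = 1.0) -> Mesh:
    """Structured unit-square-style mesh used by the patch tests."""
    xs = np.linspace(0, lx, n + 1)
    ys = np.linspace(0, ly, n + 1)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel()])
    tris = []
    for j in range(n):
        for i in range(n):
            a = j * (n + 1) + i
            b, c, d = a + 1, a + n + 1, a + n + 2
            if (i + j) % 2 == 0:
                tris += [[a, b, d], [a, d, c]]
            else:
                tris += [[a, b, c], [b, d, c]]
    tris = np.asarray(tris)
    m = len(tris)
    return Mesh(
        nodes=nodes, triangles=tris,
        element_labels=np.array(["WM"] * m, dtype=object),
        element_layer=np.zeros(m, dtype=int),
        element_segment=np.zeros(m, dtype=int),
        boundary_tags={
            "domain_exterior": np.unique(np.concatenate([
                np.flatnonzero(nodes[:, 0] < 1e-12),
                np.flatnonzero(nodes[:, 0] > lx - 1e-12),
                np.flatnonzero(nodes[:, 1] < 1e-12),
                np.flatnonzero(nodes[:, 1] > ly - 1e-12)]))},
        element_tangent=np.zeros((m, 2)),
        target_edge=lx / n)


# ---------------------------------------------------------------------------
# full-size reference fixture (shared by the acceptance tests)
# ---------------------------------------------------------------------------

def _reference_runs(target_edge: float, scenarios=("stiffness",)):
    geom = gs.generate_gyrus(gs.GyrusConfig(seed=1))
    mesh = gs.triangulate(geom, target_edge)
    mats = MaterialField.from_regions(mesh)
    flat = flatten(mesh, mats, n_steps=20)
    fixture = act.solve_baseline(mesh, mats, flat.prestress, 2)
    runs = {}
    for scenario in scenarios:
        spec = act._scenario_spec(scenario, 0.10)
        spec.use_prestress = True
        runs[scenario] = act.run_scenario(
            mesh, mats, flat.prestress, spec, n_increments=2,
            fixture=fixture)
    return {"geom": geom, "mesh": mesh, "materials": mats, "flat": flat,
            "fixture": fixture, "runs": runs}


@pytest.fixture(scope="session")
def reference_coarse():
    """Default gyrus, ~206 um mesh, all three 10% scenarios."""
    return _reference_runs(0.206, ("stiffness", "volume", "combined"))


@pytest.fixture(scope="session")
def reference_fine():
    """Default gyrus, ~143 um mesh, stiffness scenario only."""
    return _reference_runs(0.143, ("stiffness",))
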