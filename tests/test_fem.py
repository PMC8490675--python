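"""Constitutive law oracles and solver verification (patch tests,
growth, objectivity, near-incompressibility)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from gyrusim import fem
from gyrusim.fem import (
    DirichletBC, ElementInversionError, GrowthSpec, MaterialField,
    PrestressField, cauchy_stress, probe_displacement, solve_quasistatic,
    strain_energy_density, total_displacement_field,
)

from conftest import rect_mesh

MU, KAPPA = 1400.0, 1.4e7


def random_plane_strain_F(rng, scale=0.15):
    F = np.eye(3)
    F[:2, :2] += scale * rng.standard_normal((2, 2))
    if np.linalg.det(F) <= 0.05:
        F[:2, :2] = np.eye(2)
    return F


class TestStrainEnergy:
    def test_identity_is_zero(self):
        assert strain_energy_density(np.eye(3), 7.0, 900.0) == 0.0

    def test_isochoric_biaxial_value(self):
        # J = 1, I1 = 1.21 + 1/1.21 + 1 -> W = mu/2 (I1 - 3)
        F = np.diag([1.1, 1 / 1.1, 1.0])
        expect = 0.5 * (1.21 + 1 / 1.21 + 1 - 3)
        assert strain_energy_density(F, 1.0, 123.0) == pytest.approx(
            expect, rel=1e-12)
        assert expect == pytest.approx(0.018223, abs=1e-6)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000), st.floats(-np.pi, np.pi))
    def test_frame_invariance(self, seed, angle):
        rng = np.random.default_rng(seed)
        F = random_plane_strain_F(rng)
        R = Rotation.from_euler("z", angle).as_matrix()
        w1 = strain_energy_density(F, MU, KAPPA)
        w2 = strain_energy_density(R @ F, MU, KAPPA)
        assert w2 == pytest.approx(w1, rel=1e-12, abs=1e-12)

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            F = random_plane_strain_F(rng)
            assert strain_energy_density(F, MU, KAPPA) >= 0

    def test_inverted_state_raises(self):
        with pytest.raises(ElementInversionError):
            strain_energy_density(np.diag([-1.0, 1.0, 1.0]), MU, KAPPA)


class TestCauchyStress:
    def test_zero_at_identity(self):
        assert np.allclose(cauchy_stress(np.eye(3), MU, KAPPA), 0.0)

    def test_prestress_definition(self):
        s0 = np.array([[10.0, 3.0], [3.0, -4.0]])
        sig = cauchy_stress(np.eye(3), MU, KAPPA, prestress=s0)
        assert np.allclose(sig[:2, :2], s0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_finite_difference_oracle(self, seed):
        rng = np.random.default_rng(seed)
        F = random_plane_strain_F(rng)
        sig = cauchy_stress(F, MU, KAPPA)
        h = 1e-6
        P = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                P[i, j] = (strain_energy_density(Fp, MU, KAPPA)
                           - strain_energy_density(Fm, MU, KAPPA)) / (2 * h)
        oracle = P @ F.T / np.linalg.det(F)
        assert np.allclose(sig, oracle, rtol=1e-6,
                           atol=1e-6 * np.abs(oracle).max())

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        F = random_plane_strain_F(rng)
        sig = cauchy_stress(F, MU, KAPPA)
        assert np.allclose(sig, sig.T, rtol=1e-10)


def _uniaxial_bc(mesh, lam):
    nodes = mesh.nodes
    left = np.flatnonzero(nodes[:, 0] < 1e-12)
    right = np.flatnonzero(nodes[:, 0] > nodes[:, 0].max() - 1e-12)
    return DirichletBC(
        nodes=np.concatenate([left, right, [0]]),
        comps=np.concatenate([np.zeros(len(left) + len(right), dtype=int), [1]]),
        values=np.concatenate([np.zeros(len(left)),
                               (lam - 1) * nodes[right, 0], [0.0]]))


class TestQuasistaticSolver:
    def test_zero_load_zero_displacement(self):
        mesh = rect_mesh(4)
        mats = MaterialField(np.full(32, MU), np.full(32, KAPPA),
                             np.full(32, 1040.0))
        bc = DirichletBC.fix(mesh.boundary_tags["domain_exterior"])
        st_ = solve_quasistatic(mesh, mats, bc, n_increments=1)
        assert st_.converged
        assert st_.residual_norm == 0.0
        assert np.all(st_.u == 0.0) and np.all(st_.v == 0.0)

    @pytest.mark.parametrize("kappa", [1.4e5, 1.4e7, 5e9])
    def test_uniaxial_patch_matches_closed_form(self, kappa):
        lam = 1.05
        mesh = rect_mesh(4)
        m = mesh.n_elements
        mats = MaterialField(np.full(m, MU), np.full(m, kappa),
                             np.full(m, 1040.0))
        st_ = solve_quasistatic(mesh, mats, _uniaxial_bc(mesh, lam),
                                n_increments=2)
        assert st_.converged

        def s_yy(lam_y):
            return cauchy_stress(np.diag([lam, lam_y, 1.0]), MU, kappa)[1, 1]

        lam_y = brentq(s_yy, 0.7, 1.3, xtol=1e-15)
        exact = cauchy_stress(np.diag([lam, lam_y, 1.0]), MU, kappa)
        got = st_.sigma.mean(axis=(0, 1))
        assert got[0, 0] == pytest.approx(exact[0, 0], rel=1e-4)
        assert abs(got[1, 1]) < 1e-4 * abs(exact[0, 0])
        # near-incompressibility at converged solve
        if kappa / MU >= 1e3:
            assert np.abs(st_.J - 1.0).max() < 0.01

    def test_uniform_growth_is_stress_free(self):
        mesh = rect_mesh(4)
        m = mesh.n_elements
        mats = MaterialField(np.full(m, MU), np.full(m, KAPPA),
                             np.full(m, 1040.0))
        # pin rigid modes only: corner fully, bottom-right corner in y
        bc = DirichletBC(nodes=np.array([0, 0, 4]),
                         comps=np.array([0, 1, 1]), values=np.zeros(3))
        g = np.sqrt(1.10)
        st_ = solve_quasistatic(mesh, mats, bc,
                                growth=np.full(m, g), n_increments=2)
        assert st_.converged
        assert np.abs(st_.sigma).max() < 1e-6 * MU
        assert np.allclose(st_.u, (g - 1) * st_.p2_nodes[:, 0], atol=1e-9)
        assert np.allclose(st_.v, (g - 1) * st_.p2_nodes[:, 1], atol=1e-9)
        # with growth g the converged volume tracks g^2
        assert np.abs(st_.J - g**2).max() < 0.01

    def test_growth_spec_resolution(self, small_mesh):
        spec = GrowthSpec({(1, 3): 1.05})
        g = spec.resolve(small_mesh)
        mask = (small_mesh.element_layer == 1) & (small_mesh.element_segment == 3)
        assert np.all(g[mask] == 1.05)
        assert np.all(g[~mask] == 1.0)
        with pytest.raises(KeyError):
            GrowthSpec({(1, 99): 1.05}).resolve(small_mesh)

    def test_residual_is_energy_gradient(self):
        # conservative configuration (no prestress): assembled residual
        # equals the finite-difference gradient of the total energy
        mesh = rect_mesh(3)
        m = mesh.n_elements
        mats = MaterialField(np.full(m, MU), np.full(m, 200 * MU),
                             np.full(m, 1040.0))
        bc = DirichletBC(nodes=np.array([0]), comps=np.array([0]),
                         values=np.array([0.0]))
        sys_ = fem._System(mesh, mats, np.full(m, 1.02),
                           np.zeros((m, 2, 2)), bc)
        rng = np.random.default_rng(1)
        U = 0.01 * rng.standard_normal(sys_.ndof)
        R = sys_.residual(U, 1.0)
        eps = 1e-7
        for d in range(0, sys_.ndof, 11):
            Up, Um = U.copy(), U.copy()
            Up[d] += eps
            Um[d] -= eps
            fd = (sys_.energy(Up, 1.0) - sys_.energy(Um, 1.0)) / (2 * eps)
            assert R[d] == pytest.approx(fd, rel=1e-5, abs=1e-4)

    def test_objectivity_under_rotation(self):
        # rotate geometry and BCs by 90 degrees: displacement magnitudes
        # are preserved
        mesh = rect_mesh(4)
        m = mesh.n_elements
        mats = MaterialField(np.full(m, MU), np.full(m, KAPPA),
                             np.full(m, 1040.0))
        g = np.ones(m)
        g[:8] = 1.05     # localized growth patch
        bc = DirichletBC.fix(mesh.boundary_tags["domain_exterior"])
        st1 = solve_quasistatic(mesh, mats, bc, growth=g, n_increments=2)

        rot = rect_mesh(4)
        rot.nodes = np.column_stack([-mesh.nodes[:, 1], mesh.nodes[:, 0]])
        # reverse triangle orientation flip: 90-degree rotation preserves
        # orientation, so connectivity is unchanged
        st2 = solve_quasistatic(rot, mats, bc, growth=g, n_increments=2)
        d1 = np.hypot(st1.u, st1.v)
        d2 = np.hypot(st2.u, st2.v)
        assert np.allclose(d1, d2, atol=1e-8)

    def test_nonconvergence_is_flagged(self):
        mesh = rect_mesh(2)
        m = mesh.n_elements
        mats = MaterialField(np.full(m, MU), np.full(m, KAPPA),
                             np.full(m, 1040.0))
        st_ = solve_quasistatic(mesh, mats, _uniaxial_bc(mesh, 1.4),
                                n_increments=1, max_iterations=1)
        assert not st_.converged


class TestDisplacementFields:
    def _toy_state(self):
        mesh = rect_mesh(2)
        m = mesh.n_elements
        mats = MaterialField(np.full(m, MU), np.full(m, KAPPA),
                             np.full(m, 1040.0))
        bc = DirichletBC(nodes=np.array([0]), comps=np.array([0]),
                         values=np.array([0.0]))
        sys_ = fem._System(mesh, mats, np.ones(m), np.zeros((m, 2, 2)), bc)
        U = np.zeros(sys_.ndof)
        return fem._make_state(sys_, U, True, 0.0, {})

    def test_three_four_five(self):
        st_ = self._toy_state()
        st_.u[:] = 3e-3   # mm
        st_.v[:] = 4e-3
        assert np.allclose(total_displacement_field(st_), 5.0)  # um

    def test_zero_state(self):
        st_ = self._toy_state()
        assert np.all(total_displacement_field(st_) == 0.0)

    def test_swap_symmetry(self):
        st_ = self._toy_state()
        rng = np.random.default_rng(0)
        st_.u = rng.random(len(st_.u))
        st_.v = rng.random(len(st_.v))
        d1 = total_displacement_field(st_)
        st_.u, st_.v = st_.v.copy(), st_.u.copy()
        assert np.allclose(d1, total_displacement_field(st_))

    def test_probe_at_node_and_centroid(self):
        st_ = self._toy_state()
        # linear displacement field: interpolation is exact
        st_.u = 1e-3 * st_.p2_nodes[:, 0]
        st_.v = 2e-3 * st_.p2_nodes[:, 1]
        node = st_.p2_nodes[4]
        d_node = probe_displacement(st_, node)
        assert d_node == pytest.approx(
            1e3 * np.hypot(1e-3 * node[0], 2e-3 * node[1]), rel=1e-9)
        tri = st_.mesh.triangles[0]
        centroid = st_.mesh.nodes[tri].mean(axis=0)
        expect = 1e3 * np.hypot(1e-3 * centroid[0], 2e-3 * centroid[1])
        assert probe_displacement(st_, centroid) == pytest.approx(expect,
                                                                  rel=1e-9)

    def test_probe_outside_mesh_errors(self):
        st_ = self._toy_state()
        with pytest.raises(ValueError, match="outside"):
            probe_displacement(st_, (10.0, 10.0))
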