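"""Plane-strain quasi-static FEM for nearly incompressible neo-Hookean tissue.

The constitutive model is the compressible neo-Hookean strain-energy
density

    W(F) = mu/2 [tr(F F^T) J^(-2/3) - 3] + kappa/2 (J - 1)^2,   J = det F,

with Cauchy stress sigma = (1/J) dW/dF F^T.  Near-incompressibility is
enforced by a volumetric penalty kappa >> mu.  The 2D idealization is
plane strain (F_33 = 1): the through-plane extent of the tissue slab is
kept constant.

Discretization: 6-node quadratic triangles built on top of the linear
triangulation from :mod:`gyrusim.geometry`, 3-point Gauss quadrature,
total-Lagrangian Newton iterations with incremental loading and a
backtracking line search.  The consistent tangent is obtained by central
finite differences of the first Piola-Kirchhoff stress at each
quadrature point, which keeps the implementation independent of the
stress routine it linearizes.

Isotropic in-plane growth (tissue swelling) uses the multiplicative
decomposition F = F_e F_g with F_g = diag(g, g, 1); the energy is
evaluated on the elastic part F_e and weighted by det F_g.  A prescribed
in-plane volume (area) change of p per cent corresponds to
g = sqrt(1 + p/100).

Initial (pre-)stress is supported as a per-element Cauchy stress tensor
added within the stress evaluation; in the small-perturbation regime of
this application the distinction between stress measures for the initial
stress is below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from gyrusim.geometry import Mesh, CORTICAL_LAYERS

__all__ = [
    "MaterialField", "GrowthSpec", "PrestressField", "DeformationState",
    "DirichletBC", "ElementInversionError",
    "strain_energy_density", "cauchy_stress", "solve_quasistatic",
    "total_displacement_field", "probe_displacement", "extract_submesh",
    "TISSUE_LABELS", "DEFAULT_MU", "DEFAULT_RHO",
]

TISSUE_LABELS = ("WM",) + CORTICAL_LAYERS + ("GM_surround",)

#: Baseline shear moduli (Pa): cortical GM 1.4 kPa, WM ~35% stiffer.
#: CSF carries a placeholder (it is excluded from every solve: the pial
#: surface is traction-free, CSF mechanics is not modeled).
DEFAULT_MU = {"WM": 1900.0, "GM_surround": 1400.0, "CSF": 1400.0,
              **{lab: 1400.0 for lab in CORTICAL_LAYERS}}
#: Literature bulk moduli (Pa) in the GPa range (kappa="table" option).
TABLE_KAPPA = {"WM": 1.9e9, "GM_surround": 1.4e9, "CSF": 1.4e9,
               **{lab: 1.4e9 for lab in CORTICAL_LAYERS}}
DEFAULT_RHO = 1040.0   # kg/m^3, carried but unused in quasi-statics
#: Default penalty ratio kappa/mu (see docs/methods.md).
DEFAULT_KAPPA_RATIO = 1e4


class ElementInversionError(RuntimeError):
    """Raised when det F <= 0 is detected (element inversion)."""

    def __init__(self, elements):
        self.elements = np.atleast_1d(elements)
        super().__init__(f"element inversion (det F <= 0) in element(s) "
                         f"{self.elements[:10].tolist()}")


# ---------------------------------------------------------------------------
# material / load descriptions
# ---------------------------------------------------------------------------

@dataclass
class MaterialField:
    """Per-element shear modulus, bulk modulus and density."""

    mu: np.ndarray
    kappa: np.ndarray
    rho: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if np.any(self.mu <= 0):
            raise ValueError("mu must be positive")
        if np.any(self.kappa < 100.0 * self.mu):
            raise ValueError("kappa must be >= 100*mu (near-incompressibility)")

    @classmethod
    def from_regions(cls, mesh: Mesh, mu: dict[str, float] | None = None,
                     kappa: dict[str, float] | str | float | None = None,
                     rho: float = DEFAULT_RHO) -> "MaterialField":
        """Build a field from per-region values.

        ``kappa`` may be a dict (Pa per region), the string ``"table"``
        (bulk moduli in the GPa range), or None for the default penalty
        ``kappa = 1e4 * mu``.
        """
        mu = {**DEFAULT_MU, **(mu or {})}
        mu_e = np.array([mu[lab] for lab in mesh.element_labels])
        if kappa is None:
            kap_e = DEFAULT_KAPPA_RATIO * mu_e
        elif kappa == "table":
            kap_e = np.array([TABLE_KAPPA[lab] for lab in mesh.element_labels])
        elif isinstance(kappa, dict):
            kap_e = np.array([kappa[lab] for lab in mesh.element_labels])
        else:
            kap_e = np.full_like(mu_e, float(kappa))
        return cls(mu=mu_e, kappa=kap_e, rho=np.full_like(mu_e, rho))

    def copy(self) -> "MaterialField":
        return MaterialField(self.mu.copy(), self.kappa.copy(), self.rho.copy())

    def stiffen(self, mask: np.ndarray, factor: float) -> "MaterialField":
        """Return a copy with mu (and the penalty kappa with it) scaled by
        ``factor`` on the masked elements."""
        out = self.copy()
        out.mu[mask] *= factor
        out.kappa[mask] *= factor
        return out


@dataclass
class GrowthSpec:
    """Isotropic in-plane growth stretches g per region or segment.

    Keys are region labels or ``(layer, segment)`` tuples; values are the
    stretch g > 0 (g_x = g_y = g, g_z = 1).
    """

    values: dict = field(default_factory=dict)

    def __post_init__(self):
        for g in self.values.values():
            if g <= 0:
                raise ValueError("growth stretch g must be > 0")

    @classmethod
    def from_volume_change(cls, keys, volume_change: float) -> "GrowthSpec":
        """Growth for an in-plane area increase of ``volume_change``
        (fraction): g = sqrt(1 + volume_change)."""
        g = float(np.sqrt(1.0 + volume_change))
        return cls({k: g for k in keys})

    def resolve(self, mesh: Mesh) -> np.ndarray:
        g = np.ones(mesh.n_elements)
        for key, val in self.values.items():
            if isinstance(key, tuple):
                layer, seg = key
                mask = ((mesh.element_layer == layer)
                        & (mesh.element_segment == seg))
            else:
                mask = mesh.element_labels == key
            if not mask.any():
                raise KeyError(f"growth key {key!r} matches no elements")
            g[mask] = val
        return g


@dataclass
class PrestressField:
    """Per-element initial Cauchy stress tensors (Pa) in the reference
    configuration; symmetric 2x2 in-plane blocks."""

    sigma: np.ndarray    # (n_elements, 2, 2)

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.sigma.ndim != 3 or self.sigma.shape[1:] != (2, 2):
            raise ValueError("sigma must have shape (n_elements, 2, 2)")
        if not np.allclose(self.sigma, np.swapaxes(self.sigma, 1, 2),
                           rtol=0, atol=1e-8 * (1 + np.abs(self.sigma).max())):
            raise ValueError("prestress tensors must be symmetric")

    @classmethod
    def zero(cls, mesh: Mesh) -> "PrestressField":
        return cls(np.zeros((mesh.n_elements, 2, 2)))

    def scaled(self, s: float) -> "PrestressField":
        return PrestressField(s * self.sigma)


@dataclass
class DirichletBC:
    """Prescribed displacement components at (corner) nodes.

    ``nodes``/``comps``/``values`` are parallel arrays; comp 0 is u (x),
    comp 1 is v (y).  Values are scaled by the load factor during
    incremental loading.
    """

    nodes: np.ndarray
    comps: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=np.int64)
        self.comps = np.asarray(self.comps, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)

    @classmethod
    def fix(cls, nodes, comps=(0, 1)) -> "DirichletBC":
        nodes = np.asarray(nodes, dtype=np.int64)
        n, c, v = [], [], []
        for comp in comps:
            n.append(nodes)
            c.append(np.full(len(nodes), comp))
            v.append(np.zeros(len(nodes)))
        return cls(np.concatenate(n), np.concatenate(c), np.concatenate(v))

    @classmethod
    def combine(cls, *bcs: "DirichletBC") -> "DirichletBC":
        return cls(np.concatenate([b.nodes for b in bcs]),
                   np.concatenate([b.comps for b in bcs]),
                   np.concatenate([b.values for b in bcs]))


@dataclass
class DeformationState:
    """Solution of a quasi-static solve.

    Displacements are stored for all quadratic nodes; the first
    ``mesh.n_nodes`` entries correspond to the corner nodes of ``mesh``.
    ``F`` holds the in-plane deformation gradient block per element and
    quadrature point (plane strain: F_33 = 1, so J = det of the block).
    """

    mesh: Mesh
    u: np.ndarray                  # (n_p2_nodes,) x-displacement, mm
    v: np.ndarray                  # (n_p2_nodes,) y-displacement, mm
    F: np.ndarray                  # (n_elements, n_qp, 2, 2)
    J: np.ndarray                  # (n_elements, n_qp)
    sigma: np.ndarray              # (n_elements, n_qp, 2, 2) Cauchy, Pa
    converged: bool
    residual_norm: float
    p2_nodes: np.ndarray           # (n_p2_nodes, 2) reference coordinates
    p2_triangles: np.ndarray       # (n_elements, 6)
    diagnostics: dict = field(default_factory=dict)

    def displacement_at_corners(self) -> np.ndarray:
        n = self.mesh.n_nodes
        return np.column_stack([self.u[:n], self.v[:n]])

    def element_mean_stress(self) -> np.ndarray:
        return self.sigma.mean(axis=1)

    def subtriangulation(self):
        """P1 subdivision of the quadratic elements (4 subtriangles each)."""
        c = self.p2_triangles
        subs = np.concatenate([
            c[:, [0, 3, 5]], c[:, [3, 1, 4]], c[:, [5, 4, 2]], c[:, [3, 4, 5]],
        ])
        return subs


# ---------------------------------------------------------------------------
# constitutive routines (exposed, array-friendly)
# ---------------------------------------------------------------------------

def _as_F3(F) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] == (3, 3):
        return F
    if F.shape[-2:] == (2, 2):
        F3 = np.zeros(F.shape[:-2] + (3, 3))
        F3[..., :2, :2] = F
        F3[..., 2, 2] = 1.0
        return F3
    raise ValueError("F must be (...,2,2) or (...,3,3)")


def strain_energy_density(F, mu, kappa):
    """Neo-Hookean strain-energy density W (Pa).

    W = mu/2 [tr(F F^T) J^(-2/3) - 3] + kappa/2 (J - 1)^2.  W(I) = 0.
    Raises :class:`ElementInversionError` if det F <= 0.
    """
    F3 = _as_F3(F)
    J = np.linalg.det(F3)
    if np.any(J <= 0):
        raise ElementInversionError(np.argwhere(J <= 0))
    I1 = np.einsum("...ij,...ij->...", F3, F3)
    return (np.asarray(mu) / 2.0 * (I1 * J ** (-2.0 / 3.0) - 3.0)
            + np.asarray(kappa) / 2.0 * (J - 1.0) ** 2)


def _piola3(F3, mu, kappa):
    """First Piola-Kirchhoff stress dW/dF for the neo-Hookean model."""
    J = np.linalg.det(F3)
    if np.any(J <= 0):
        raise ElementInversionError(np.argwhere(J <= 0))
    Finv = np.linalg.inv(F3)
    FinvT = np.swapaxes(Finv, -1, -2)
    I1 = np.einsum("...ij,...ij->...", F3, F3)
    mu = np.asarray(mu)[..., None, None]
    kappa = np.asarray(kappa)[..., None, None]
    Jn = J[..., None, None]
    return (mu * Jn ** (-2.0 / 3.0) * (F3 - (I1[..., None, None] / 3.0) * FinvT)
            + kappa * Jn * (Jn - 1.0) * FinvT)


def cauchy_stress(F, mu, kappa, prestress=None):
    """Cauchy stress sigma = (1/J) dW/dF F^T (+ initial stress).

    ``prestress`` (same trailing shape as the returned tensor, or 2x2
    in-plane) is added per the initial-stress convention: sigma(I) with
    prestress sigma0 equals sigma0.
    """
    F3 = _as_F3(F)
    J = np.linalg.det(F3)[..., None, None]
    P = _piola3(F3, mu, kappa)
    sig = P @ np.swapaxes(F3, -1, -2) / J
    sig = 0.5 * (sig + np.swapaxes(sig, -1, -2))  # symmetrize round-off
    if prestress is not None:
        s0 = np.asarray(prestress, dtype=float)
        if s0.shape[-2:] == (2, 2):
            s3 = np.zeros(s0.shape[:-2] + (3, 3))
            s3[..., :2, :2] = s0
            s0 = s3
        sig = sig + s0
    return sig


# ---------------------------------------------------------------------------
# quadratic elements
# ---------------------------------------------------------------------------

def _cof2(F2: np.ndarray) -> np.ndarray:
    """2D cofactor cof(F) = J F^{-T} (linear in F)."""
    cof = np.empty_like(F2)
    cof[..., 0, 0] = F2[..., 1, 1]
    cof[..., 0, 1] = -F2[..., 1, 0]
    cof[..., 1, 0] = -F2[..., 0, 1]
    cof[..., 1, 1] = F2[..., 0, 0]
    return cof


# 3-point Gauss rule on the reference triangle (degree 2).
_QP = np.array([[1 / 6, 1 / 6], [2 / 3, 1 / 6], [1 / 6, 2 / 3]])
_QW = np.full(3, 1 / 6)


def _p2_shape_gradients():
    """dN/d(xi,eta) for the 6 quadratic shape functions at the 3 QPs."""
    out = np.empty((3, 6, 2))
    for q, (xi, eta) in enumerate(_QP):
        lam = 1.0 - xi - eta
        # N = [lam(2lam-1), xi(2xi-1), eta(2eta-1), 4 lam xi, 4 xi eta, 4 eta lam]
        dxi = np.array([1 - 4 * lam, 4 * xi - 1, 0.0,
                        4 * (lam - xi), 4 * eta, -4 * eta])
        deta = np.array([1 - 4 * lam, 0.0, 4 * eta - 1,
                         -4 * xi, 4 * xi, 4 * (lam - eta)])
        out[q] = np.column_stack([dxi, deta])
    return out


_DN = _p2_shape_gradients()


def build_p2(mesh: Mesh):
    """Quadratic node set: corner nodes first, unique edge midpoints after.

    Returns (coords, conn6, edges) where ``conn6[:, 3:]`` indexes the
    midside nodes of edges (0-1, 1-2, 2-0).
    """
    t = mesh.triangles
    edges = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    edges_sorted = np.sort(edges, axis=1)
    uniq, inv = np.unique(edges_sorted, axis=0, return_inverse=True)
    mid = 0.5 * (mesh.nodes[uniq[:, 0]] + mesh.nodes[uniq[:, 1]])
    coords = np.vstack([mesh.nodes, mid])
    mid_ids = mesh.n_nodes + inv.reshape(3, -1).T   # (M, 3)
    conn6 = np.column_stack([t, mid_ids])
    return coords, conn6, uniq


class _System:
    """Assembled quadratic FE system for one solve configuration."""

    def __init__(self, mesh: Mesh, materials: MaterialField,
                 growth_elem: np.ndarray, prestress_elem: np.ndarray,
                 bc: DirichletBC):
        self.mesh = mesh
        self.mu = materials.mu
        self.kappa = materials.kappa
        self.g = growth_elem
        self.s0 = prestress_elem          # (M, 2, 2)
        self.coords, self.conn, self.p2_edges = build_p2(mesh)
        self.n_nodes = len(self.coords)
        self.ndof = 2 * self.n_nodes

        xy = self.coords[self.conn[:, :3]]           # (M, 3, 2)
        Jm = np.stack([xy[:, 1] - xy[:, 0], xy[:, 2] - xy[:, 0]], axis=2)
        detJ = np.linalg.det(Jm)
        if np.any(detJ <= 0):
            raise ValueError("negative Jacobian in reference mesh")
        Jinv = np.linalg.inv(Jm)
        # dN/dX[e, q, a, j] = dN/dxi[q, a, k] * Jinv[e, k, j]
        self.G = np.einsum("qak,ekj->eqaj", _DN, Jinv)
        self.w = _QW[None, :] * detJ[:, None]        # (M, 3)
        self.Ve = self.w.sum(axis=1)                 # element areas
        self.has_prestress = bool(np.any(prestress_elem))
        # Augmented-Lagrangian treatment of the volumetric penalty: inner
        # Newton solves use a moderate effective bulk modulus (robust),
        # multiplier augmentations converge to the true-kappa solution.
        self.keff = np.minimum(self.kappa, 100.0 * self.mu)
        self.pbar = np.zeros(len(self.mu))           # volumetric multiplier
        # Characteristic internal-force norm (unit-strain scale); floors
        # the relative convergence criterion for stress-free solutions.
        self.f_char = float(np.mean(self.mu) * np.sqrt(self.Ve.sum()))

        # dof maps for assembly
        dofs = np.empty((len(self.conn), 12), dtype=np.int64)
        dofs[:, 0::2] = 2 * self.conn
        dofs[:, 1::2] = 2 * self.conn + 1
        self.edofs = dofs
        self.Krows = np.repeat(dofs, 12, axis=1).ravel()
        self.Kcols = np.tile(dofs, (1, 12)).ravel()

        # Dirichlet dofs: prescribed corner dofs plus midside nodes of
        # edges whose both endpoints are prescribed for that component.
        con = {}
        for n, c, v in zip(bc.nodes, bc.comps, bc.values):
            con[2 * int(n) + int(c)] = float(v)
        e0, e1 = self.p2_edges[:, 0], self.p2_edges[:, 1]
        for comp in (0, 1):
            d0 = 2 * e0 + comp
            d1 = 2 * e1 + comp
            both = [i for i in range(len(e0))
                    if d0[i] in con and d1[i] in con]
            for i in both:
                mid_dof = 2 * (mesh.n_nodes + i) + comp
                con[mid_dof] = 0.5 * (con[d0[i]] + con[d1[i]])
        self.fixed_dofs = np.array(sorted(con), dtype=np.int64)
        self.fixed_vals = np.array([con[d] for d in self.fixed_dofs])
        free = np.ones(self.ndof, dtype=bool)
        free[self.fixed_dofs] = False
        self.free = np.flatnonzero(free)

    # -- kinematics ---------------------------------------------------

    def deformation_gradient(self, U):
        De = U.reshape(-1, 2)[self.conn]              # (M, 6, 2)
        F = np.einsum("eai,eqaj->eqij", De, self.G, optimize=True)
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        return F

    def _growth(self, load_factor):
        return 1.0 + (self.g - 1.0) * load_factor

    def dev_piola(self, F2, load_factor):
        """Isochoric (mu) first Piola stress plus the initial-stress term.

        The volumetric kappa-term is handled separately with an
        element-averaged J (mean dilatation), which removes both the
        volumetric locking and the penalty-driven Newton fragility of
        fully pointwise integration.
        """
        gl = self._growth(load_factor)
        Fe = F2 / gl[:, None, None, None]
        # plane strain: J and I1 from the in-plane block (F_33 = 1)
        J = Fe[..., 0, 0] * Fe[..., 1, 1] - Fe[..., 0, 1] * Fe[..., 1, 0]
        if np.any(J <= 0):
            raise ElementInversionError(np.unique(np.argwhere(J <= 0)[:, 0]))
        I1 = 1.0 + (Fe * Fe).sum(axis=(-2, -1))
        FinvT = _cof2(Fe) / J[..., None, None]
        mu = self.mu[:, None, None, None]
        Jn = J[..., None, None]
        Pdev = mu * Jn ** (-2.0 / 3.0) * (Fe - (I1[..., None, None] / 3.0) * FinvT)
        P = Pdev * gl[:, None, None, None]
        if load_factor != 0.0 and self.has_prestress:
            # P0 = J sigma0 F^{-T} = sigma0 cof(F)
            s0 = load_factor * self.s0[:, None]
            P = P + s0 @ _cof2(F2)
        return P

    def _vol_terms(self, F2, load_factor):
        """Mean elastic dilatation and the volumetric B-vector per element."""
        gl = self._growth(load_factor)
        J = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
        Jbar = (self.w * J).sum(axis=1) / self.Ve          # (M,)
        Je = Jbar / gl**2
        cof = _cof2(F2)
        # Bv[e, a, i] = sum_q w cof(F)[i, j] G[a, j]
        Bv = np.einsum("eq,eqij,eqaj->eai", self.w, cof, self.G, optimize=True)
        return gl, Je, Bv

    # -- assembly -----------------------------------------------------

    def _pressure(self, Je):
        """Augmented volumetric pressure; equals kappa*(Je - 1) at the
        converged multiplier."""
        return self.pbar + self.keff * (Je - 1.0 - self.pbar / self.kappa)

    def residual(self, U, load_factor, with_scale=False):
        F2 = self.deformation_gradient(U)
        P = self.dev_piola(F2, load_factor)
        Re = np.einsum("eq,eqij,eqaj->eai", self.w, P, self.G, optimize=True)
        gl, Je, Bv = self._vol_terms(F2, load_factor)
        pbar = self._pressure(Je)                          # (M,)
        Re += pbar[:, None, None] * Bv
        R = np.zeros(self.ndof)
        np.add.at(R, self.edofs.reshape(-1, 12), Re.reshape(-1, 12))
        if not with_scale:
            return R
        # Cancellation-free internal-force scale for the relative
        # convergence criterion.
        Sabs = np.einsum("eq,eqij,eqaj->eai", self.w, np.abs(P),
                         np.abs(self.G), optimize=True)
        Sabs += np.abs(pbar)[:, None, None] * np.abs(Bv)
        Rs = np.zeros(self.ndof)
        np.add.at(Rs, self.edofs.reshape(-1, 12), Sabs.reshape(-1, 12))
        return R, Rs

    def tangent(self, U, load_factor, h=1e-7):
        F2 = self.deformation_gradient(U)
        # FD tangent of the isochoric/prestress part (qp-local)
        A = np.empty(F2.shape[:2] + (2, 2, 2, 2))
        for k in range(2):
            for l in range(2):
                Fp = F2.copy()
                Fp[..., k, l] += h
                Fm = F2.copy()
                Fm[..., k, l] -= h
                A[..., k, l] = (self.dev_piola(Fp, load_factor)
                                - self.dev_piola(Fm, load_factor)) / (2 * h)
        Ke = np.einsum("eq,eqaj,eqijkl,eqbl->eaibk", self.w, self.G, A,
                       self.G, optimize=True)
        # Exact volumetric tangent: rank-one mean-dilatation term plus the
        # (constant) cofactor derivative d cof(F)/dF.
        gl, Je, Bv = self._vol_terms(F2, load_factor)
        pbar = self._pressure(Je)
        coef = self.keff / (gl**2 * self.Ve)
        Ke += coef[:, None, None, None, None] * np.einsum(
            "eai,ebk->eaibk", Bv, Bv, optimize=True)
        # d cof(F)_ij / dF_kl is the (constant) 2D permutation tensor
        D = np.zeros((2, 2, 2, 2))
        D[0, 0, 1, 1] = D[1, 1, 0, 0] = 1.0
        D[0, 1, 1, 0] = D[1, 0, 0, 1] = -1.0
        Ke += pbar[:, None, None, None, None] * np.einsum(
            "eq,eqaj,ijkl,eqbl->eaibk", self.w, self.G, D, self.G,
            optimize=True)
        K = sp.coo_matrix(
            (Ke.reshape(-1, 12, 12).ravel(), (self.Krows, self.Kcols)),
            shape=(self.ndof, self.ndof)).tocsc()
        return K

    def energy(self, U, load_factor):
        """Total potential of the conservative terms (isochoric +
        augmented volumetric); the initial-stress loading has no exact
        potential and is excluded."""
        F2 = self.deformation_gradient(U)
        gl = self._growth(load_factor)
        Fe3 = _as_F3(F2 / gl[:, None, None, None])
        J = np.linalg.det(Fe3)
        if np.any(J <= 0):
            return np.inf
        I1 = np.einsum("...ij,...ij->...", Fe3, Fe3)
        Wdev = self.mu[:, None] / 2.0 * (I1 * J ** (-2.0 / 3.0) - 3.0)
        E = float((self.w * Wdev * gl[:, None] ** 2).sum())
        _, Je, _ = self._vol_terms(F2, load_factor)
        c = Je - 1.0 - self.pbar / self.kappa
        phi = self.pbar * Je + self.keff / 2.0 * c**2
        E += float((gl**2 * self.Ve * phi).sum())
        return E

    def augment(self, U, load_factor):
        """Multiplier update; returns the relative multiplier change."""
        F2 = self.deformation_gradient(U)
        _, Je, _ = self._vol_terms(F2, load_factor)
        q = self._pressure(Je)
        delta = float(np.max(np.abs(q - self.pbar)) / np.mean(self.mu))
        self.pbar = q
        return delta

    # -- Newton -------------------------------------------------------

    def newton(self, U, load_factor, tol, max_iter, n_linesearch=8):
        free = self.free
        for it in range(max_iter + 1):
            R, Rs = self.residual(U, load_factor, with_scale=True)
            rnorm = np.linalg.norm(R[free])
            scale = np.linalg.norm(Rs[free])
            if rnorm <= tol * max(scale, self.f_char) or scale == 0.0:
                return U, True, rnorm, it
            if it == max_iter:
                return U, False, rnorm, it
            K = self.tangent(U, load_factor)
            dU = np.zeros(self.ndof)
            Kff = K[np.ix_(free, free)]
            dU[free] = splu(Kff.tocsc()).solve(-R[free])
            # backtracking line search on the residual norm; keeps
            # halving past the nominal budget while the trial state is
            # inverted (recoverable overshoot)
            step = 1.0
            for _ in range(60):
                Utry = U + step * dU
                try:
                    Rtry = self.residual(Utry, load_factor)
                    rtry = np.linalg.norm(Rtry[free])
                except ElementInversionError:
                    rtry = np.inf
                if np.isfinite(rtry) and (rtry < rnorm
                                          or step <= 1.0 / 2 ** n_linesearch):
                    break
                step *= 0.5
                if step < 1e-14:
                    raise ElementInversionError(np.array([-1]))
            U = Utry
        return U, False, rnorm, max_iter


def solve_quasistatic(mesh: Mesh, materials: MaterialField, bcs: DirichletBC,
                      growth: GrowthSpec | np.ndarray | None = None,
                      prestress: PrestressField | None = None,
                      n_increments: int = 10, tol: float = 1e-8,
                      max_iterations: int = 25,
                      warm_start: np.ndarray | None = None) -> DeformationState:
    """Incremental-loading Newton solve of quasi-static equilibrium.

    The load factor ramps Dirichlet values, growth stretches and the
    initial stress linearly over ``n_increments``.  Returns a full
    :class:`DeformationState`; non-convergence is flagged (never silent).
    """
    if n_increments < 1:
        raise ValueError("n_increments must be >= 1")
    if growth is None:
        g_elem = np.ones(mesh.n_elements)
    elif isinstance(growth, GrowthSpec):
        g_elem = growth.resolve(mesh)
    else:
        g_elem = np.asarray(growth, dtype=float)
    s0 = prestress.sigma if prestress is not None else None
    if s0 is not None and len(s0) != mesh.n_elements:
        raise ValueError("prestress field does not match the mesh")

    sys_ = _System(mesh, materials, g_elem,
                   s0 if s0 is not None else np.zeros((mesh.n_elements, 2, 2)),
                   bcs)
    U = np.zeros(sys_.ndof) if warm_start is None else warm_start.copy()
    converged = True
    rnorm = 0.0
    iters = []
    # incremental loading with adaptive cutback on non-convergence
    lf = 0.0
    dlf = 1.0 / n_increments
    while lf < 1.0 - 1e-12:
        step = min(dlf, 1.0 - lf)
        lf_try = lf + step
        Utry = U.copy()
        Utry[sys_.fixed_dofs] = lf_try * sys_.fixed_vals
        try:
            Utry, ok, rnorm, it_inc = advance(
                sys_, Utry, lf_try, tol, max_iterations,
                aug_tol=None if lf_try >= 1.0 - 1e-12 else 1e-4)
        except ElementInversionError:
            ok = False
            it_inc = 0
        if ok:
            U, lf = Utry, lf_try
            iters.append(it_inc)
            dlf = min(dlf * 1.5, 1.0 / n_increments)
        else:
            dlf *= 0.5
            if dlf < 1.0 / (64.0 * n_increments):
                converged = False   # return last good state, flagged
                break
    return _make_state(sys_, U, converged, rnorm,
                       {"increments": len(iters), "newton_iterations": iters})


def advance(sys_: _System, U, load_factor, tol=1e-8, max_iterations=25,
            aug_tol=None):
    """Newton solve at one load level followed by volumetric multiplier
    augmentations until the pressure is converged.

    The default multiplier tolerance (1e-6 of the mean shear modulus,
    ~1 mPa here) is far below the ~100 Pa activation loads and their
    micrometre responses; intermediate continuation steps may pass a
    looser value since only the final state is reported.
    """
    if aug_tol is None:
        aug_tol = max(1e-6, 100.0 * tol)
    it_tot = 0
    rnorm = np.inf
    for _aug in range(30):
        U, ok, rnorm, it = sys_.newton(U, load_factor, tol, max_iterations)
        it_tot += it
        if not ok:
            return U, False, rnorm, it_tot
        if sys_.augment(U, load_factor) <= aug_tol:
            return U, True, rnorm, it_tot
    return U, False, rnorm, it_tot


def _make_state(sys_: _System, U, converged, rnorm, diagnostics):
    F2 = sys_.deformation_gradient(U)
    J = np.linalg.det(F2)
    gl = sys_.g[:, None, None, None]
    Fe3 = _as_F3(F2 / gl)
    Je = np.linalg.det(Fe3)
    # Deviatoric Cauchy stress at the quadrature points plus the
    # element-mean volumetric pressure (consistent with the solver's
    # mean-dilatation discretization) plus the initial stress.
    Be = Fe3 @ np.swapaxes(Fe3, -1, -2)
    I1 = np.einsum("...ii->...", Be)
    sig = (sys_.mu[:, None, None, None] * Je[..., None, None] ** (-5.0 / 3.0)
           * (Be - (I1[..., None, None] / 3.0)
              * np.eye(3)))[..., :2, :2]
    _, Jebar, _ = sys_._vol_terms(F2, 1.0)
    sig = sig + sys_._pressure(Jebar)[:, None, None, None] * np.eye(2)
    sig = sig + sys_.s0[:, None]
    return DeformationState(
        mesh=sys_.mesh,
        u=U[0::2].copy(), v=U[1::2].copy(),
        F=F2, J=J, sigma=sig,
        converged=converged, residual_norm=float(rnorm),
        p2_nodes=sys_.coords, p2_triangles=sys_.conn,
        diagnostics=diagnostics)


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------

def total_displacement_field(state: DeformationState) -> np.ndarray:
    """Per-node total displacement d_tot = sqrt(u^2 + v^2) in micrometres."""
    return 1e3 * np.hypot(state.u, state.v)


def probe_displacement(state: DeformationState, point) -> float:
    """d_tot (micrometres) at an arbitrary point, by linear interpolation of
    (u, v) on the P1 subdivision of the quadratic elements."""
    import matplotlib.tri as mtri

    point = np.asarray(point, dtype=float)
    subs = state.subtriangulation()
    tri = mtri.Triangulation(state.p2_nodes[:, 0], state.p2_nodes[:, 1], subs)
    ui = mtri.LinearTriInterpolator(tri, state.u)(point[0], point[1])
    vi = mtri.LinearTriInterpolator(tri, state.v)(point[0], point[1])
    if np.ma.is_masked(ui) or np.ma.is_masked(vi):
        raise ValueError(f"point {point.tolist()} lies outside the mesh")
    return float(1e3 * np.hypot(float(ui), float(vi)))


def extract_submesh(mesh: Mesh, labels) -> tuple[Mesh, np.ndarray, np.ndarray]:
    """Submesh containing only elements whose label is in ``labels``.

    Returns (submesh, node_map, elem_map): ``node_map[i]`` is the parent
    node id of submesh node i, ``elem_map[e]`` the parent element id of
    submesh element e.  Boundary tags are restricted to surviving nodes.
    """
    labels = set(labels)
    emask = np.array([lab in labels for lab in mesh.element_labels])
    elem_map = np.flatnonzero(emask)
    tris = mesh.triangles[emask]
    node_map = np.unique(tris)
    renum = -np.ones(mesh.n_nodes, dtype=np.int64)
    renum[node_map] = np.arange(len(node_map))
    sub = Mesh(
        nodes=mesh.nodes[node_map].copy(),
        triangles=renum[tris],
        element_labels=mesh.element_labels[emask].copy(),
        element_layer=mesh.element_layer[emask].copy(),
        element_segment=mesh.element_segment[emask].copy(),
        boundary_tags={k: renum[v[renum[v] >= 0]]
                       for k, v in mesh.boundary_tags.items()},
        element_tangent=mesh.element_tangent[emask].copy(),
        target_edge=mesh.target_edge,
        crown_point=None if mesh.crown_point is None else mesh.crown_point.copy(),
    )
    return sub, node_map, elem_map
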