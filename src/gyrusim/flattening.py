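"""Baseline cortical stress from numerical unfolding of the gyrus.

The folded cortex is assumed to carry residual stress acquired during
development.  Lacking an in vivo measurement, the baseline stress
distribution is estimated by deforming the folded cortical band back to a
flat slab: the pial and GM/WM boundaries are driven, in small quasi-static
steps, onto two parallel horizontal lines (y prescribed, x free), and the
Cauchy stresses of the flattened state are then mapped element-by-element
back onto the folded reference mesh, where they serve as the initial
stress of the activation scenarios.

The mapped-back field is not self-equilibrated in the folded
configuration: applied as-is it relaxes the folded mesh by hundreds of
micrometres, and scenario responses evaluated around such a drifted state
pick up large spurious couplings (the volume mechanism becomes strongly
prestress-dependent, breaking the near-additivity of the two
mechanisms).  The default therefore re-equilibrates the mapped field by
a few fixed-point passes — solve the baseline under the current field,
replace the field by the total stress of the relaxed state — which
drives the residual drift toward zero while preserving the field's
magnitude and pattern; the drift of every pass is recorded in the
result.  ``equilibrate=0`` recovers the raw as-is behavior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gyrusim import fem
from gyrusim.geometry import Mesh, CORTICAL_LAYERS
from gyrusim.fem import (
    DeformationState, DirichletBC, MaterialField, PrestressField,
    TISSUE_LABELS, extract_submesh, solve_quasistatic,
    total_displacement_field, ElementInversionError,
)


def equilibrate_prestress(mesh: Mesh, materials: MaterialField,
                          prestress: PrestressField, passes: int = 2,
                          n_increments: int = 4):
    """Fixed-point re-equilibration of an initial-stress field.

    Each pass solves the baseline problem (tissue submesh, exterior
    fixed) under the current field and replaces the field by the total
    Cauchy stress of the relaxed state, which is in discrete equilibrium;
    the residual drift (max total displacement, micrometres) contracts by
    roughly the drift strain per pass.  Returns the equilibrated field
    and the per-pass drift log.
    """
    sub, _node_map, elem_map = extract_submesh(mesh, TISSUE_LABELS)
    mats = MaterialField(materials.mu[elem_map], materials.kappa[elem_map],
                         materials.rho[elem_map])
    bc = DirichletBC.fix(sub.boundary_tags["domain_exterior"])
    sigma = prestress.sigma.copy()
    drifts = []
    for _ in range(passes):
        ps = PrestressField(sigma[elem_map])
        state = solve_quasistatic(sub, mats, bc, prestress=ps,
                                  n_increments=n_increments)
        drifts.append(float(total_displacement_field(state).max()))
        sigma = sigma.copy()
        sigma[elem_map] = state.element_mean_stress()
    return PrestressField(sigma), drifts


def _unfold(cortex: Mesh, mats: MaterialField, bc: DirichletBC,
            pial: np.ndarray, gmwm: np.ndarray, n_steps: int,
            tol: float) -> DeformationState:
    """Continuation loop for the unfolding solve.

    Each step prescribes the boundary y-coordinates at an intermediate
    load factor; the prescribed increment is extended into the band
    interior (linear blend across the cortical depth) as the initial
    guess, so boundary elements are not inverted by the bare Dirichlet
    jump.  Steps are bisected adaptively on non-convergence.
    """
    sys_ = fem._System(cortex, mats, np.ones(cortex.n_elements),
                       np.zeros((cortex.n_elements, 2, 2)), bc)

    # Full-load y-displacement of the two boundaries as graphs of x.
    coords = sys_.coords
    val = {2 * int(n) + int(c): float(v)
           for n, c, v in zip(bc.nodes, bc.comps, bc.values)}
    xp = np.sort(cortex.nodes[pial, 0])
    dp = np.array([val[2 * n + 1] for n in pial[np.argsort(cortex.nodes[pial, 0])]])
    xg = np.sort(cortex.nodes[gmwm, 0])
    dg = np.array([val[2 * n + 1] for n in gmwm[np.argsort(cortex.nodes[gmwm, 0])]])
    y_pial_ref = np.interp(coords[:, 0], xp,
                           cortex.nodes[pial, 1][np.argsort(cortex.nodes[pial, 0])])
    y_gmwm_ref = np.interp(coords[:, 0], xg,
                           cortex.nodes[gmwm, 1][np.argsort(cortex.nodes[gmwm, 0])])
    with np.errstate(divide="ignore", invalid="ignore"):
        eta = (coords[:, 1] - y_gmwm_ref) / (y_pial_ref - y_gmwm_ref)
    eta = np.clip(np.nan_to_num(eta, nan=0.5), 0.0, 1.0)
    v_unit = eta * np.interp(coords[:, 0], xp, dp) \
        + (1.0 - eta) * np.interp(coords[:, 0], xg, dg)

    U = np.zeros(sys_.ndof)
    lf = 0.0
    dlf = 1.0 / n_steps
    rnorm = np.inf
    iters = []
    while lf < 1.0 - 1e-12:
        step = min(dlf, 1.0 - lf)
        Utry = U.copy()
        Utry[1::2] += step * v_unit
        lf_new = lf + step
        Utry[sys_.fixed_dofs] = lf_new * sys_.fixed_vals
        try:
            Utry, ok, rnorm, it = fem.advance(
                sys_, Utry, lf_new, tol,
                aug_tol=None if lf_new >= 1.0 - 1e-12 else 1e-4)
        except ElementInversionError:
            ok = False
            it = 0
        if ok:
            U, lf = Utry, lf_new
            iters.append(it)
            if it <= 6:
                dlf = min(dlf * 1.5, 1.0 / n_steps)
        else:
            dlf *= 0.5
            if dlf < 1.0 / (64.0 * n_steps):
                state = fem._make_state(sys_, U, False, rnorm, {
                    "steps_completed": len(iters), "load_factor": lf,
                    "newton_iterations": iters})
                return state
    return fem._make_state(sys_, U, True, 0.0, {
        "steps_completed": len(iters), "newton_iterations": iters})

__all__ = ["FlatteningResult", "flatten", "map_stress_back",
           "scale_prestress", "equilibrate_prestress"]


@dataclass
class FlatteningResult:
    """Output of the unfolding procedure.

    ``prestress`` lives on the full folded mesh (zero outside the cortex);
    ``normalized_stress`` is the tangential normal stress of the flattened
    state divided by the GM shear modulus, per full-mesh element (NaN
    outside the cortex).
    """

    flattened_state: DeformationState      # on the cortical submesh
    prestress: PrestressField              # on the full folded mesh
    normalized_stress: np.ndarray          # (n_elements,) sigma_tt / mu_GM
    scale: float
    target_separation: float
    elongation: float                      # flattened / folded lateral extent
    arc_length_folded: float               # pial boundary, folded (mm)
    arc_length_flat: float                 # pial boundary, flattened (mm)
    boundary_straightness: float           # max |y - target| after solve (mm)
    raw_prestress: PrestressField = None   # mapped back without equilibration
    drift_log: list = None                 # max drift per equilibration pass (um)
    submesh: Mesh = None
    node_map: np.ndarray = None
    elem_map: np.ndarray = None
    mesh_hash: str = ""


def _ordered_boundary(mesh: Mesh, tag: str) -> np.ndarray:
    nodes = mesh.boundary_tags[tag]
    order = np.argsort(mesh.nodes[nodes, 0])
    return nodes[order]


def _polyline_length(points: np.ndarray) -> float:
    return float(np.hypot(*np.diff(points, axis=0).T).sum())


def flatten(mesh: Mesh, materials: MaterialField, n_steps: int = 20,
            target_separation: float | None = None, tol: float = 1e-8,
            mu_gm: float = 1400.0, equilibrate: int = 3) -> FlatteningResult:
    """Unfold the cortical band of ``mesh`` to a flat slab.

    ``materials`` is the material field of the full mesh.  Each of the
    ``n_steps`` load steps prescribes the boundary y-coordinates as a
    linear interpolation between the folded position and the target lines
    (x left free; one node pinned laterally); a quasi-static solve is
    performed per step.  The stresses of the final state define the
    baseline prestress of the folded configuration.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    cortex, node_map, elem_map = extract_submesh(mesh, CORTICAL_LAYERS)
    mats = MaterialField(materials.mu[elem_map], materials.kappa[elem_map],
                         materials.rho[elem_map])

    pial = _ordered_boundary(cortex, "pial")
    gmwm = _ordered_boundary(cortex, "gm_wm")
    if len(pial) == 0 or len(gmwm) == 0:
        raise ValueError("mesh lacks tagged pial / gm_wm boundaries")

    pial_xy = cortex.nodes[pial]
    gmwm_xy = cortex.nodes[gmwm]
    area = float(cortex.areas().sum())
    mid_len = 0.5 * (_polyline_length(pial_xy) + _polyline_length(gmwm_xy))
    if target_separation is None:
        # preserve the mean cortical thickness
        target_separation = area / mid_len
    y_center = 0.5 * float(pial_xy[:, 1].mean() + gmwm_xy[:, 1].mean())
    y_pial = y_center + 0.5 * target_separation
    y_gmwm = y_center - 0.5 * target_separation

    # Prescribed y-displacements; x pinned at the node closest to the apex.
    bc_nodes = np.concatenate([pial, gmwm])
    bc_vals = np.concatenate([y_pial - pial_xy[:, 1], y_gmwm - gmwm_xy[:, 1]])
    pin = pial[int(np.argmax(pial_xy[:, 1]))]
    bc = DirichletBC(
        nodes=np.concatenate([bc_nodes, [pin]]),
        comps=np.concatenate([np.ones(len(bc_nodes), dtype=int), [0]]),
        values=np.concatenate([bc_vals, [0.0]]))

    state = _unfold(cortex, mats, bc, pial, gmwm, n_steps, tol)

    # Straightness of the boundaries in the deformed configuration.
    npial = cortex.n_nodes
    y_def = cortex.nodes[:, 1] + state.v[:npial]
    straight = max(float(np.abs(y_def[pial] - y_pial).max()),
                   float(np.abs(y_def[gmwm] - y_gmwm).max()))

    # Per-element stresses of the flattened state, mapped back unchanged
    # onto the folded reference mesh, then (by default) re-equilibrated.
    sig_sub = state.element_mean_stress()
    sigma_full = np.zeros((mesh.n_elements, 2, 2))
    sigma_full[elem_map] = sig_sub
    raw = PrestressField(sigma_full)
    if equilibrate > 0:
        prestress, drift_log = equilibrate_prestress(
            mesh, materials, raw, passes=equilibrate)
    else:
        prestress, drift_log = raw, []

    # Tangential normal stress normalized by the GM stiffness, using the
    # band direction of the folded reference configuration.
    tang = mesh.element_tangent
    with np.errstate(invalid="ignore"):
        sig_tt = np.einsum("ei,eij,ej->e", tang, sigma_full, tang)
    normalized = np.where(mesh.element_layer > 0, sig_tt / mu_gm, np.nan)

    x_def = cortex.nodes[:, 0] + state.u[:npial]
    elongation = float((x_def.max() - x_def.min())
                       / (cortex.nodes[:, 0].max() - cortex.nodes[:, 0].min()))
    pial_def = np.column_stack([x_def[pial], y_def[pial]])
    order = np.argsort(pial_def[:, 0])

    return FlatteningResult(
        flattened_state=state,
        prestress=prestress,
        normalized_stress=normalized,
        scale=1.0,
        raw_prestress=raw,
        drift_log=drift_log,
        target_separation=float(target_separation),
        elongation=elongation,
        arc_length_folded=_polyline_length(pial_xy),
        arc_length_flat=_polyline_length(pial_def[order]),
        boundary_straightness=straight,
        submesh=cortex,
        node_map=node_map,
        elem_map=elem_map,
        mesh_hash=mesh.content_hash(),
    )


def map_stress_back(flattening: FlatteningResult, folded_mesh: Mesh) -> PrestressField:
    """Assign the flattened-state stresses to the same material points
    (elements) of the folded reference mesh."""
    if folded_mesh.content_hash() != flattening.mesh_hash:
        raise ValueError("folded mesh does not match the flattening result "
                         "(different element identity)")
    sigma = np.zeros((folded_mesh.n_elements, 2, 2))
    sigma[flattening.elem_map] = flattening.flattened_state.element_mean_stress()
    return PrestressField(flattening.scale * sigma)


def scale_prestress(prestress: PrestressField, s: float) -> PrestressField:
    """Globally scale a prestress field by s >= 0 (s = 1: identity)."""
    if s < 0:
        raise ValueError("scale factor must be >= 0")
    return prestress.scaled(s)
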