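"""Vasodilation scenarios and robustness studies.

Neural activity dilates the vasculature of a small cortical patch, which
(i) stiffens the perfused tissue by a few percent and (ii) increases its
volume by a few percent.  Both are modeled on one (or several) layer
segments of the gyrus: a stiffness change multiplies the local shear
modulus by (1 + c); a volume change of p applies isotropic in-plane
growth g = sqrt(1 + p).  The baseline residual stress estimated by
:mod:`gyrusim.flattening` is applied as initial stress.

A stiffness change acts through the baseline stress: the stress carried
by the stiffened elastic network scales with its shear modulus, so the
activated elements' initial stress is scaled together with mu, creating
a local stress surplus of c * sigma0.  Every scenario is evaluated as
the *difference* between an activated solve and a baseline solve under
identical boundary conditions: a zero parameter change yields exactly
zero displacement, and any residual relaxation drift of the (by default
re-equilibrated) prestress field is recorded in the scenario
diagnostics instead of contaminating the activation response.

All displacements are reported as d_tot = sqrt(u^2 + v^2) in micrometres
at the gyral crown (apex of the pial surface).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gyrusim.geometry import Mesh, CORTICAL_LAYERS
from gyrusim.fem import (
    DeformationState, DirichletBC, MaterialField, PrestressField,
    TISSUE_LABELS, extract_submesh, solve_quasistatic,
)

__all__ = [
    "ActivationSpec", "SweepResult", "ScenarioRun",
    "default_activated_segment", "run_scenario", "sweep", "additivity_gap",
    "layer_depth_study", "segment_extent_study", "parameter_grid_study",
    "tangential_position_study", "crown_displacement", "crown_probe_point",
    "solve_baseline", "ScenarioFixture",
]

SCENARIOS = ("stiffness", "volume", "combined")


@dataclass
class ActivationSpec:
    """Which segments are 'activated' and by how much.

    ``stiffness_change`` / ``volume_change`` are fractions (0.10 = 10%);
    the explored range is capped at ``max_change`` (default the 10% the
    reference study sweeps).  ``use_prestress=None`` selects the scenario
    default: on for stiffness/combined, off for volume (the baseline
    stress is irrelevant for the volume mechanism).
    """

    scenario: str
    segments: list[tuple[int, int]] | None = None
    stiffness_change: float = 0.10
    volume_change: float = 0.10
    step: float = 0.005
    use_prestress: bool | None = None
    max_change: float = 0.10

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"scenario must be one of {SCENARIOS}")
        for name in ("stiffness_change", "volume_change"):
            val = getattr(self, name)
            if not (0.0 <= val <= self.max_change + 1e-12):
                raise ValueError(
                    f"{name} = {val} outside the explored range "
                    f"[0, {self.max_change}]")
        if self.step <= 0:
            raise ValueError("step must be > 0")

    @property
    def prestress_active(self) -> bool:
        if self.use_prestress is not None:
            return self.use_prestress
        return self.scenario in ("stiffness", "combined")

    def change_level(self) -> float:
        """The scenario's headline change fraction."""
        if self.scenario == "stiffness":
            return self.stiffness_change
        if self.scenario == "volume":
            return self.volume_change
        return max(self.stiffness_change, self.volume_change)

    def at_level(self, level: float) -> "ActivationSpec":
        sc = level if self.scenario in ("stiffness", "combined") else 0.0
        vc = level if self.scenario in ("volume", "combined") else 0.0
        return ActivationSpec(self.scenario, self.segments, sc, vc,
                              self.step, self.use_prestress, self.max_change)


@dataclass
class ScenarioRun:
    """A solved scenario: the difference state plus bookkeeping."""

    state: DeformationState         # displacement = activated - baseline
    active_state: DeformationState
    baseline_state: DeformationState | None
    spec: ActivationSpec
    crown_d_tot: float              # micrometres at the crown probe
    baseline_drift: float           # micrometres at the crown probe
    node_map: np.ndarray
    elem_map: np.ndarray


@dataclass
class SweepResult:
    """Parameter sweep of one scenario."""

    levels: np.ndarray              # change fractions, strictly increasing
    crown_d_tot: np.ndarray         # micrometres per level
    slope: float                    # micrometres per percent change
    r_squared: float
    scenario: str
    converged: np.ndarray
    runs: list = field(default_factory=list, repr=False)


def default_activated_segment(mesh: Mesh) -> tuple[int, int]:
    """The L1 segment on the gyral bank at half fold height.

    An asymmetric source on one bank reproduces the lateral
    left-to-right tissue shift of the reference configuration; its
    default position is the left-bank segment containing the point where
    the pial surface crosses half the fold amplitude (the mid-bank
    position of the highlighted segment in the reference figure).
    Mid-bank segments displace the crown in the *same* direction under
    the stiffness and volume mechanisms; segments straddling the apex do
    not, and are never selected (see docs/methods.md).  The exact traced
    layout is not available, so the placement is an approximation.
    """
    if mesh.crown_point is None:
        raise ValueError("mesh has no crown point")
    cx = mesh.crown_point[0]
    pial = mesh.boundary_tags["pial"]
    xy = mesh.nodes[pial]
    left = xy[xy[:, 0] <= cx]
    order = np.argsort(left[:, 0])
    xs, ys = left[order, 0], left[order, 1]
    y_half = 0.5 * (ys.min() + ys.max())
    above = np.flatnonzero(ys >= y_half)
    if len(above) == 0 or above[0] == 0:
        x_half = xs[len(xs) // 2]          # flat slab: mid of the band
    else:
        i = above[0]
        f = (y_half - ys[i - 1]) / max(ys[i] - ys[i - 1], 1e-30)
        x_half = xs[i - 1] + f * (xs[i] - xs[i - 1])
    segs = np.unique(mesh.element_segment[mesh.element_layer == 1])
    cent = mesh.centroids()
    for s in segs:
        m = (mesh.element_layer == 1) & (mesh.element_segment == s)
        if cent[m, 0].min() - 1e-9 <= x_half <= cent[m, 0].max() + 1e-9:
            return (1, int(s))
    return (1, int(segs[len(segs) // 2]))


def _segment_mask(mesh: Mesh, segments) -> np.ndarray:
    mask = np.zeros(mesh.n_elements, dtype=bool)
    for layer, seg in segments:
        m = (mesh.element_layer == layer) & (mesh.element_segment == seg)
        if not m.any():
            raise KeyError(f"segment ({layer}, {seg}) not present in mesh")
        mask |= m
    return mask


def crown_probe_point(mesh: Mesh, inset: float = 0.05) -> np.ndarray:
    """Probe point just inside the pial apex (mesh-independent)."""
    return np.asarray([mesh.crown_point[0], mesh.crown_point[1] - inset])


def _probe_quadratic(state: DeformationState, point) -> tuple[float, float]:
    """(u, v) at a point via quadratic shape functions (mm)."""
    import matplotlib.tri as mtri

    mesh = state.mesh
    tri = mtri.Triangulation(mesh.nodes[:, 0], mesh.nodes[:, 1],
                             mesh.triangles)
    elem = int(tri.get_trifinder()(point[0], point[1]))
    if elem < 0:
        raise ValueError(f"point {point} outside mesh")
    conn = state.p2_triangles[elem]
    p = mesh.nodes[mesh.triangles[elem]]
    T = np.column_stack([p[1] - p[0], p[2] - p[0]])
    xi, eta = np.linalg.solve(T, np.asarray(point) - p[0])
    lam = 1 - xi - eta
    N = np.array([lam * (2 * lam - 1), xi * (2 * xi - 1), eta * (2 * eta - 1),
                  4 * lam * xi, 4 * xi * eta, 4 * eta * lam])
    return float(N @ state.u[conn]), float(N @ state.v[conn])


def crown_displacement(state: DeformationState, mesh: Mesh | None = None) -> float:
    """d_tot (micrometres) at the crown probe point of the state's mesh."""
    mesh = mesh or state.mesh
    u, v = _probe_quadratic(state, crown_probe_point(mesh))
    return float(1e3 * np.hypot(u, v))


def _difference_state(active: DeformationState,
                      baseline: DeformationState | None) -> DeformationState:
    if baseline is None:
        return active
    return DeformationState(
        mesh=active.mesh,
        u=active.u - baseline.u, v=active.v - baseline.v,
        F=active.F, J=active.J, sigma=active.sigma,
        converged=active.converged and baseline.converged,
        residual_norm=max(active.residual_norm, baseline.residual_norm),
        p2_nodes=active.p2_nodes, p2_triangles=active.p2_triangles,
        diagnostics={"active": active.diagnostics,
                     "baseline": baseline.diagnostics})


def solve_baseline(mesh: Mesh, materials: MaterialField,
                   prestress: PrestressField | None,
                   n_increments: int = 10) -> "ScenarioFixture":
    """Prepare the tissue submesh and (if needed) the baseline solve.

    The baseline is the relaxation of the tissue under the mapped-back
    prestress with unmodified materials; its crown drift measures how far
    the prestress is from self-equilibrium.
    """
    sub, node_map, elem_map = extract_submesh(mesh, TISSUE_LABELS)
    mats = MaterialField(materials.mu[elem_map], materials.kappa[elem_map],
                         materials.rho[elem_map])
    ps = (PrestressField(prestress.sigma[elem_map])
          if prestress is not None else None)
    bc = DirichletBC.fix(sub.boundary_tags["domain_exterior"])
    base = None
    if ps is not None and np.any(ps.sigma):
        base = solve_quasistatic(sub, mats, bc, prestress=ps,
                                 n_increments=n_increments)
    return ScenarioFixture(mesh, sub, node_map, elem_map, mats, ps, bc,
                           base, n_increments)


@dataclass
class ScenarioFixture:
    """Reusable pieces shared by all scenario runs on one mesh."""

    mesh: Mesh
    sub: Mesh
    node_map: np.ndarray
    elem_map: np.ndarray
    materials: MaterialField
    prestress: PrestressField | None
    bc: DirichletBC
    baseline: DeformationState | None
    n_increments: int


def run_scenario(mesh: Mesh, materials: MaterialField,
                 prestress: PrestressField | None, spec: ActivationSpec,
                 n_increments: int = 10,
                 fixture: ScenarioFixture | None = None,
                 warm_start: np.ndarray | None = None) -> ScenarioRun:
    """Solve one activation scenario and return the difference state.

    Stiffness scenario: mu -> (1 + stiffness_change) mu on the activated
    elements, prestress applied.  Volume: growth g = sqrt(1 +
    volume_change) on the activated elements (prestress off by default).
    Combined: both simultaneously.
    """
    use_ps = spec.prestress_active
    if fixture is None or (fixture.prestress is None) != (
            prestress is None or not use_ps):
        fixture = solve_baseline(mesh, materials,
                                 prestress if use_ps else None, n_increments)
    sub, elem_map = fixture.sub, fixture.elem_map

    segments = spec.segments or [default_activated_segment(mesh)]
    mask = _segment_mask(sub, segments)

    mats = fixture.materials
    ps_active = fixture.prestress
    if spec.scenario in ("stiffness", "combined") and spec.stiffness_change:
        mats = mats.copy()
        mats.mu = mats.mu.copy()
        mats.mu[mask] *= (1.0 + spec.stiffness_change)
        # The baseline stress of stiffened tissue is carried by its
        # elastic network: at fixed baseline strain it scales with the
        # shear modulus, so the activated elements' initial stress is
        # scaled by the same factor.  This local stress surplus is what
        # drives the stiffness mechanism.
        if ps_active is not None:
            sig = ps_active.sigma.copy()
            sig[mask] *= (1.0 + spec.stiffness_change)
            ps_active = PrestressField(sig)
    growth = None
    if spec.scenario in ("volume", "combined") and spec.volume_change:
        growth = np.ones(sub.n_elements)
        growth[mask] = np.sqrt(1.0 + spec.volume_change)

    no_load = (growth is None and fixture.prestress is None
               and spec.stiffness_change == 0.0)
    if spec.scenario == "stiffness" and fixture.prestress is None:
        # Without baseline stress a stiffness change exerts no force.
        no_load = True

    active = solve_quasistatic(
        sub, mats, fixture.bc, growth=growth, prestress=ps_active,
        n_increments=1 if no_load else n_increments,
        warm_start=warm_start)
    diff = _difference_state(active, fixture.baseline)

    crown = crown_displacement(diff, sub)
    drift = (crown_displacement(fixture.baseline, sub)
             if fixture.baseline is not None else 0.0)
    return ScenarioRun(state=diff, active_state=active,
                       baseline_state=fixture.baseline, spec=spec,
                       crown_d_tot=crown, baseline_drift=drift,
                       node_map=fixture.node_map, elem_map=elem_map)


def sweep(mesh: Mesh, materials: MaterialField,
          prestress: PrestressField | None, spec: ActivationSpec,
          n_increments: int = 10, keep_fields: bool = False) -> SweepResult:
    """Sweep the parameter change from 0 to its maximum in equidistant
    steps and fit a zero-intercept line to crown d_tot vs percent change."""
    max_change = spec.change_level()
    n_levels = int(round(max_change / spec.step))
    levels = np.linspace(0.0, max_change, n_levels + 1)

    fixture = solve_baseline(mesh, materials,
                             prestress if spec.prestress_active else None,
                             n_increments)
    crown = np.zeros(len(levels))
    conv = np.ones(len(levels), dtype=bool)
    runs = []
    warm = None
    for i, lev in enumerate(levels[1:], start=1):
        run = run_scenario(mesh, materials, prestress, spec.at_level(lev),
                           n_increments=1, fixture=fixture, warm_start=warm)
        crown[i] = run.crown_d_tot
        conv[i] = run.state.converged
        warm = np.column_stack([run.active_state.u,
                                run.active_state.v]).ravel()
        if keep_fields:
            runs.append(run)

    pct = 100.0 * levels
    denom = float(pct @ pct)
    slope = float(pct @ crown) / denom if denom > 0 else 0.0
    resid = crown - slope * pct
    ss_tot = float(crown @ crown)
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return SweepResult(levels=levels, crown_d_tot=crown, slope=slope,
                       r_squared=r2, scenario=spec.scenario, converged=conv,
                       runs=runs)


def additivity_gap(stiff: DeformationState, vol: DeformationState,
                   comb: DeformationState, point) -> float:
    """|d_comb - (d_stiff + d_vol)| (micrometres) at a probe point.

    The three states must come from the same fixture (identical meshes).
    """
    for other in (vol, comb):
        if (other.mesh.n_nodes != stiff.mesh.n_nodes
                or not np.array_equal(other.mesh.triangles,
                                      stiff.mesh.triangles)):
            raise ValueError("states come from different fixtures")
    d = []
    for st in (stiff, vol, comb):
        u, v = _probe_quadratic(st, point)
        d.append(1e3 * np.hypot(u, v))
    return float(abs(d[2] - (d[0] + d[1])))


def layer_depth_study(mesh: Mesh, materials: MaterialField,
                      prestress: PrestressField | None, scenario: str,
                      change: float = 0.10, segment_index: int | None = None,
                      n_increments: int = 10) -> pd.DataFrame:
    """Activate the same tangential segment in each layer i = 1..6.

    Returns a table with the crown d_tot, the segment area A_i and the
    area-normalized response d_tot / A_i per layer.
    """
    from gyrusim.geometry import region_area

    if segment_index is None:
        segment_index = default_activated_segment(mesh)[1]
    spec0 = _scenario_spec(scenario, change)
    fixture = solve_baseline(mesh, materials,
                             prestress if spec0.prestress_active else None,
                             n_increments)
    rows = []
    for layer in range(1, 7):
        spec = _scenario_spec(scenario, change, [(layer, segment_index)])
        run = run_scenario(mesh, materials, prestress, spec,
                           n_increments=n_increments, fixture=fixture)
        area = region_area(mesh, (layer, segment_index))
        rows.append({"layer": layer, "segment": segment_index,
                     "d_tot_um": run.crown_d_tot, "area_mm2": area,
                     "d_per_area": run.crown_d_tot / area,
                     "converged": run.state.converged})
    return pd.DataFrame(rows)


def tangential_position_study(mesh: Mesh, materials: MaterialField,
                              prestress: PrestressField | None, scenario: str,
                              change: float = 0.10, layer: int = 1,
                              n_increments: int = 10) -> pd.DataFrame:
    """Move the activated segment tangentially at fixed layer depth."""
    spec0 = _scenario_spec(scenario, change)
    fixture = solve_baseline(mesh, materials,
                             prestress if spec0.prestress_active else None,
                             n_increments)
    segs = np.unique(mesh.element_segment[mesh.element_layer == layer])
    rows = []
    for seg in segs:
        spec = _scenario_spec(scenario, change, [(layer, int(seg))])
        run = run_scenario(mesh, materials, prestress, spec,
                           n_increments=n_increments, fixture=fixture)
        rows.append({"layer": layer, "segment": int(seg),
                     "d_tot_um": run.crown_d_tot,
                     "converged": run.state.converged})
    return pd.DataFrame(rows)


def segment_extent_study(mesh: Mesh, materials: MaterialField,
                         prestress: PrestressField | None, scenario: str,
                         extents=(1, 2, 3, 4), mode: str = "radial",
                         change: float = 0.10,
                         n_increments: int = 10) -> pd.DataFrame:
    """Grow the activated region from one segment to several.

    ``mode="radial"`` extends in depth (L1..Ln at the same tangential
    index); ``mode="tangential"`` extends laterally within L1, growing
    up the bank from the default mid-bank segment (staying on one bank,
    so the added sources displace the crown coherently).
    """
    if mode not in ("radial", "tangential"):
        raise ValueError("mode must be 'radial' or 'tangential'")
    layer0, seg0 = default_activated_segment(mesh)
    spec0 = _scenario_spec(scenario, change)
    fixture = solve_baseline(mesh, materials,
                             prestress if spec0.prestress_active else None,
                             n_increments)
    rows = []
    for n in extents:
        if mode == "radial":
            segments = [(layer, seg0) for layer in range(1, n + 1)]
        else:
            segments = [(layer0, seg0 + k) for k in range(n)]
        spec = _scenario_spec(scenario, change, segments)
        run = run_scenario(mesh, materials, prestress, spec,
                           n_increments=n_increments, fixture=fixture)
        rows.append({"extent": n, "mode": mode,
                     "d_tot_um": run.crown_d_tot,
                     "converged": run.state.converged})
    return pd.DataFrame(rows)


def parameter_grid_study(mesh: Mesh, mu_values, kappa_values, scenario: str,
                         change: float, prestress: PrestressField | None,
                         wm_ratio: float = 1.357,
                         n_increments: int = 10) -> pd.DataFrame:
    """Crown d_tot over a grid of baseline GM stiffness and bulk modulus.

    The WM shear modulus is tied to the GM one by ``wm_ratio`` (the ~35%
    contrast of the reference materials).  The prestress field is held
    fixed across the grid, matching the robustness protocol it mimics.
    """
    rows = []
    for mu_gm in mu_values:
        for kappa in kappa_values:
            mats = MaterialField.from_regions(
                mesh,
                mu={**{lab: float(mu_gm) for lab in CORTICAL_LAYERS},
                    "GM_surround": float(mu_gm),
                    "WM": float(mu_gm) * wm_ratio},
                kappa=float(kappa))
            spec = _scenario_spec(scenario, change)
            run = run_scenario(mesh, mats, prestress, spec,
                               n_increments=n_increments)
            rows.append({"mu_gm": float(mu_gm), "kappa": float(kappa),
                         "d_tot_um": run.crown_d_tot,
                         "converged": run.state.converged})
    return pd.DataFrame(rows)


def _scenario_spec(scenario: str, change: float,
                   segments=None) -> ActivationSpec:
    return ActivationSpec(
        scenario=scenario, segments=segments,
        stiffness_change=change if scenario in ("stiffness", "combined") else 0.0,
        volume_change=change if scenario in ("volume", "combined") else 0.0)
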