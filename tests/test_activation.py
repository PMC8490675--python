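"""Vasodilation scenarios: zero-change behavior, sweeps, additivity,
layer-depth / extent / parameter-grid studies."""

import numpy as np
import pytest

from gyrusim import activation as act
from gyrusim.activation import (
    ActivationSpec, additivity_gap, crown_displacement, crown_probe_point,
    default_activated_segment, layer_depth_study, parameter_grid_study,
    run_scenario, segment_extent_study, sweep,
)
from gyrusim.fem import MaterialField, total_displacement_field
from gyrusim.flattening import flatten
from gyrusim.geometry import CORTICAL_LAYERS


class TestActivationSpec:
    def test_scenario_validated(self):
        with pytest.raises(ValueError):
            ActivationSpec("melt")

    def test_change_range_enforced(self):
        with pytest.raises(ValueError, match="explored range"):
            ActivationSpec("stiffness", stiffness_change=0.2)
        ActivationSpec("stiffness", stiffness_change=0.2, max_change=0.5)

    def test_prestress_defaults_per_scenario(self):
        assert ActivationSpec("stiffness").prestress_active
        assert ActivationSpec("combined").prestress_active
        assert not ActivationSpec("volume").prestress_active

    def test_default_segment_on_flank(self, small_mesh):
        layer, seg = default_activated_segment(small_mesh)
        assert layer == 1
        # not the crown-straddling segment
        cx = small_mesh.crown_point[0]
        cent = small_mesh.centroids()
        m = (small_mesh.element_layer == 1) & (small_mesh.element_segment == seg)
        assert cent[m, 0].max() < cx


class TestRunScenario:
    def test_zero_change_zero_displacement(self, small_mesh, small_materials,
                                           small_flattening):
        spec = ActivationSpec("stiffness", stiffness_change=0.0)
        run = run_scenario(small_mesh, small_materials,
                           small_flattening.prestress, spec, n_increments=1)
        assert run.crown_d_tot == pytest.approx(0.0, abs=1e-9)
        assert np.abs(run.state.u).max() < 1e-12

    def test_orderings_match_reference_pattern(self, small_runs):
        d = {k: r.crown_d_tot for k, r in small_runs.items()}
        assert d["volume"] > d["stiffness"]
        assert d["combined"] > d["volume"]
        assert d["combined"] > d["stiffness"]

    def test_baseline_drift_recorded(self, small_runs):
        run = small_runs["stiffness"]
        assert run.baseline_drift > 0.0

    def test_displacement_peaks_in_fold_and_decays(self, small_runs):
        """The pial displacement peaks within the fold (activated flank /
        crown region) and decays with distance from the gyrus peak."""
        run = small_runs["combined"]
        sub = run.state.mesh
        pial = sub.boundary_tags["pial"]
        d = total_displacement_field(run.state)[pial]
        x = sub.nodes[pial, 0]
        peak_x = x[np.argmax(d)]
        assert abs(peak_x - sub.crown_point[0]) < 2.5
        far = np.abs(x - sub.crown_point[0]) > 2.5
        assert d[far].max() < 0.5 * d.max()


class TestSweep:
    @pytest.fixture(scope="class")
    def sweeps(self, small_mesh, small_materials, small_flattening):
        out = {}
        for scenario in ("stiffness", "volume", "combined"):
            spec = act._scenario_spec(scenario, 0.10)
            spec.step = 0.025
            out[scenario] = sweep(small_mesh, small_materials,
                                  small_flattening.prestress, spec,
                                  n_increments=1)
        return out

    def test_linearity(self, sweeps):
        for scenario, sw in sweeps.items():
            assert sw.r_squared > 0.99, scenario
            assert sw.crown_d_tot[0] == 0.0
            assert np.all(np.diff(sw.levels) > 0)

    def test_volume_slope_exceeds_stiffness_slope(self, sweeps):
        assert sweeps["volume"].slope > sweeps["stiffness"].slope

    def test_per_percent_field_level_independent(
            self, small_mesh, small_materials, small_flattening):
        """d_tot field divided by the percent change is the same at 5%
        and 10% within 2% (spatial linearity)."""
        fields = {}
        for level in (0.05, 0.10):
            spec = act._scenario_spec("volume", level)
            run = run_scenario(small_mesh, small_materials,
                               small_flattening.prestress, spec,
                               n_increments=2)
            fields[level] = total_displacement_field(run.state) / (100 * level)
        a, b = fields[0.05], fields[0.10]
        scale = b.max()
        assert np.abs(a - b).max() < 0.02 * scale

    def test_stiffness_response_invariant_under_mu_doubling(
            self, small_mesh, small_materials, small_flattening):
        """Doubling every shear modulus doubles the flattening stresses,
        so the stiffness-scenario displacement (driven by prestress/mu)
        is unchanged within 5%."""
        spec = act._scenario_spec("stiffness", 0.10)
        base = run_scenario(small_mesh, small_materials,
                            small_flattening.prestress, spec, n_increments=2)
        mats2 = MaterialField(2 * small_materials.mu,
                              2 * small_materials.kappa,
                              small_materials.rho)
        flat2 = flatten(small_mesh, mats2, n_steps=12, mu_gm=2800.0)
        run2 = run_scenario(small_mesh, mats2, flat2.prestress, spec,
                            n_increments=2)
        assert run2.crown_d_tot == pytest.approx(base.crown_d_tot, rel=0.05)


class TestAdditivity:
    def test_gap_vanishes_with_zero_volume_state(
            self, small_runs, small_mesh, small_materials, small_flattening):
        # comb vs (comb + zero-change volume state) -> exactly zero gap
        zero = run_scenario(small_mesh, small_materials,
                            small_flattening.prestress,
                            ActivationSpec("volume", volume_change=0.0,
                                           use_prestress=True),
                            n_increments=1)
        comb = small_runs["combined"].state
        gap = additivity_gap(comb, zero.state, comb,
                             crown_probe_point(small_mesh))
        assert gap == pytest.approx(0.0, abs=1e-9)

    def test_mechanisms_nearly_additive(self, small_runs, small_mesh):
        gap = additivity_gap(small_runs["stiffness"].state,
                             small_runs["volume"].state,
                             small_runs["combined"].state,
                             crown_probe_point(small_mesh))
        total = small_runs["combined"].crown_d_tot
        # the residual is the second-order coupling of the two mechanisms
        # through the shared segment (~5% of the response here)
        assert gap < 0.08 * total

    def test_mismatched_fixture_rejected(self, small_runs, small_geometry,
                                         small_materials, small_mesh):
        import gyrusim as gs
        other_mesh = gs.triangulate(small_geometry, 0.35)
        mats = MaterialField.from_regions(other_mesh)
        spec = act._scenario_spec("volume", 0.10)
        other = run_scenario(other_mesh, mats, None, spec, n_increments=1)
        with pytest.raises(ValueError, match="fixture"):
            additivity_gap(small_runs["stiffness"].state, other.state,
                           small_runs["combined"].state,
                           crown_probe_point(small_mesh))


class TestStudies:
    def test_layer_depth_study(self, small_mesh, small_materials,
                               small_flattening):
        table = layer_depth_study(small_mesh, small_materials,
                                  small_flattening.prestress, "volume",
                                  change=0.10, n_increments=1)
        assert list(table["layer"]) == [1, 2, 3, 4, 5, 6]
        assert table["converged"].all()
        areas = [table.loc[table.layer == i, "area_mm2"].item()
                 for i in range(1, 7)]
        assert all(a > 0 for a in areas)
        # the absolute response is largest for the (thickest) layer 3
        d = table["d_tot_um"].to_numpy()
        assert int(table["layer"][np.argmax(d)]) == 3

    def test_layer_normalized_response_decays_with_depth(
            self, small_mesh, small_materials, small_flattening):
        """Normalized by segment area, the stiffness response of the
        outermost layer exceeds the innermost by more than 2x."""
        table = layer_depth_study(small_mesh, small_materials,
                                  small_flattening.prestress, "stiffness",
                                  change=0.10, n_increments=1)
        norm = table["d_per_area"].to_numpy()
        assert norm[0] / norm[-1] > 2.0
        corr = np.corrcoef(table["layer"], norm)[0, 1]
        assert corr < 0

    def test_zero_change_layer_row(self, small_mesh, small_materials,
                                   small_flattening):
        spec = ActivationSpec("volume", segments=[(3, 2)], volume_change=0.0)
        run = run_scenario(small_mesh, small_materials,
                           small_flattening.prestress, spec, n_increments=1)
        assert run.crown_d_tot == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("mode", ["radial", "tangential"])
    def test_extent_monotone(self, small_mesh, small_materials,
                             small_flattening, mode):
        table = segment_extent_study(small_mesh, small_materials,
                                     small_flattening.prestress, "volume",
                                     extents=(1, 2, 3), mode=mode,
                                     change=0.10, n_increments=1)
        d = table["d_tot_um"].to_numpy()
        assert np.all(np.diff(d) > 0)

    def test_extent_one_reproduces_run_scenario(self, small_mesh,
                                                small_materials,
                                                small_flattening):
        table = segment_extent_study(small_mesh, small_materials,
                                     small_flattening.prestress, "volume",
                                     extents=(1,), mode="radial",
                                     change=0.10, n_increments=1)
        spec = act._scenario_spec(
            "volume", 0.10, [default_activated_segment(small_mesh)])
        run = run_scenario(small_mesh, small_materials,
                           small_flattening.prestress, spec, n_increments=1)
        assert table["d_tot_um"].iloc[0] == pytest.approx(run.crown_d_tot,
                                                          rel=1e-9)

    def test_parameter_grid_kappa_insensitive_mu_scaling(
            self, small_mesh, small_flattening):
        """Bulk modulus variation across the literature range changes the
        response by < 1%; the response scales inversely with the baseline
        stiffness when the stress field is held fixed."""
        table = parameter_grid_study(
            small_mesh, mu_values=(800.0, 4000.0),
            kappa_values=(0.5e9, 5e9), scenario="stiffness", change=0.02,
            prestress=small_flattening.prestress, n_increments=1)
        assert table["converged"].all()
        for mu in (800.0, 4000.0):
            sub = table[table.mu_gm == mu]["d_tot_um"].to_numpy()
            assert abs(sub[0] - sub[1]) < 0.01 * sub.mean()
        lo = table[table.mu_gm == 800.0]["d_tot_um"].mean()
        hi = table[table.mu_gm == 4000.0]["d_tot_um"].mean()
        # fixed stress field: softer tissue moves further, ~1/mu
        assert lo / hi == pytest.approx(4000.0 / 800.0, rel=0.25)

    def test_grid_linearity_between_change_levels(
            self, small_mesh, small_flattening):
        t2 = parameter_grid_study(small_mesh, (1400.0,), (1.4e9,),
                                  "stiffness", 0.02,
                                  small_flattening.prestress, n_increments=1)
        t10 = parameter_grid_study(small_mesh, (1400.0,), (1.4e9,),
                                   "stiffness", 0.10,
                                   small_flattening.prestress, n_increments=1)
        ratio = t10["d_tot_um"].iloc[0] / t2["d_tot_um"].iloc[0]
        assert ratio == pytest.approx(5.0, rel=0.05)
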