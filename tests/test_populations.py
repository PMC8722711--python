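"""Trajectory populations and extracellular potential sampling."""

import numpy as np
import pytest

from injectsim import build_default_configuration
from injectsim.populations import (
    generate_cutaneous_population,
    generate_vagus_population,
    sample_potentials,
)
from injectsim.recruitment import cable_for_class


class TestVagusPopulation:
    def test_count_matches_circle_enumeration(self, full_config):
        fibers = generate_vagus_population(full_config)
        # independent brute-force enumeration of the 100 um grid in a circle
        r = full_config.nerve.diameter / 2
        s = 100e-6
        count = 0
        n = int(np.floor(r / s))
        for i in range(-n, n + 1):
            for j in range(-n, n + 1):
                if (i * s) ** 2 + (j * s) ** 2 < r**2:
                    count += 1
        assert len(fibers) == count

    def test_coarse_grid_keeps_center_fiber(self, full_config):
        fibers = generate_vagus_population(
            full_config, spacing=full_config.nerve.diameter)
        assert len(fibers) >= 1

    def test_trajectories_inside_nerve_cylinder(self, full_config):
        g = full_config.geometry
        r = full_config.nerve.diameter / 2
        cy = g.domain_width / 2
        zc = full_config.nerve.depth_below_surface
        for f in generate_vagus_population(full_config, spacing_scale=3.0):
            pts = f.points()
            rad = np.hypot(pts[:, 1] - cy, pts[:, 2] - zc)
            assert np.all(rad < r)

    def test_generation_is_deterministic(self, full_config):
        a = generate_vagus_population(full_config, spacing_scale=3.0)
        b = generate_vagus_population(full_config, spacing_scale=3.0)
        assert [f.fiber_id for f in a] == [f.fiber_id for f in b]
        assert all(fa.polyline == fb.polyline for fa, fb in zip(a, b))


class TestCutaneousPopulation:
    def test_grid_count_for_5cm_patch(self):
        cfg = build_default_configuration("full_biophysical", patch_side=0.05)
        patch = cfg.return_electrode()
        fibers = generate_cutaneous_population(cfg, patch, "cutaneous_Abeta")
        # 60 x 60 mm footprint (patch + 5 mm margins) on a 1.5 mm grid
        assert len(fibers) == 41 * 41

    @pytest.mark.parametrize("cls, depth", [
        ("cutaneous_Abeta", 900e-6), ("cutaneous_Adelta", 500e-6),
    ])
    def test_terminal_depths(self, full_config, cls, depth):
        patch = full_config.return_electrode()
        fibers = generate_cutaneous_population(full_config, patch, cls,
                                               spacing_scale=3.0)
        assert all(f.points()[0][2] == pytest.approx(depth) for f in fibers)
        assert all(f.terminal_depth == depth for f in fibers)

    def test_run_depth_and_margin(self, full_config):
        patch = full_config.return_electrode()
        x0, x1, y0, y1 = patch.bounds()
        fibers = generate_cutaneous_population(
            full_config, patch, "cutaneous_Abeta", spacing_scale=3.0)
        xs = np.array([f.points()[0][0] for f in fibers])
        ys = np.array([f.points()[0][1] for f in fibers])
        assert xs.min() == pytest.approx(x0 - 5e-3)
        assert ys.min() == pytest.approx(y0 - 5e-3)
        assert all(f.points()[-1][2] == pytest.approx(4e-3) for f in fibers)

    def test_patch_too_close_to_domain_edge_rejected(self):
        cfg = build_default_configuration("full_biophysical", patch_side=0.10)
        patch = cfg.return_electrode()
        with pytest.raises(ValueError, match="domain"):
            generate_cutaneous_population(cfg, patch, "cutaneous_Abeta")


class TestPotentialSampling:
    def test_uniform_gradient_samples_linearly(self, full_solution):
        # overwrite the field with a synthetic uniform-gradient potential:
        # samples along a straight fiber must be linear in arc length
        import copy

        sol = copy.copy(full_solution)
        mesh = sol.system.mesh
        coords = mesh.node_coords()
        sol = sol.scaled(0.0)
        sol.potentials = 5.0 * coords[:, 0] + 2.0 * coords[:, 2]
        sol._interp_cache = None
        fibers = generate_vagus_population(sol.system.config, spacing_scale=8.0)
        cable = cable_for_class("vagus_Abeta", n_nodes=11)
        d = sample_potentials(sol, fibers[0], cable.morphology, center=0.05)
        ve = d.ve_unit
        s = cable.morphology.arc_um  # compartments are non-uniformly spaced
        fit = np.polyval(np.polyfit(s, ve, 1), s)
        assert np.max(np.abs(ve - fit)) < 0.01 * np.ptp(ve)

    def test_amplitude_linearity_is_exact(self, full_solution):
        # solving at twice the drive amplitude leaves the per-unit drive
        # unchanged (the per-compartment drive itself scales exactly 2x)
        from injectsim import DriveSpec, solve

        fibers = generate_vagus_population(full_solution.system.config,
                                           spacing_scale=8.0)
        cable = cable_for_class("vagus_Abeta", n_nodes=11)
        d1 = sample_potentials(full_solution, fibers[0], cable.morphology,
                               center=0.05)
        doubled = solve(full_solution.system, DriveSpec("current", 2.0, 0.0))
        d2 = sample_potentials(doubled, fibers[0], cable.morphology,
                               center=0.05)
        assert np.allclose(d2.ve_unit, d1.ve_unit, rtol=1e-9)

    def test_mirror_symmetric_fibers_see_mirror_fields(self, full_solution):
        cfg = full_solution.system.config
        cy = cfg.geometry.domain_width / 2
        fibers = generate_vagus_population(cfg, spacing_scale=4.0)
        by_offset = {round((f.points()[0][1] - cy) / 1e-6): f for f in fibers}
        cable = cable_for_class("vagus_Abeta", n_nodes=11)
        for off in sorted(k for k in by_offset if k > 0):
            up = sample_potentials(full_solution, by_offset[off],
                                   cable.morphology, center=0.05)
            dn = sample_potentials(full_solution, by_offset[-off],
                                   cable.morphology, center=0.05)
            assert np.allclose(up.ve_unit, dn.ve_unit, rtol=1e-4)

    def test_out_of_domain_compartment_reported(self, full_solution):
        from injectsim.populations import FiberTrajectory

        # short polyline heading out of the domain: arc-mapped compartments
        # extrapolate past x = 0
        bad = FiberTrajectory(
            fiber_id="bad", fiber_class="vagus_Abeta",
            polyline=((0.005, 0.055, 0.026), (0.0, 0.055, 0.026)),
        )
        cable = cable_for_class("vagus_Abeta", n_nodes=21)
        with pytest.raises(ValueError, match="arc position"):
            sample_potentials(full_solution, bad, cable.morphology,
                              center="start")
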