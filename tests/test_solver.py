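"""Field solver: assembly, circuit coupling, conservation, analytic limits."""

from dataclasses import replace

import numpy as np
import pytest

from injectsim import (
    DriveSpec,
    LayeredGeometry,
    ModelConfiguration,
    SurfaceElectrode,
    TissueMaterial,
    assemble,
    build_default_configuration,
    compute_metrics,
    generate_mesh,
    solve,
    surface_current_density,
)
from injectsim.oracles import SlabOracle, slab_impedance
from injectsim.solver import boundary_current_imbalance


def make_slab_config(material: TissueMaterial, thicknesses=(1e-3, 5e-3, 40e-3)):
    """Uniform-material stack with a full-face plate: a 1D slab problem.

    The square patch covers the entire (square) top face; the mesh's ground
    set is replaced by the bottom face so the current path is purely
    vertical (zero-normal-current laterally).
    """
    geom = LayeredGeometry(
        domain_length=0.11, domain_width=0.11,
        skin_thickness=thicknesses[0], fat_thickness=thicknesses[1],
        muscle_thickness=thicknesses[2],
    )
    electrode = SurfaceElectrode(
        side_length=0.11, center_xy=(0.055, 0.055), polarity="source",
        hydrogel_thickness=1e-3, hydrogel_material=replace(material, name="hydrogel"),
    )
    mats = {name: replace(material, name=name)
            for name in ("skin", "fat", "muscle")}
    cfg = ModelConfiguration(
        geometry=geom, materials=mats, electrodes=(electrode,),
        collectors=(), load=None, nerve=None, mode="monopolar",
        variant="simplified",
    )
    mesh = generate_mesh(cfg, "coarse")
    nx, ny, nz = mesh.shape_nodes
    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    mesh.ground_nodes = mesh.node_index(I.ravel(), J.ravel(), nz - 1)
    return cfg, mesh


class TestAssembly:
    def test_dc_matrix_is_real(self, coarse_system):
        K = coarse_system.matrix(0.0)
        assert K.dtype == np.float64

    def test_ac_matrix_is_complex_with_displacement_term(self, coarse_system):
        assert coarse_system.matrix(1e3).dtype == np.complex128

    def test_gauge_error_without_reference(self, coarse_mesh, simplified_config):
        system = assemble(coarse_mesh, simplified_config)  # fresh, mutated below
        system.electrode_dofs = system.electrode_dofs[:1]  # drop the return
        with pytest.raises(ValueError, match="gauge"):
            solve(system, DriveSpec("current", 1e-3, 0.0))


class TestSlabOracle:
    """Full solver against the exact 1D layered-slab impedance."""

    @pytest.mark.parametrize("frequency", [0.0, 1e2, 1e3, 1e4, 2.5e4])
    def test_uniform_slab_impedance(self, frequency):
        mat = TissueMaterial("uniform", 0.1, 1e4)
        cfg, mesh = make_slab_config(mat)
        system = assemble(mesh, cfg)
        sol = solve(system, DriveSpec("current", 1e-3, frequency, "monopolar"))
        z_fem = sol.v_tes / sol.i_tes
        oracle = SlabOracle(
            thicknesses=(1e-3, 1e-3, 5e-3, 40e-3),  # hydrogel + 3 layers
            materials=(mat,) * 4, plate_area=0.11 * 0.11,
        )
        z_exact = slab_impedance(oracle, frequency)
        assert abs(z_fem - z_exact) / abs(z_exact) < 0.01

    def test_three_material_slab_dc_resistance(self):
        # distinct layer conductivities; DC resistance = sum d_i/(sigma_i A)
        cfg, mesh = make_slab_config(TissueMaterial("uniform", 1.0, 1e3))
        mats = {
            "skin": TissueMaterial("skin", 1.80e-4, 1.17e3),
            "fat": TissueMaterial("fat", 2.46e-2, 2.08e4),
            "muscle": TissueMaterial("muscle", 5.23e-1, 1.24e6),
        }
        cfg = cfg.with_materials(**mats)
        gel = cfg.electrodes[0].hydrogel_material
        sol = solve(assemble(mesh, cfg), DriveSpec("current", 1e-3, 0.0, "monopolar"))
        a = 0.11 * 0.11
        z_exact = (1e-3 / (gel.conductivity * a)
                   + 1e-3 / (1.80e-4 * a) + 5e-3 / (2.46e-2 * a)
                   + 40e-3 / (5.23e-1 * a))
        assert sol.v_tes / sol.i_tes == pytest.approx(z_exact, rel=0.01)


class TestSolveProperties:
    def test_linearity_exact(self, coarse_system):
        a = solve(coarse_system, DriveSpec("current", 19e-3, 0.0))
        b = solve(coarse_system, DriveSpec("current", 38e-3, 0.0))
        assert b.load_current == pytest.approx(2 * a.load_current, rel=1e-9)
        m_a, m_b = compute_metrics(a), compute_metrics(b)
        assert m_b.i_nerve == pytest.approx(2 * m_a.i_nerve, rel=1e-9)
        assert m_b.efficiency == pytest.approx(m_a.efficiency, rel=1e-9)

    def test_reciprocity_on_asymmetric_geometry(self):
        # different collector sizes: swapping source/return patches must
        # leave |I_Nerve| unchanged for this passive linear network
        cfg = build_default_configuration("simplified")
        colls = (replace(cfg.collectors[0], diameter=0.015), cfg.collectors[1])
        cfg = replace(cfg, collectors=colls)
        mesh = generate_mesh(cfg, "coarse")
        fwd = solve(assemble(mesh, cfg), DriveSpec("current", 19e-3, 0.0))
        swapped = replace(cfg, electrodes=(
            replace(cfg.electrodes[0], polarity="return"),
            replace(cfg.electrodes[1], polarity="source"),
        ))
        # electrode order in the mesh is positional; rebuild with the new roles
        cfg2 = replace(swapped, electrodes=(swapped.electrodes[1],
                                            swapped.electrodes[0]))
        rev = solve(assemble(generate_mesh(cfg2, "coarse"), cfg2),
                    DriveSpec("current", 19e-3, 0.0))
        assert abs(rev.load_current) == pytest.approx(abs(fwd.load_current),
                                                      rel=1e-6)

    def test_dc_limit_of_frequency_domain(self, coarse_system, dc_solution):
        tiny = solve(coarse_system, DriveSpec("current", 19e-3, 1e-8))
        assert np.allclose(np.real(tiny.potentials), dc_solution.potentials,
                           rtol=1e-9, atol=1e-12, equal_nan=True)

    def test_zero_drive_is_identically_zero(self, coarse_system):
        sol = solve(coarse_system, DriveSpec("current", 0.0, 0.0))
        m = compute_metrics(sol)
        assert np.nanmax(np.abs(sol.potentials)) == 0
        assert m.i_tes == 0 and m.i_nerve == 0
        assert not m.efficiency_defined

    def test_charge_conservation(self, dc_solution, hf_solution):
        assert boundary_current_imbalance(dc_solution) < 1e-3
        assert boundary_current_imbalance(hf_solution) < 1e-3

    def test_high_frequency_less_efficient_than_dc(self, dc_solution,
                                                   hf_solution):
        assert (compute_metrics(hf_solution).efficiency
                < compute_metrics(dc_solution).efficiency)

    def test_monopolar_less_efficient_than_bipolar(self, dc_solution):
        cfg = build_default_configuration("simplified", mode="monopolar")
        sol = solve(assemble(generate_mesh(cfg, "coarse"), cfg),
                    DriveSpec("current", 19e-3, 0.0, "monopolar"))
        assert (compute_metrics(sol).efficiency
                < compute_metrics(dc_solution).efficiency)

    def test_voltage_drive_consistent_with_current_drive(self, coarse_system,
                                                         dc_solution):
        v = solve(coarse_system,
                  DriveSpec("voltage", float(np.real(dc_solution.v_tes)), 0.0))
        assert abs(v.i_tes) == pytest.approx(19e-3, rel=1e-6)


class TestSurfaceCurrentDensity:
    def test_facet_currents_sum_to_drive(self, dc_solution):
        _, dens, areas = surface_current_density(dc_solution, 0)
        total = float(np.sum(dens * areas))
        assert total == pytest.approx(19e-3, rel=5e-3)

    def test_uniform_slab_density_is_uniform(self):
        mat = TissueMaterial("uniform", 0.1, 1e4)
        cfg, mesh = make_slab_config(mat)
        sol = solve(assemble(mesh, cfg), DriveSpec("current", 1e-3, 0.0, "monopolar"))
        _, dens, areas = surface_current_density(sol, 0)
        expected = 1e-3 / (0.11 * 0.11)
        assert np.all(np.abs(dens / expected - 1) < 0.02)

    def test_resistive_hydrogel_flattens_edge_density(self, dc_solution,
                                                      simplified_config):
        # a near-perfectly conducting interlayer stands in for "no hydrogel"
        centers, dens, _ = surface_current_density(dc_solution, 0)
        metal_gel = TissueMaterial("hydrogel", 1e3, 1.0)
        els = tuple(replace(e, hydrogel_material=metal_gel)
                    for e in simplified_config.electrodes)
        bare = replace(simplified_config, electrodes=els)
        sol2 = solve(assemble(generate_mesh(bare, "coarse"), bare),
                     DriveSpec("current", 19e-3, 0.0))
        _, dens2, _ = surface_current_density(sol2, 0)

        def edge_to_center(c, d):
            cx = c[:, 0].mean()
            cy = c[:, 1].mean()
            r = np.hypot(c[:, 0] - cx, c[:, 1] - cy)
            edge = np.abs(d[r > 0.8 * r.max()]).mean()
            center = np.abs(d[r < 0.3 * r.max()]).mean()
            return edge / center

        assert edge_to_center(centers, dens) < edge_to_center(centers, dens2)

    def test_unknown_electrode_rejected(self, dc_solution):
        with pytest.raises(ValueError, match="electrode"):
            surface_current_density(dc_solution, 7)
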