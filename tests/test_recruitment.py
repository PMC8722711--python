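"""Threshold search and population recruitment statistics."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from injectsim import DriveSpec, assemble, generate_mesh, solve
from injectsim.axon import ExtracellularDrive, build_axon, build_cable, \
    detect_propagation_batch, focus_node, integrate
from injectsim.recruitment import (
    RecruitmentSummary,
    cable_for_class,
    find_threshold,
    find_thresholds_batch,
    population_thresholds,
    selectivity_ratios,
    strip_injectrode,
)

from .helpers import point_source_drive


@pytest.fixture(scope="module")
def small_cable():
    return build_cable(build_axon(10.0, 15))


class TestBinarySearch:
    def test_matches_brute_force_sweep_on_three_axons(self, small_cable):
        """Bisection to 1 uA equals an exhaustive 1 uA amplitude sweep."""
        m = small_cable.morphology
        for dist in (1e-3, 2e-3, 4e-3):
            drive = point_source_drive(m, distance_m=dist)
            res = find_threshold(small_cable, drive)
            assert res.converged
            # brute force: walk upward in 1 uA steps from below the bracket
            focus = focus_node(m, drive.ve_unit)
            start = res.threshold_ma - 0.05
            amp = start
            found = None
            while amp <= res.threshold_ma + 0.05:
                traj = integrate(small_cable, drive, amp, early_stop=True)
                if detect_propagation_batch(traj, m, np.array([focus]))[0]:
                    found = amp
                    break
                amp += 1e-3
            assert found == pytest.approx(res.threshold_ma, abs=1.5e-3)

    def test_bracket_invariant(self, small_cable):
        m = small_cable.morphology
        drive = point_source_drive(m)
        res = find_threshold(small_cable, drive)
        sub, supra = res.bracket
        assert supra - sub <= 1e-3 + 1e-12
        focus = focus_node(m, drive.ve_unit)
        for amp, expect in ((sub, False), (supra, True)):
            traj = integrate(small_cable, drive, amp, early_stop=True)
            assert detect_propagation_batch(
                traj, m, np.array([focus]))[0] == expect

    def test_search_cap_below_threshold_reports_unconverged(self, small_cable):
        drive = point_source_drive(small_cable.morphology)
        res = find_threshold(small_cable, drive, search_cap_ma=0.05)
        assert not res.converged
        assert np.isnan(res.threshold_ma)

    def test_repeatability_is_bit_exact(self, small_cable):
        drive = point_source_drive(small_cable.morphology)
        a = find_threshold(small_cable, drive)
        b = find_threshold(small_cable, drive)
        assert a.threshold_ma == b.threshold_ma
        assert a.bracket == b.bracket

    def test_batch_matches_single_fiber_results(self, small_cable):
        m = small_cable.morphology
        drives = [point_source_drive(m, distance_m=d) for d in (1e-3, 3e-3)]
        ve = np.stack([d.ve_unit for d in drives])
        th, conv, _ = find_thresholds_batch(small_cable, ve)
        for d, t in zip(drives, th):
            assert find_threshold(small_cable, d).threshold_ma == t


class TestPopulationThresholds:
    @pytest.fixture(scope="class")
    def tiny_study(self, full_config, full_solution):
        from injectsim.populations import generate_vagus_population

        tes = strip_injectrode(full_config)
        sol_tes = solve(assemble(generate_mesh(tes, "coarse"), tes),
                        DriveSpec("current", 1.0, 0.0))
        pops = {"vagus_Abeta": generate_vagus_population(
            full_config, spacing_scale=10.0)}
        return population_thresholds(
            {"injectrode": full_solution, "tes_alone": sol_tes}, pops, 0.02)

    def test_injectrode_always_lowers_vagal_thresholds(self, tiny_study):
        inj = tiny_study["injectrode"].data.set_index("fiber_id")
        tes = tiny_study["tes_alone"].data.set_index("fiber_id")
        joined = inj.join(tes, lsuffix="_inj", rsuffix="_tes")
        assert (joined.threshold_ma_inj < joined.threshold_ma_tes).all()

    def test_summary_medians_over_converged_only(self, tiny_study):
        s = tiny_study["injectrode"]
        med = s.median("vagus_Abeta")
        d = s.data[s.data.converged]
        assert med == pytest.approx(float(np.median(d.threshold_ma)))

    def test_empty_population_rejected(self, full_solution):
        with pytest.raises(ValueError, match="empty"):
            population_thresholds({"injectrode": full_solution}, {}, 0.02)

    def test_threshold_scales_with_conductivity_and_load(self, full_config):
        """Scaling every conductivity by k scales all thresholds by k."""
        from injectsim.populations import generate_vagus_population

        k = 2.0
        pops = generate_vagus_population(full_config, spacing_scale=15.0)[:2]
        cable = cable_for_class("vagus_Abeta", n_nodes=21)
        sols = []
        for factor in (1.0, k):
            mats = {
                name: m.with_conductivity(m.conductivity * factor)
                for name, m in full_config.materials.items()
            }
            # every conductive element scales: tissues, hydrogel, nerve,
            # and the contact impedance (a resistance, scaled by 1/k)
            cfg = replace(
                full_config, materials=mats,
                electrodes=tuple(
                    replace(e, hydrogel_material=e.hydrogel_material
                            .with_conductivity(
                                e.hydrogel_material.conductivity * factor))
                    for e in full_config.electrodes),
                collectors=tuple(
                    replace(c, contact_impedance=c.contact_impedance / factor)
                    for c in full_config.collectors),
                nerve=replace(
                    full_config.nerve,
                    material=full_config.nerve.material.with_conductivity(
                        full_config.nerve.material.conductivity * factor)),
            )
            sols.append(solve(assemble(generate_mesh(cfg, "coarse"), cfg),
                              DriveSpec("current", 1.0, 0.0)))
        from injectsim.populations import sample_potentials

        for f in pops:
            t = []
            for sol in sols:
                d = sample_potentials(sol, f, cable.morphology, center="auto")
                t.append(find_threshold(cable, d).threshold_ma)
            assert t[1] == pytest.approx(k * t[0], rel=0.01)


class TestSelectivityRatios:
    def _summary(self, df, condition):
        return RecruitmentSummary(data=df, condition=condition,
                                  patch_side_m=0.02)

    def test_identical_populations_give_unit_ratio(self):
        rng = np.random.default_rng(5)
        th = rng.uniform(1, 10, 30)
        rows = []
        for cls in ("vagus_Abeta", "cutaneous_Abeta"):
            for i, t in enumerate(th):
                rows.append({"fiber_id": f"{cls}_{i}", "fiber_class": cls,
                             "threshold_ma": t, "converged": True})
        df = pd.DataFrame(rows)
        table = selectivity_ratios(self._summary(df, "injectrode"),
                                   self._summary(df, "tes_alone"))
        assert (table.ratio == 1.0).all()

    def test_underpowered_classes_are_flagged(self):
        rows = [{"fiber_id": f"v{i}", "fiber_class": "vagus_Abeta",
                 "threshold_ma": 1.0 + i, "converged": True} for i in range(4)]
        rows += [{"fiber_id": f"c{i}", "fiber_class": "cutaneous_Abeta",
                  "threshold_ma": 0.5, "converged": True} for i in range(12)]
        df = pd.DataFrame(rows)
        table = selectivity_ratios(self._summary(df, "injectrode"),
                                   self._summary(df, "tes_alone"))
        assert table.underpowered.all()
        assert (table.n_vagus == 4).all()

    def test_top10_uses_ten_lowest_thresholds(self):
        df = pd.DataFrame([
            {"fiber_id": f"v{i}", "fiber_class": "vagus_Abeta",
             "threshold_ma": float(i + 1), "converged": True}
            for i in range(20)
        ])
        s = self._summary(df, "injectrode")
        med, n = s.top10_median("vagus_Abeta")
        assert n == 10
        assert med == pytest.approx(np.median(np.arange(1, 11, dtype=float)))
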