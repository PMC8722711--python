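"""Parameter sweeps and sensitivity analyses of the coupling model.

Every sweep anchors on the standard configuration and varies exactly one
parameter, mirroring the study design; results are tidy DataFrames (one row
per parameter value and drive condition).  Sweeps are deterministic and
reproducible bit-exactly from the configuration they record.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .geometry import ModelConfiguration, build_default_configuration
from .mesh import generate_mesh
from .populations import generate_cutaneous_population, generate_vagus_population
from .recruitment import (
    RecruitmentSummary,
    population_thresholds,
    selectivity_ratios,
    strip_injectrode,
)
from .solver import (
    DriveSpec,
    assemble,
    compute_metrics,
    solve,
    surface_current_density,
)

DEFAULT_CURRENT_A = 19e-3
DEFAULT_VOLTAGE_V = 28.0


@dataclass(frozen=True)
class SweepSpec:
    """One-parameter sweep description (recorded in every result)."""

    parameter: str
    values: tuple
    resolution: str = "coarse"
    drive_modes: tuple = ("current",)
    frequencies: tuple = (0.0,)


@dataclass
class SweepResult:
    spec: SweepSpec
    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _solve_metrics(config: ModelConfiguration, resolution: str,
                   drive: DriveSpec):
    mesh = generate_mesh(config, resolution)
    system = assemble(mesh, config)
    sol = solve(system, drive)
    return sol, compute_metrics(sol)


def run_collector_diameter_sweep(
    diameters_m: Iterable[float] = (0.005, 0.01, 0.021, 0.03, 0.04, 0.05, 0.06, 0.07),
    resolution: str = "coarse",
    conditions: tuple = (("bipolar", 0.0), ("bipolar", 1e4), ("monopolar", 0.0)),
) -> SweepResult:
    """Efficiency vs collector diameter (collector center spacing fixed)."""
    rows = []
    for d in diameters_m:
        for mode, freq in conditions:
            cfg = build_default_configuration(
                "simplified", collector_diameter=d, mode=mode)
            _, m = _solve_metrics(cfg, resolution,
                                  DriveSpec("current", DEFAULT_CURRENT_A, freq, mode))
            rows.append({
                "collector_diameter_m": d, "mode": mode, "frequency_hz": freq,
                "efficiency_pct": m.efficiency, "i_nerve_ma": m.i_nerve,
                "i_tes_ma": m.i_tes, "v_tes_v": m.v_tes,
            })
    spec = SweepSpec("collector_diameter", tuple(diameters_m), resolution)
    return SweepResult(spec, pd.DataFrame(rows))


def run_collector_depth_sweep(
    depths_m: Iterable[float] = (0.5e-3, 1e-3, 1.5e-3, 2e-3, 3e-3, 4e-3, 5e-3),
    resolution: str = "coarse",
) -> SweepResult:
    """DC efficiency vs collector depth (0.5 mm = mid-skin .. 5 mm)."""
    rows = []
    for depth in depths_m:
        cfg = build_default_configuration("simplified", collector_depth=depth)
        _, m = _solve_metrics(cfg, resolution,
                              DriveSpec("current", DEFAULT_CURRENT_A, 0.0))
        rows.append({
            "collector_depth_m": depth, "efficiency_pct": m.efficiency,
            "i_nerve_ma": m.i_nerve,
        })
    spec = SweepSpec("collector_depth", tuple(depths_m), resolution)
    return SweepResult(spec, pd.DataFrame(rows))


def run_patch_size_sweep(
    sides_m: Iterable[float] = (0.01, 0.02, 0.03, 0.04, 0.05, 0.06, 0.07),
    resolution: str = "coarse",
) -> SweepResult:
    """I_Nerve / mean surface current density vs patch side (2 cm gap)."""
    rows = []
    for side in sides_m:
        cfg = build_default_configuration("simplified", patch_side=side)
        sol, m = _solve_metrics(cfg, resolution,
                                DriveSpec("current", DEFAULT_CURRENT_A, 0.0))
        _, dens, areas = surface_current_density(sol, 0)
        mean_dens = float(np.sum(np.abs(dens) * areas) / np.sum(areas))
        rows.append({
            "patch_side_m": side, "efficiency_pct": m.efficiency,
            "i_nerve_ma": m.i_nerve,
            "mean_surface_density_a_m2": mean_dens,
            "nerve_to_density_ratio": (m.i_nerve / 1e3) / mean_dens,
        })
    spec = SweepSpec("patch_side", tuple(sides_m), resolution)
    return SweepResult(spec, pd.DataFrame(rows))


def run_separation_sweep(
    separations_m: Iterable[float] = (0.0005, 0.005, 0.01, 0.02, 0.03, 0.04, 0.05, 0.06),
    resolution: str = "coarse",
) -> SweepResult:
    """DC efficiency vs edge-to-edge patch separation (collectors centered)."""
    rows = []
    for sep in separations_m:
        cfg = build_default_configuration("simplified", separation=sep)
        _, m = _solve_metrics(cfg, resolution,
                              DriveSpec("current", DEFAULT_CURRENT_A, 0.0))
        rows.append({
            "separation_m": sep, "efficiency_pct": m.efficiency,
            "i_nerve_ma": m.i_nerve,
        })
    spec = SweepSpec("separation", tuple(separations_m), resolution)
    return SweepResult(spec, pd.DataFrame(rows))


_SENSITIVITY_DEFAULTS = {
    "offset": (-0.02, -0.014, -0.01, -0.005, 0.0, 0.005, 0.01, 0.014, 0.02),
    "skin_sigma": (0.5, 0.75, 1.0, 1.25, 1.5),
    "skin_eps": (0.5, 0.75, 1.0, 1.25, 1.5),
    "skin_thickness": (0.5e-3, 0.75e-3, 1e-3, 1.5e-3, 2e-3),
    "fat_sigma": (0.5, 0.75, 1.0, 1.25, 1.5),
    "fat_eps": (0.5, 0.75, 1.0, 1.25, 1.5),
}


def run_patient_sensitivity(
    parameter: str,
    values: Optional[Iterable] = None,
    drive_modes: tuple = ("current", "voltage"),
    frequency: float = 0.0,
    resolution: str = "coarse",
) -> SweepResult:
    """I_Nerve stability to patient-dependent variations, both drive modes.

    ``parameter``: offset (patch shift along x, m), skin_sigma / skin_eps /
    fat_sigma / fat_eps (multiplicative factors on the default property), or
    skin_thickness (m).  The stability metric (max relative deviation of
    I_Nerve across the sweep) is in ``result.metadata``.
    """
    if parameter not in _SENSITIVITY_DEFAULTS:
        raise ValueError(f"unknown sensitivity parameter {parameter!r}")
    values = tuple(values) if values is not None else _SENSITIVITY_DEFAULTS[parameter]
    rows = []
    for v in values:
        cfg = build_default_configuration("simplified")
        if parameter == "offset":
            els = tuple(
                replace(e, center_xy=(e.center_xy[0] + v, e.center_xy[1]))
                for e in cfg.electrodes
            )
            cfg = replace(cfg, electrodes=els)
        elif parameter == "skin_thickness":
            cfg = replace(cfg, geometry=replace(cfg.geometry, skin_thickness=v))
        else:
            layer, prop = parameter.split("_")
            mat = cfg.materials[layer]
            if prop == "sigma":
                mat = replace(mat, conductivity=mat.conductivity * v)
            else:
                mat = replace(mat, relative_permittivity=mat.relative_permittivity * v)
            cfg = cfg.with_materials(**{layer: mat})
        for mode in drive_modes:
            amp = DEFAULT_CURRENT_A if mode == "current" else DEFAULT_VOLTAGE_V
            _, m = _solve_metrics(cfg, resolution, DriveSpec(mode, amp, frequency))
            rows.append({
                "parameter": parameter, "value": v, "drive_mode": mode,
                "frequency_hz": frequency, "i_nerve_ma": m.i_nerve,
                "efficiency_pct": m.efficiency,
            })
    table = pd.DataFrame(rows)
    stability = {}
    for mode in drive_modes:
        t = table[table.drive_mode == mode]
        ref = t.i_nerve_ma.iloc[len(t) // 2] if parameter != "offset" else \
            t[t.value == 0.0].i_nerve_ma.iloc[0] if (t.value == 0.0).any() else \
            t.i_nerve_ma.iloc[len(t) // 2]
        stability[mode] = float(np.max(np.abs(t.i_nerve_ma - ref) / ref))
    spec = SweepSpec(parameter, values, resolution, drive_modes, (frequency,))
    return SweepResult(spec, table, metadata={"max_relative_deviation": stability})


def run_biophysical_study(
    patch_sides_m: Iterable[float] = (0.02, 0.03, 0.05),
    conditions: tuple = ("injectrode", "tes_alone"),
    classes: tuple = ("vagus_Abeta", "cutaneous_Abeta", "cutaneous_Adelta"),
    spacing_scale: float = 3.0,
    resolution: str = "coarse",
    **search_kwargs,
) -> dict:
    """Recruitment study across patch sizes and Injectrode conditions.

    Returns {"summaries": {(side, condition): RecruitmentSummary},
    "ratios": DataFrame of top-10 vagus/cutaneous Abeta threshold ratios}.
    """
    summaries: dict = {}
    ratio_frames = []
    for side in patch_sides_m:
        cfg = build_default_configuration(
            "full_biophysical", patch_side=side, separation=0.02)
        patch = cfg.return_electrode()
        pops = {}
        for cls in classes:
            if cls == "vagus_Abeta":
                pops[cls] = generate_vagus_population(cfg, spacing_scale=spacing_scale)
            else:
                pops[cls] = generate_cutaneous_population(
                    cfg, patch, cls, spacing_scale=spacing_scale)
        sols = {}
        for cond in conditions:
            c = cfg if cond == "injectrode" else strip_injectrode(cfg)
            mesh = generate_mesh(c, resolution)
            sols[cond] = solve(assemble(mesh, c), DriveSpec("current", 1.0, 0.0))
        res = population_thresholds(
            sols, pops, side,
            metadata={"spacing_scale": spacing_scale, "resolution": resolution},
            **search_kwargs,
        )
        for cond, summary in res.items():
            summaries[(side, cond)] = summary
        if "injectrode" in res and "tes_alone" in res and "cutaneous_Abeta" in classes:
            ratio_frames.append(
                selectivity_ratios(res["injectrode"], res["tes_alone"]))
    ratios = pd.concat(ratio_frames, ignore_index=True) if ratio_frames else None
    return {"summaries": summaries, "ratios": ratios}
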