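"""Configuration files, result serialization, field export, run manifests.

All physical quantities in configuration files carry explicit unit suffixes
in their keys (``_m``, ``_ohm``, ``_S_per_m`` ...) to prevent unit bugs.
Unknown keys are rejected by name.  Field exports use the legacy ASCII VTK
unstructured-grid format (readable by ParaView and by :func:`import_fields`
for round-trips).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .geometry import (
    CircuitLoad,
    Collector,
    LayeredGeometry,
    ModelConfiguration,
    NerveSpec,
    SurfaceElectrode,
)
from .materials import TissueMaterial
from .mesh import VolumeMesh
from .solver import FieldSolution
from .sweeps import SweepSpec


# ---------------------------------------------------------------------------
# configuration serialization
# ---------------------------------------------------------------------------

def _material_to_dict(m: TissueMaterial) -> dict:
    d = {
        "conductivity_S_per_m": float(m.conductivity),
        "relative_permittivity": float(m.relative_permittivity),
    }
    if m.allow_nonphysical:
        d["allow_nonphysical"] = True
    return d


def _material_from_dict(name: str, d: dict) -> TissueMaterial:
    _check_keys(d, {"conductivity_S_per_m", "relative_permittivity",
                    "allow_nonphysical"}, f"materials.{name}")
    return TissueMaterial(
        name=name,
        conductivity=d["conductivity_S_per_m"],
        relative_permittivity=d.get("relative_permittivity", 1.0),
        allow_nonphysical=d.get("allow_nonphysical", False),
    )


def _check_keys(d: dict, allowed: set, where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


def config_to_dict(config: ModelConfiguration) -> dict:
    g = config.geometry
    out = {
        "variant": config.variant,
        "mode": config.mode,
        "geometry": {
            "domain_length_m": g.domain_length,
            "domain_width_m": g.domain_width,
            "skin_thickness_m": g.skin_thickness,
            "fat_thickness_m": g.fat_thickness,
            "muscle_thickness_m": g.muscle_thickness,
        },
        "materials": {
            name: _material_to_dict(m) for name, m in sorted(config.materials.items())
        },
        "electrodes": [
            {
                "side_length_m": e.side_length,
                "center_x_m": e.center_xy[0],
                "center_y_m": e.center_xy[1],
                "polarity": e.polarity,
                "hydrogel_thickness_m": e.hydrogel_thickness,
                "hydrogel_material": _material_to_dict(e.hydrogel_material),
            }
            for e in config.electrodes
        ],
        "collectors": [
            {
                "diameter_m": c.diameter,
                "depth_below_surface_m": c.depth_below_surface,
                "center_x_m": c.center_xy[0],
                "center_y_m": c.center_xy[1],
                "contact_impedance_ohm_m2": c.contact_impedance,
            }
            for c in config.collectors
        ],
    }
    if config.load is not None:
        out["load"] = {
            "resistance_ohm": config.load.resistance,
            "terminals": list(config.load.terminals),
        }
    if config.nerve is not None:
        n = config.nerve
        out["nerve"] = {
            "diameter_m": n.diameter,
            "depth_below_surface_m": n.depth_below_surface,
            "cuff_length_m": n.cuff_length,
            "material": _material_to_dict(n.material),
        }
    return out


def config_from_dict(d: dict) -> ModelConfiguration:
    _check_keys(d, {"variant", "mode", "geometry", "materials", "electrodes",
                    "collectors", "load", "nerve", "sweep"}, "configuration")
    gd = d["geometry"]
    _check_keys(gd, {"domain_length_m", "domain_width_m", "skin_thickness_m",
                     "fat_thickness_m", "muscle_thickness_m"}, "geometry")
    geometry = LayeredGeometry(
        domain_length=gd["domain_length_m"],
        domain_width=gd["domain_width_m"],
        skin_thickness=gd["skin_thickness_m"],
        fat_thickness=gd["fat_thickness_m"],
        muscle_thickness=gd["muscle_thickness_m"],
    )
    materials = {
        name: _material_from_dict(name, md) for name, md in d["materials"].items()
    }
    electrodes = []
    for ed in d["electrodes"]:
        _check_keys(ed, {"side_length_m", "center_x_m", "center_y_m", "polarity",
                         "hydrogel_thickness_m", "hydrogel_material"}, "electrodes[]")
        electrodes.append(SurfaceElectrode(
            side_length=ed["side_length_m"],
            center_xy=(ed["center_x_m"], ed["center_y_m"]),
            polarity=ed["polarity"],
            hydrogel_thickness=ed.get("hydrogel_thickness_m", 1e-3),
            hydrogel_material=_material_from_dict(
                "hydrogel", ed["hydrogel_material"]),
        ))
    collectors = []
    for cd in d.get("collectors", []):
        _check_keys(cd, {"diameter_m", "depth_below_surface_m", "center_x_m",
                         "center_y_m", "contact_impedance_ohm_m2"}, "collectors[]")
        collectors.append(Collector(
            diameter=cd["diameter_m"],
            depth_below_surface=cd["depth_below_surface_m"],
            center_xy=(cd["center_x_m"], cd["center_y_m"]),
            contact_impedance=cd["contact_impedance_ohm_m2"],
        ))
    load = None
    if "load" in d:
        _check_keys(d["load"], {"resistance_ohm", "terminals"}, "load")
        load = CircuitLoad(
            resistance=d["load"]["resistance_ohm"],
            terminals=tuple(d["load"]["terminals"]),
        )
    nerve = None
    if "nerve" in d:
        nd = d["nerve"]
        _check_keys(nd, {"diameter_m", "depth_below_surface_m", "cuff_length_m",
                         "material"}, "nerve")
        nerve = NerveSpec(
            diameter=nd["diameter_m"],
            depth_below_surface=nd["depth_below_surface_m"],
            cuff_length=nd["cuff_length_m"],
            material=_material_from_dict("epineurium", nd["material"]),
        )
    return ModelConfiguration(
        geometry=geometry, materials=materials,
        electrodes=tuple(electrodes), collectors=tuple(collectors),
        load=load, nerve=nerve, mode=d.get("mode", "bipolar"),
        variant=d.get("variant", "simplified"),
    )


def save_config(config: ModelConfiguration, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


def load_config(path) -> tuple[ModelConfiguration, Optional[SweepSpec]]:
    """Load and validate a configuration (+ optional sweep section)."""
    d = yaml.safe_load(Path(path).read_text())
    config = config_from_dict(d)
    sweep = None
    if "sweep" in d:
        sd = d["sweep"]
        _check_keys(sd, {"parameter", "values", "resolution"}, "sweep")
        sweep = SweepSpec(
            parameter=sd["parameter"], values=tuple(sd["values"]),
            resolution=sd.get("resolution", "coarse"),
        )
    return config, sweep


def config_hash(config: ModelConfiguration) -> str:
    text = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# VTK field export (legacy ASCII unstructured grid)
# ---------------------------------------------------------------------------

# VTK_HEXAHEDRON ordering relative to our (x fastest, y, z) local ordering
_VTK_ORDER = [0, 1, 3, 2, 4, 5, 7, 6]


def export_fields(solution: FieldSolution, mesh: VolumeMesh, path) -> None:
    """Write potential (magnitude/phase) and current density to a VTK file."""
    path = Path(path)
    conn, mats, sizes = mesh.cells()
    coords = mesh.node_coords()
    v = solution.potentials
    vmag = np.abs(np.nan_to_num(v))
    vphase = np.angle(np.nan_to_num(v)) if np.iscomplexobj(v) else np.zeros_like(vmag)

    # cell-centered current density J = -sigma* grad(V) (real part exported)
    from .materials import EPS0
    from .solver import _default_material

    sig = np.empty(len(mesh.material_names), dtype=complex)
    for i, name in enumerate(mesh.material_names):
        mat = solution.system.config.materials.get(name)
        if mat is None:
            mat = _default_material(solution.system.config, name)
        sig[i] = mat.admittivity(solution.frequency)
    ve = np.nan_to_num(v)[conn]  # (N, 8)
    dx, dy, dz = sizes.T
    gx = (ve[:, [1, 3, 5, 7]].sum(1) - ve[:, [0, 2, 4, 6]].sum(1)) / (4 * dx)
    gy = (ve[:, [2, 3, 6, 7]].sum(1) - ve[:, [0, 1, 4, 5]].sum(1)) / (4 * dy)
    gz = (ve[:, [4, 5, 6, 7]].sum(1) - ve[:, [0, 1, 2, 3]].sum(1)) / (4 * dz)
    J = -np.real(sig[mats][:, None] * np.column_stack([gx, gy, gz]))

    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("electroquasistatic field solution\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(coords)} double\n")
        np.savetxt(f, coords, fmt="%.9g")
        f.write(f"CELLS {len(conn)} {len(conn) * 9}\n")
        cells = np.column_stack([np.full(len(conn), 8), conn[:, _VTK_ORDER]])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {len(conn)}\n")
        np.savetxt(f, np.full(len(conn), 12), fmt="%d")
        f.write(f"POINT_DATA {len(coords)}\n")
        f.write("SCALARS potential_magnitude double 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, vmag, fmt="%.9g")
        f.write("SCALARS potential_phase double 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, vphase, fmt="%.9g")
        f.write(f"CELL_DATA {len(conn)}\n")
        f.write("VECTORS current_density double\n")
        np.savetxt(f, J, fmt="%.9g")


def import_fields(path) -> dict:
    """Minimal reader for files written by :func:`export_fields`."""
    lines = Path(path).read_text().splitlines()
    i = 0
    out: dict = {}

    def read_block(n, ncol):
        nonlocal i
        rows = []
        while len(rows) < n:
            rows.extend([lines[i].split()])
            i += 1
        a = np.array(rows, dtype=float)
        return a if ncol > 1 else a.ravel()

    while i < len(lines):
        line = lines[i]
        i += 1
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            out["points"] = read_block(n, 3)
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            i += 1  # LOOKUP_TABLE
            out[name] = read_block(len(out["points"]), 1)
        elif line.startswith("VECTORS"):
            name = line.split()[1]
            out[name] = read_block(out["n_cells"], 3)
        elif line.startswith("CELLS "):
            out["n_cells"] = int(line.split()[1])
    return out


# ---------------------------------------------------------------------------
# trace CSV and run manifest
# ---------------------------------------------------------------------------

def write_traces_csv(traces, path) -> None:
    """CSV mirror of a TimeTraceSet (time_s, v_tes_V, i_tes_mA, i_nerve_mA)."""
    import pandas as pd

    pd.DataFrame({
        "time_s": traces.time, "v_tes_V": traces.v_tes,
        "i_tes_mA": traces.i_tes, "i_nerve_mA": traces.i_nerve,
    }).to_csv(path, index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written atomically at the end of a run."""

    config_hash: str
    code_version: str
    resolution: str
    seed: Optional[int]
    outputs: dict  # filename -> sha256
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def write_manifest(out_dir, config: ModelConfiguration, resolution: str,
                   outputs: list, seed: Optional[int] = None,
                   parameters: Optional[dict] = None) -> RunManifest:
    out_dir = Path(out_dir)
    manifest = RunManifest(
        config_hash=config_hash(config),
        code_version=__version__,
        resolution=resolution,
        seed=seed,
        outputs={Path(p).name: _sha256(Path(p)) for p in outputs},
        parameters=parameters or {},
    )
    tmp = out_dir / ".manifest.json.tmp"
    tmp.write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True))
    os.replace(tmp, out_dir / "manifest.json")
    save_config(config, out_dir / "config.yaml")
    return manifest


def read_manifest(out_dir) -> RunManifest:
    d = json.loads((Path(out_dir) / "manifest.json").read_text())
    return RunManifest(**d)
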