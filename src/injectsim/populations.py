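"""Axon trajectory populations and extracellular potential sampling.

Two deterministic populations mirror the study design: straight vagal axons
seeded on a regular grid across the nerve cross-section (100 um spacing), and
cutaneous afferents whose terminals tile a regular grid under the active
surface patch (1.5 mm spacing, +5 mm margin) at class-specific depths --
900 um for Abeta endings, 500 um for Adelta endings.  Each cutaneous fiber
runs parallel to the nerve at 4 mm depth in fat and rises to its terminal
along a straight oblique segment.

``spacing_scale`` multiplies the grid spacings (scaled-down populations for
desk-scale runs); population counts remain deterministic functions of the
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .axon import AxonMorphology, ExtracellularDrive
from .geometry import ModelConfiguration, SurfaceElectrode
from .solver import FieldSolution

VAGUS_GRID_SPACING = 100e-6
CUTANEOUS_GRID_SPACING = 1.5e-3
CUTANEOUS_MARGIN = 5e-3
CUTANEOUS_RUN_DEPTH = 4e-3
TERMINAL_DEPTH = {"cutaneous_Abeta": 900e-6, "cutaneous_Adelta": 500e-6}
RISE_HORIZONTAL = 3e-3  # horizontal extent of the oblique rising branch


@dataclass(frozen=True)
class FiberTrajectory:
    fiber_id: str
    fiber_class: str  # vagus_Abeta | cutaneous_Abeta | cutaneous_Adelta
    polyline: tuple  # ((x, y, z), ...) in m
    terminal_depth: Optional[float] = None
    # direction of the terminal arbor (negative arc coordinates); cutaneous
    # arbors spread horizontally under the epidermis at terminal depth
    arbor_direction: Optional[tuple] = None

    def points(self) -> np.ndarray:
        return np.asarray(self.polyline, dtype=float)

    def arc_lengths(self) -> np.ndarray:
        p = self.points()
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass(frozen=True)
class PopulationGrid:
    """Bookkeeping for one regular seed/terminal grid."""

    spacing: float
    extent: tuple
    points: tuple


def generate_vagus_population(
    config: ModelConfiguration,
    spacing: float = VAGUS_GRID_SPACING,
    spacing_scale: float = 1.0,
) -> list[FiberTrajectory]:
    """Straight axons seeded on a regular grid inside the nerve cross-section.

    The grid is centered on the nerve axis; every grid point strictly inside
    the circular cross-section seeds one axon running the full nerve length.
    """
    nerve = config.nerve
    if nerve is None:
        raise ValueError("configuration has no nerve")
    g = config.geometry
    s = spacing * spacing_scale
    r = nerve.diameter / 2.0
    zc = nerve.depth_below_surface
    cy = g.domain_width / 2.0
    n = int(np.floor(r / s))
    offsets = np.arange(-n, n + 1) * s
    fibers = []
    k = 0
    for dy in offsets:
        for dz in offsets:
            if dy * dy + dz * dz < r * r:
                fibers.append(FiberTrajectory(
                    fiber_id=f"vagus_{k:05d}",
                    fiber_class="vagus_Abeta",
                    polyline=((0.0, cy + dy, zc + dz),
                              (g.domain_length, cy + dy, zc + dz)),
                ))
                k += 1
    return fibers


def generate_cutaneous_population(
    config: ModelConfiguration,
    patch: SurfaceElectrode,
    fiber_class: str,
    spacing: float = CUTANEOUS_GRID_SPACING,
    margin: float = CUTANEOUS_MARGIN,
    spacing_scale: float = 1.0,
) -> list[FiberTrajectory]:
    """Cutaneous afferent trajectories terminating under `patch`.

    Terminals tile the patch footprint extended by `margin` on all four
    sides.  Each trajectory descends obliquely from its terminal to a
    horizontal run at 4 mm depth heading toward the domain center (parallel
    to the nerve axis).
    """
    if fiber_class not in TERMINAL_DEPTH:
        raise ValueError(f"unknown cutaneous class {fiber_class!r}")
    g = config.geometry
    depth = TERMINAL_DEPTH[fiber_class]
    s = spacing * spacing_scale
    x0, x1, y0, y1 = patch.bounds()
    gx0, gx1 = x0 - margin, x1 + margin
    gy0, gy1 = y0 - margin, y1 + margin
    if gx0 < 0 or gy0 < 0 or gx1 > g.domain_length or gy1 > g.domain_width:
        raise ValueError("cutaneous terminal grid extends outside the domain")
    nx = int(np.floor((gx1 - gx0) / s + 1e-9)) + 1
    ny = int(np.floor((gy1 - gy0) / s + 1e-9)) + 1
    run_len = 0.05
    fibers = []
    k = 0
    for i in range(nx):
        xt = gx0 + i * s
        direction = 1.0 if xt < g.domain_length / 2.0 else -1.0
        for j in range(ny):
            yt = gy0 + j * s
            bend = (xt + direction * RISE_HORIZONTAL, yt, CUTANEOUS_RUN_DEPTH)
            far_x = np.clip(bend[0] + direction * run_len, 0.0, g.domain_length)
            fibers.append(FiberTrajectory(
                fiber_id=f"{fiber_class}_{k:05d}",
                fiber_class=fiber_class,
                polyline=((xt, yt, depth), bend, (far_x, yt, CUTANEOUS_RUN_DEPTH)),
                terminal_depth=depth,
                arbor_direction=(-direction, 0.0, 0.0),
            ))
            k += 1
    return fibers


def _field_interpolator(solution: FieldSolution, method: str = "pchip"):
    """Shape-preserving C1 interpolant of the nodal potential field (cached).

    Neural sampling needs better than trilinear interpolation: a merely C0
    interpolant has slope kinks at every cell face which appear as spurious
    spikes in the activating function (second spatial difference along a
    fiber) and can dominate thresholds on graded meshes.  Ordinary cubic
    splines instead overshoot at the genuine derivative jumps across layer
    interfaces.  Tensor-product PCHIP is C1 and monotonicity-preserving:
    smooth where the field is smooth, no ringing at material interfaces.
    """
    cache = getattr(solution, "_interp_cache", None)
    if cache is not None and cache[0] == method:
        return cache[1]
    mesh = solution.system.mesh
    shape = mesh.shape_nodes
    vals = np.nan_to_num(
        np.real(solution.potentials[: mesh.n_grid_nodes])
    ).reshape(shape)
    interp = RegularGridInterpolator(
        (mesh.x, mesh.y, mesh.z), vals, method=method,
        bounds_error=False, fill_value=None,
    )
    solution._interp_cache = (method, interp)
    return interp


def _points_along(traj: FiberTrajectory, s: np.ndarray) -> np.ndarray:
    """3D points at (possibly out-of-range) arc coordinates along a polyline.

    Coordinates beyond either end extrapolate along the first/last segment
    direction (used by terminal arbors extending past the terminal point).
    """
    p = traj.points()
    arcs = traj.arc_lengths()
    out = np.empty((len(s), 3))
    for d in range(3):
        out[:, d] = np.interp(s, arcs, p[:, d])
    before = s < 0
    if before.any():
        if traj.arbor_direction is not None:
            d0 = -np.asarray(traj.arbor_direction, dtype=float)
        else:
            d0 = p[1] - p[0]
        d0 = d0 / np.linalg.norm(d0)
        out[before] = p[0] + np.outer(s[before], d0)
    beyond = s > arcs[-1]
    if beyond.any():
        d1 = p[-1] - p[-2]
        d1 = d1 / np.linalg.norm(d1)
        out[beyond] = p[-1] + np.outer(s[beyond] - arcs[-1], d1)
    return out


def sample_potentials(
    solution: FieldSolution,
    trajectory: FiberTrajectory,
    morphology: AxonMorphology,
    center: str | float = "auto",
    pulse_width_ms: float = 0.3,
) -> ExtracellularDrive:
    """Interpolate the unit-drive potential field onto compartment midpoints.

    The field is sampled (shape-preserving C1 interpolation) at compartment
    midpoints mapped by arc length along the trajectory polyline.  ``center`` places the
    morphology on the (possibly much longer) trajectory:

    * ``"start"`` -- compartment 0 at the polyline start (cutaneous fibers:
      the terminal is compartment 0);
    * ``"auto"`` -- centered on the site of maximal activating function of
      the full-length trajectory (desk-scale stand-in for an axon spanning
      the whole trajectory);
    * a float -- explicit arc coordinate (m) for the morphology midpoint.

    The returned drive is in mV per mA of stimulus (== V/A), exact in
    amplitude by linearity of the field problem.
    """
    interp = _field_interpolator(solution)
    amp_a = abs(solution.drive.amplitude)
    if amp_a == 0:
        raise ValueError("unit field must be solved with a nonzero drive")
    arcs = trajectory.arc_lengths()
    total = arcs[-1]
    comp_arc = morphology.arc_um * 1e-6  # signed, terminal/first node at 0

    if center == "start":
        shift = 0.0
    elif center == "auto":
        delta = morphology.geometry.internode_length * 1e-6
        sgrid = np.arange(0.0, total + delta / 2, delta)
        ve_line = interp(_points_along(trajectory, sgrid))
        f = np.empty_like(ve_line)
        f[1:-1] = ve_line[:-2] - 2 * ve_line[1:-1] + ve_line[2:]
        f[0], f[-1] = f[1], f[-2]
        sign = np.sign(solution.drive.amplitude) or 1.0
        s_star = sgrid[int(np.argmax(sign * f))]
        half = (comp_arc.max() - max(comp_arc.min(), 0.0)) / 2.0
        shift = float(np.clip(s_star - half, 0.0, max(total - 2 * half, 0.0)))
    else:
        shift = float(center) - (comp_arc.max() + max(comp_arc.min(), 0.0)) / 2.0

    s = comp_arc + shift
    pts = _points_along(trajectory, s)
    mesh = solution.system.mesh
    lo = np.array([mesh.x[0], mesh.y[0], 0.0])
    hi = np.array([mesh.x[-1], mesh.y[-1], mesh.z[-1]])
    outside = (pts < lo - 1e-9) | (pts > hi + 1e-9)
    if outside.any():
        bad = int(np.argwhere(outside.any(axis=1))[0][0])
        raise ValueError(
            f"compartment at arc position {s[bad] * 1e3:.2f} mm lies outside "
            "the meshed domain"
        )
    # V per A is numerically identical to mV per mA
    ve_unit = interp(pts) / amp_a
    return ExtracellularDrive(ve_unit=ve_unit, pulse_width_ms=pulse_width_ms)
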