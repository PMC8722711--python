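"""Structured graded hexahedral meshing of the layered model.

The grid is a tensor product of three monotone plane arrays (x, y, z).  All
geometric features (patch edges, collector extents and depths, layer
boundaries, the nerve cylinder bounding box) are snapped onto grid planes so
electrode/collector footprints resolve to whole boundary facets.  Grading is
piecewise-uniform: every interval between consecutive feature planes is
subdivided against a local target size that is finer near electrodes,
collectors, and the nerve.

Disc and cylinder footprints are staircase approximations; coupling areas are
rescaled so the total contact area matches the exact analytic area (the
documented area-correction factor).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .geometry import ModelConfiguration

Resolution = Literal["coarse", "standard", "fine"]

# lateral target sizes (fine-near-feature, far-field) and through-thickness
# layer counts / targets per resolution level
_LATERAL = {"coarse": (5e-3, 15e-3), "standard": (2.5e-3, 10e-3), "fine": (2.0e-3, 8e-3)}
_SKIN_LAYERS = {"coarse": 2, "standard": 3, "fine": 4}
_GEL_LAYERS = {"coarse": 1, "standard": 1, "fine": 1}
_Z_SCALE = {"coarse": 1.0, "standard": 0.7, "fine": 0.6}


@dataclass
class ContactPatch:
    """Tissue nodes coupled to one ideal conductor through a contact impedance."""

    name: str
    nodes: np.ndarray  # flat node indices
    areas: np.ndarray  # m^2 per node, rescaled to the exact analytic area
    n_facets: int
    area_correction: float  # exact area / staircase area


@dataclass
class PlaneSplit:
    """Impermeable-disc bookkeeping: nodes duplicated across a z-plane.

    A metallic collector disc blocks through-plane conduction.  Interior
    footprint nodes on the disc plane are duplicated; cells below the plane
    reference the duplicates, so tissue above and below communicates only
    through the conductor (via the contact impedance on both faces).
    """

    plane_k: int
    original: np.ndarray  # grid node ids on the plane (interior footprint)
    duplicate: np.ndarray  # appended node ids used by the cells below


@dataclass
class VolumeMesh:
    """Rectilinear hexahedral mesh with per-cell materials and boundary tags."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    material_id: np.ndarray  # (nex, ney, nez) int; -1 = void (no element)
    material_names: list[str]
    resolution: str
    electrode_nodes: list[np.ndarray] = field(default_factory=list)
    collector_patches: list[ContactPatch] = field(default_factory=list)
    cuff_patches: list[ContactPatch] = field(default_factory=list)
    ground_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    plane_splits: list[PlaneSplit] = field(default_factory=list)

    @property
    def shape_nodes(self) -> tuple[int, int, int]:
        return (len(self.x), len(self.y), len(self.z))

    @property
    def n_grid_nodes(self) -> int:
        return len(self.x) * len(self.y) * len(self.z)

    @property
    def n_nodes(self) -> int:
        return self.n_grid_nodes + sum(len(s.duplicate) for s in self.plane_splits)

    def node_index(self, i, j, k):
        ny1, nz1 = len(self.y), len(self.z)
        return (np.asarray(i) * ny1 + np.asarray(j)) * nz1 + np.asarray(k)

    def node_coords(self) -> np.ndarray:
        X, Y, Z = np.meshgrid(self.x, self.y, self.z, indexing="ij")
        coords = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
        for s in self.plane_splits:
            coords = np.vstack([coords, coords[s.original]])
        return coords

    def cells(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Existing cells: (connectivity (N,8), material ids (N,), sizes (N,3)).

        Local node ordering follows the trilinear reference cube
        (i,j,k), (i+1,j,k), (i,j+1,k), (i+1,j+1,k), then the k+1 plane.
        """
        nex, ney, nez = self.material_id.shape
        ii, jj, kk = np.nonzero(self.material_id >= 0)
        mats = self.material_id[ii, jj, kk]
        conn = np.empty((len(ii), 8), dtype=np.int64)
        c = 0
        for dk in (0, 1):
            for dj in (0, 1):
                for di in (0, 1):
                    conn[:, c] = self.node_index(ii + di, jj + dj, kk + dk)
                    c += 1
        # impermeable discs: cells just below a split plane use the duplicates
        for s in self.plane_splits:
            remap = {o: d for o, d in zip(s.original, s.duplicate)}
            below = np.nonzero(kk == s.plane_k)[0]
            for row in below:
                for c in range(4):  # dk = 0 corners lie on the plane
                    conn[row, c] = remap.get(conn[row, c], conn[row, c])
        sizes = np.column_stack(
            [np.diff(self.x)[ii], np.diff(self.y)[jj], np.diff(self.z)[kk]]
        )
        return conn, mats, sizes


def _subdivide(breaks: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Subdivide each interval [breaks[i], breaks[i+1]] at its target size."""
    pts = [breaks[0]]
    for a, b, t in zip(breaks[:-1], breaks[1:], targets):
        n = max(1, int(np.ceil((b - a) / t - 1e-9)))
        pts.extend(np.linspace(a, b, n + 1)[1:])
    return np.asarray(pts)


def _merge_breaks(lo: float, hi: float, candidates) -> np.ndarray:
    vals = sorted({lo, hi, *(c for c in candidates if lo < c < hi)})
    out = [vals[0]]
    for v in vals[1:]:
        if v - out[-1] > 1e-7:
            out.append(v)
        else:
            out[-1] = v if v in (lo, hi) else out[-1]
    return np.asarray(out)


def _lateral_planes(lo, hi, feature_spans, fine, coarse) -> np.ndarray:
    """1D graded planes: fine inside feature spans (+1 cm halo), coarse outside."""
    margin = 0.01
    cand = []
    for a, b, t in feature_spans:
        cand.extend([a, b])
    halo = [(max(lo, a - margin), min(hi, b + margin)) for a, b, _ in feature_spans]
    cand.extend([c for ab in halo for c in ab])
    breaks = _merge_breaks(lo, hi, cand)
    targets = []
    for a, b in zip(breaks[:-1], breaks[1:]):
        mid = 0.5 * (a + b)
        t = coarse
        for (fa, fb) in halo:
            if fa - 1e-9 <= mid <= fb + 1e-9:
                t = min(t, fine)
        for fa, fb, ft in feature_spans:
            if fa - 1e-9 <= mid <= fb + 1e-9:
                t = min(t, ft)
        targets.append(t)
    return _subdivide(breaks, np.asarray(targets))


def generate_mesh(
    config: ModelConfiguration, resolution: Resolution = "standard"
) -> VolumeMesh:
    """Generate the graded hexahedral mesh for `config`.

    Raises ``ValueError`` naming the feature when the geometry is too small to
    resolve it (e.g. a collector disc that captures no boundary facet).
    """
    g = config.geometry
    fine, coarse = _LATERAL[resolution]
    zscale = _Z_SCALE[resolution]

    # ---- lateral planes -------------------------------------------------
    spans_x, spans_y = [], []
    for e in config.electrodes:
        x0, x1, y0, y1 = e.bounds()
        spans_x.append((x0, x1, fine))
        spans_y.append((y0, y1, fine))
    for c in config.collectors:
        r = c.diameter / 2.0
        cx, cy = c.center_xy
        # resolve small discs with >= ~5 cells across the diameter
        t = min(fine, c.diameter / 5.0)
        spans_x.append((cx - r, cx + r, t))
        spans_y.append((cy - r, cy + r, t))
    if config.nerve is not None:
        r = config.nerve.diameter / 2.0
        cy = g.domain_width / 2.0
        tn = config.nerve.diameter / 4.0
        spans_y.append((cy - 2 * r, cy + 2 * r, min(fine, tn)))
        # resolve the cuff windows (sharp field gradients at the cuff edges)
        half = config.nerve.cuff_length / 2.0
        for c in config.collectors:
            cx = c.center_xy[0]
            spans_x.append((cx - half - 3e-3, cx + half + 3e-3,
                            min(fine, config.nerve.cuff_length / 4.0)))
    # keep the inter-patch gap resolved even for tiny separations
    if len(config.electrodes) == 2:
        (a0, a1, _, _), (b0, b1, _, _) = (e.bounds() for e in config.electrodes)
        gap = (min(a1, b1), max(a0, b0))
        if gap[1] > gap[0]:
            spans_x.append((gap[0], gap[1], min(fine, max((gap[1] - gap[0]) / 2, 2e-4))))
    xs = _lateral_planes(0.0, g.domain_length, spans_x, fine, coarse)
    ys = _lateral_planes(0.0, g.domain_width, spans_y, fine, coarse)

    # ---- z planes -------------------------------------------------------
    gel_t = max(e.hydrogel_thickness for e in config.electrodes)
    skin_target = g.skin_thickness / _SKIN_LAYERS[resolution]
    collector_depths = [c.depth_below_surface for c in config.collectors]
    zbreaks = [-gel_t, 0.0, g.fat_top, g.muscle_top, g.total_thickness]
    zcand = list(collector_depths)
    nerve_planes = []
    if config.nerve is not None:
        zc = config.nerve.depth_below_surface
        r = config.nerve.diameter / 2.0
        nerve_planes = [zc - r, zc + r]
        zcand.extend(nerve_planes)
    zb = _merge_breaks(-gel_t, g.total_thickness, zbreaks[1:-1] + zcand)

    def ztarget(zmid: float) -> float:
        if zmid < 0:
            return gel_t / _GEL_LAYERS[resolution]
        if zmid < g.fat_top:
            return skin_target
        if zmid < g.muscle_top:
            return 1.25e-3 * zscale
        if nerve_planes and nerve_planes[0] - 3e-3 < zmid < nerve_planes[1] + 3e-3:
            if nerve_planes[0] < zmid < nerve_planes[1]:
                return min(1.5e-3, (nerve_planes[1] - nerve_planes[0]) / 4.0) * min(zscale * 2, 1.0)
            return 1.5e-3 * zscale
        if zmid < g.muscle_top + 8e-3:
            return 2.5e-3 * zscale
        return 8e-3 * zscale

    ztargets = np.array([ztarget(0.5 * (a + b)) for a, b in zip(zb[:-1], zb[1:])])
    zs = _subdivide(zb, ztargets)

    # ---- cell materials -------------------------------------------------
    mat_names = ["skin", "fat", "muscle", "hydrogel", "epineurium"]
    mat_idx = {n: i for i, n in enumerate(mat_names)}
    xc = 0.5 * (xs[:-1] + xs[1:])
    yc = 0.5 * (ys[:-1] + ys[1:])
    zc_ = 0.5 * (zs[:-1] + zs[1:])
    mid = np.full((len(xc), len(yc), len(zc_)), -1, dtype=np.int8)
    zlayer = np.full(len(zc_), mat_idx["muscle"], dtype=np.int8)
    zlayer[zc_ < g.muscle_top] = mat_idx["fat"]
    zlayer[zc_ < g.fat_top] = mat_idx["skin"]
    zlayer[zc_ < 0] = -1  # hydrogel assigned only under patches
    mid[:, :, :] = zlayer[None, None, :]
    for e in config.electrodes:
        x0, x1, y0, y1 = e.bounds()
        isel = (xc > x0 - 1e-9) & (xc < x1 + 1e-9)
        jsel = (yc > y0 - 1e-9) & (yc < y1 + 1e-9)
        ksel = zc_ < 0
        mid[np.ix_(isel, jsel, ksel)] = mat_idx["hydrogel"]
    if config.nerve is not None:
        zn = config.nerve.depth_below_surface
        r = config.nerve.diameter / 2.0
        cyn = g.domain_width / 2.0
        inside = (yc[None, :, None] - cyn) ** 2 + (zc_[None, None, :] - zn) ** 2 <= r**2
        nerve_mask = np.broadcast_to(inside, mid.shape) & (mid == mat_idx["muscle"])
        if not nerve_mask.any():
            raise ValueError("geometry too small to resolve feature: nerve cylinder")
        mid[nerve_mask] = mat_idx["epineurium"]

    mesh = VolumeMesh(
        x=xs, y=ys, z=zs, material_id=mid, material_names=mat_names,
        resolution=resolution,
    )

    # ---- boundary tags --------------------------------------------------
    for e in config.electrodes:
        x0, x1, y0, y1 = e.bounds()
        ii = np.nonzero((xs > x0 - 1e-9) & (xs < x1 + 1e-9))[0]
        jj = np.nonzero((ys > y0 - 1e-9) & (ys < y1 + 1e-9))[0]
        if len(ii) < 2 or len(jj) < 2:
            raise ValueError(
                "geometry too small to resolve feature: surface electrode footprint"
            )
        I, J = np.meshgrid(ii, jj, indexing="ij")
        mesh.electrode_nodes.append(mesh.node_index(I.ravel(), J.ravel(), 0))

    for n, c in enumerate(config.collectors):
        patch, split = _disc_patch(mesh, c, n)
        mesh.collector_patches.append(patch)
        if split is not None:
            mesh.plane_splits.append(split)

    if config.nerve is not None:
        for n, c in enumerate(config.collectors):
            mesh.cuff_patches.append(_cuff_patch(mesh, config, c, n))

    if config.mode == "monopolar":
        mesh.ground_nodes = _muscle_ground_nodes(mesh, config)
    return mesh


def _disc_patch(mesh: VolumeMesh, collector, n: int) -> ContactPatch:
    xs, ys, zs = mesh.x, mesh.y, mesh.z
    k = int(np.argmin(np.abs(zs - collector.depth_below_surface)))
    if abs(zs[k] - collector.depth_below_surface) > 1e-7:
        raise ValueError(
            f"geometry too small to resolve feature: collector_{n} depth plane"
        )
    cx, cy = collector.center_xy
    r = collector.diameter / 2.0
    xc = 0.5 * (xs[:-1] + xs[1:])
    yc = 0.5 * (ys[:-1] + ys[1:])
    # coverage-weighted staircase: boundary facets contribute the fraction of
    # their area covered by the disc (8x8 midpoint subsampling)
    sub = (np.arange(8) + 0.5) / 8.0
    cover = np.zeros((len(xc), len(yc)))
    for i in range(len(xc)):
        sx = xs[i] + sub * (xs[i + 1] - xs[i])
        if np.min(np.abs(sx - cx)) - (xs[i + 1] - xs[i]) > r:
            continue
        for j in range(len(yc)):
            sy = ys[j] + sub * (ys[j + 1] - ys[j])
            inside = (sx[:, None] - cx) ** 2 + (sy[None, :] - cy) ** 2 <= r**2
            cover[i, j] = inside.mean()
    ii, jj = np.nonzero(cover > 0)
    if len(ii) == 0:
        raise ValueError(f"geometry too small to resolve feature: collector_{n} disc")
    dax = np.diff(xs)[ii]
    day = np.diff(ys)[jj]
    fa = dax * day * cover[ii, jj]
    full_fa = dax * day
    ngrid = mesh.n_grid_nodes
    areas = np.zeros(ngrid)
    full = np.zeros(ngrid)
    for di in (0, 1):
        for dj in (0, 1):
            idx = mesh.node_index(ii + di, jj + dj, k)
            np.add.at(areas, idx, fa / 4.0)
            np.add.at(full, idx, full_fa / 4.0)
    nodes = np.nonzero(areas > 0)[0]
    stair = float(fa.sum())
    exact = np.pi * r**2
    corr = exact / stair

    # impermeable disc: duplicate interior footprint nodes (fully covered)
    interior = nodes[areas[nodes] >= 0.999 * full[nodes]]
    split = None
    base = mesh.n_nodes
    if len(interior):
        split = PlaneSplit(
            plane_k=k, original=interior,
            duplicate=base + np.arange(len(interior)),
        )
    # both disc faces couple to the conductor through the contact impedance;
    # rim (partially covered) nodes stay shared between the two sides
    node_list = list(nodes)
    area_list = [2.0 * areas[i] * corr for i in nodes]
    if split is not None:
        where = {o: q for q, o in enumerate(split.original)}
        for q, i in enumerate(node_list):
            if i in where:
                area_list[q] = areas[i] * corr  # top face only
        node_list.extend(split.duplicate)
        area_list.extend(areas[i] * corr for i in split.original)
    return ContactPatch(
        name=f"collector_{n}", nodes=np.array(node_list, dtype=np.int64),
        areas=np.array(area_list), n_facets=len(ii), area_correction=corr,
    ), split


def _cuff_patch(mesh: VolumeMesh, config, collector, n: int) -> ContactPatch:
    """Contact facets on the staircase nerve surface within the cuff window."""
    g = config.geometry
    nerve = config.nerve
    epi = mesh.material_names.index("epineurium")
    mid = mesh.material_id
    xs, ys, zs = mesh.x, mesh.y, mesh.z
    x0 = collector.center_xy[0] - nerve.cuff_length / 2.0
    x1 = collector.center_xy[0] + nerve.cuff_length / 2.0
    xc = 0.5 * (xs[:-1] + xs[1:])
    isel = np.nonzero((xc >= x0 - 1e-9) & (xc <= x1 + 1e-9))[0]
    if len(isel) == 0:
        raise ValueError(f"geometry too small to resolve feature: cuff_{n} window")
    areas = np.zeros(mesh.n_nodes)
    nfacet = 0
    dy, dz = np.diff(ys), np.diff(zs)
    dx = np.diff(xs)
    for i in isel:
        nerve_cells = np.argwhere(mid[i] == epi)
        for (j, k) in nerve_cells:
            # y-faces
            for jn, jface in ((j - 1, j), (j + 1, j + 1)):
                if jn < 0 or jn >= mid.shape[1] or mid[i, jn, k] != epi:
                    a = dx[i] * dz[k]
                    for di in (0, 1):
                        for dk in (0, 1):
                            areas[mesh.node_index(i + di, jface, k + dk)] += a / 4
                    nfacet += 1
            # z-faces
            for kn, kface in ((k - 1, k), (k + 1, k + 1)):
                if kn < 0 or kn >= mid.shape[2] or mid[i, j, kn] != epi:
                    a = dx[i] * dy[j]
                    for di in (0, 1):
                        for dj in (0, 1):
                            areas[mesh.node_index(i + di, j + dj, kface)] += a / 4
                    nfacet += 1
    nodes = np.nonzero(areas > 0)[0]
    if len(nodes) == 0:
        raise ValueError(f"geometry too small to resolve feature: cuff_{n} surface")
    stair = float(areas.sum())
    exact = np.pi * nerve.diameter * (xs[isel[-1] + 1] - xs[isel[0]])
    corr = exact / stair
    return ContactPatch(
        name=f"cuff_{n}", nodes=nodes, areas=areas[nodes] * corr,
        n_facets=nfacet, area_correction=corr,
    )


def _muscle_ground_nodes(mesh: VolumeMesh, config) -> np.ndarray:
    g = config.geometry
    xs, ys, zs = mesh.x, mesh.y, mesh.z
    ksel = np.nonzero(zs >= g.muscle_top - 1e-9)[0]
    nodes = []
    I, J = np.meshgrid(np.arange(len(xs)), np.arange(len(ys)), indexing="ij")
    # bottom face
    nodes.append(mesh.node_index(I.ravel(), J.ravel(), len(zs) - 1))
    # four lateral faces of the muscle layer
    for k in ksel:
        nodes.append(mesh.node_index(np.zeros(len(ys), int), np.arange(len(ys)), k))
        nodes.append(
            mesh.node_index(np.full(len(ys), len(xs) - 1), np.arange(len(ys)), k)
        )
        nodes.append(mesh.node_index(np.arange(len(xs)), np.zeros(len(xs), int), k))
        nodes.append(
            mesh.node_index(np.arange(len(xs)), np.full(len(xs), len(ys) - 1), k)
        )
    return np.unique(np.concatenate(nodes))
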