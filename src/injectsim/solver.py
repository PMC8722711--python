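"""Electroquasistatic finite-element solver with lumped circuit coupling.

Solves div(sigma* grad V) = 0 with sigma* = sigma + j*omega*eps0*eps_r on the
structured hexahedral mesh, subject to:

* zero normal current on untagged exterior surfaces (natural BC),
* Dirichlet ground on the five outer muscle surfaces in monopolar mode,
* equipotential surface patches (driven in current or voltage mode),
* ideal conductors (collector discs, leads, nerve cuffs) represented as
  floating equipotential degrees of freedom coupled to coincident tissue
  nodes through the contact impedance (surface current density = dV / Zc),
* a two-terminal lumped load stamped directly between conductor DOFs.

Conduction and displacement stiffness matrices are assembled once; the
complex system at any frequency is K_cond + j*omega*K_eps, so DC, harmonic,
and backward-Euler transient studies all share one assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import ModelConfiguration
from .materials import EPS0, TissueMaterial
from .mesh import VolumeMesh


def _reference_matrices() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unit-cube integrals of dNa/dxi * dNb/dxi etc. for trilinear hexes.

    Local node ordering: x fastest, then y, then z (matches VolumeMesh.cells).
    Evaluated with 2-point Gauss quadrature, which is exact here.
    """
    gp = np.array([0.5 - 0.5 / np.sqrt(3), 0.5 + 0.5 / np.sqrt(3)])
    Kx = np.zeros((8, 8))
    Ky = np.zeros((8, 8))
    Kz = np.zeros((8, 8))
    corners = [(di, dj, dk) for dk in (0, 1) for dj in (0, 1) for di in (0, 1)]

    def shape(c, u):
        return u if c else 1.0 - u

    def dshape(c):
        return 1.0 if c else -1.0

    for xi in gp:
        for eta in gp:
            for zeta in gp:
                dN = np.empty((8, 3))
                for a, (di, dj, dk) in enumerate(corners):
                    dN[a, 0] = dshape(di) * shape(dj, eta) * shape(dk, zeta)
                    dN[a, 1] = shape(di, xi) * dshape(dj) * shape(dk, zeta)
                    dN[a, 2] = shape(di, xi) * shape(dj, eta) * dshape(dk)
                w = 1.0 / 8.0
                Kx += w * np.outer(dN[:, 0], dN[:, 0])
                Ky += w * np.outer(dN[:, 1], dN[:, 1])
                Kz += w * np.outer(dN[:, 2], dN[:, 2])
    return Kx, Ky, Kz


_KX, _KY, _KZ = _reference_matrices()


@dataclass(frozen=True)
class DriveSpec:
    """Stimulus drive: enforced net current or inter-electrode voltage."""

    mode: Literal["current", "voltage"]
    amplitude: float  # A (current mode) or V (voltage mode)
    frequency: float = 0.0
    configuration: Literal["bipolar", "monopolar"] = "bipolar"

    def __post_init__(self) -> None:
        if not np.isfinite(self.amplitude):
            raise ValueError("drive amplitude must be finite")


class AssembledSystem:
    """Sparse conduction/displacement matrices over the reduced DOF set."""

    def __init__(self, mesh: VolumeMesh, config: ModelConfiguration,
                 frequency: float = 0.0):
        self.mesh = mesh
        self.config = config
        self.frequency = frequency
        conn, mats, sizes = mesh.cells()
        sigma = np.empty(len(mesh.material_names))
        eps = np.empty(len(mesh.material_names))
        for i, name in enumerate(mesh.material_names):
            mat = config.materials.get(name)
            if mat is None:
                mat = _default_material(config, name)
            sigma[i] = mat.conductivity
            eps[i] = EPS0 * mat.relative_permittivity
        dx, dy, dz = sizes.T
        a = dy * dz / dx
        b = dx * dz / dy
        c = dx * dy / dz
        geom = (a[:, None, None] * _KX + b[:, None, None] * _KY
                + c[:, None, None] * _KZ)

        # ---- DOF map: active nodes, electrode equipotential groups -------
        n_nodes = mesh.n_nodes
        active = np.zeros(n_nodes, dtype=bool)
        active[conn.ravel()] = True
        dof_of_node = np.full(n_nodes, -1, dtype=np.int64)
        self.electrode_dofs = list(range(len(mesh.electrode_nodes)))
        for d, nodes in enumerate(mesh.electrode_nodes):
            dof_of_node[nodes] = d
        free = active & (dof_of_node < 0)
        n_elec = len(mesh.electrode_nodes)
        dof_of_node[free] = n_elec + np.arange(int(free.sum()))
        ndof = n_elec + int(free.sum())
        # one floating DOF per conductor (collector + lead + cuff merged)
        self.conductor_dofs = [ndof + i for i in range(len(mesh.collector_patches))]
        ndof += len(mesh.collector_patches)
        self.ndof = ndof
        self.dof_of_node = dof_of_node

        econn = dof_of_node[conn]
        rows = np.repeat(econn, 8, axis=1).ravel()
        cols = np.tile(econn, (1, 8)).ravel()
        kc = (sigma[mats][:, None, None] * geom).ravel()
        ke = (eps[mats][:, None, None] * geom).ravel()
        self.K_cond = sp.coo_matrix((kc, (rows, cols)), shape=(ndof, ndof)).tocsr()
        self.K_eps = sp.coo_matrix((ke, (rows, cols)), shape=(ndof, ndof)).tocsr()

        # ---- contact-impedance stamps (purely resistive) -----------------
        stamps_r, stamps_c, stamps_v = [], [], []

        def stamp(d1, d2, g):
            stamps_r.extend([d1, d2, d1, d2])
            stamps_c.extend([d1, d2, d2, d1])
            stamps_v.extend([g, g, -g, -g])

        patches = list(zip(mesh.collector_patches, config.collectors))
        for n, (patch, coll) in enumerate(patches):
            cdof = self.conductor_dofs[n]
            for node, area in zip(patch.nodes, patch.areas):
                stamp(cdof, dof_of_node[node], area / coll.contact_impedance)
        for n, patch in enumerate(mesh.cuff_patches):
            cdof = self.conductor_dofs[n]
            zc = config.collectors[n].contact_impedance
            for node, area in zip(patch.nodes, patch.areas):
                stamp(cdof, dof_of_node[node], area / zc)

        # ---- lumped load -------------------------------------------------
        self.load = config.load
        if config.load is not None:
            gload = 1.0 / config.load.resistance
            t0, t1 = config.load.terminals
            d0 = self._terminal_dof(t0)
            if t1 == "ground":
                stamps_r.append(d0)
                stamps_c.append(d0)
                stamps_v.append(gload)
            else:
                stamp(d0, self._terminal_dof(t1), gload)
        if stamps_v:
            self.K_cond = (self.K_cond + sp.coo_matrix(
                (stamps_v, (stamps_r, stamps_c)), shape=(ndof, ndof))).tocsr()

        self.ground_dofs = np.unique(
            dof_of_node[mesh.ground_nodes[active[mesh.ground_nodes]]]
        ) if len(mesh.ground_nodes) else np.empty(0, dtype=np.int64)

    def _terminal_dof(self, name: str) -> int:
        if name.startswith("collector_"):
            return self.conductor_dofs[int(name.split("_")[1])]
        raise ValueError(f"unknown load terminal {name!r}")

    def matrix(self, frequency: Optional[float] = None) -> sp.csr_matrix:
        """System matrix at `frequency` (Hz); exactly real at DC."""
        f = self.frequency if frequency is None else frequency
        if f == 0:
            return self.K_cond
        return (self.K_cond + 1j * 2.0 * np.pi * f * self.K_eps).tocsr()


def _default_material(config: ModelConfiguration, name: str) -> TissueMaterial:
    if name == "hydrogel":
        return config.electrodes[0].hydrogel_material
    if name == "epineurium" and config.nerve is not None:
        return config.nerve.material
    from .materials import MATERIAL_LIBRARY

    return MATERIAL_LIBRARY[name]


def assemble(mesh: VolumeMesh, config: ModelConfiguration,
             frequency: float = 0.0) -> AssembledSystem:
    """Assemble the sparse electroquasistatic system for `config` on `mesh`."""
    return AssembledSystem(mesh, config, frequency)


@dataclass
class FieldSolution:
    """Nodal potential field at one frequency with drive bookkeeping."""

    potentials: np.ndarray  # per mesh node; NaN on void nodes
    frequency: float
    drive: DriveSpec
    collector_potentials: list
    load_current: complex
    i_tes: complex
    v_tes: complex
    system: AssembledSystem

    def scaled(self, factor: float) -> "FieldSolution":
        return FieldSolution(
            potentials=self.potentials * factor,
            frequency=self.frequency,
            drive=self.drive,
            collector_potentials=[v * factor for v in self.collector_potentials],
            load_current=self.load_current * factor,
            i_tes=self.i_tes * factor,
            v_tes=self.v_tes * factor,
            system=self.system,
        )


@dataclass(frozen=True)
class CouplingMetrics:
    """Coupling summary of one solve; all magnitudes are absolute values."""

    v_tes: float  # V
    i_tes: float  # mA
    i_nerve: float  # mA
    efficiency: float  # % = 100*|I_Nerve|/|I_TES|
    efficiency_defined: bool = True


def solve(system: AssembledSystem, drive: DriveSpec) -> FieldSolution:
    """Direct sparse solve of the assembled system under `drive`."""
    f = drive.frequency
    K = system.matrix(f)
    ndof = system.ndof
    rhs = np.zeros(ndof, dtype=complex if f != 0 else float)

    fixed = {}
    src = system.electrode_dofs[0]
    ret = system.electrode_dofs[1] if len(system.electrode_dofs) > 1 else None
    if drive.mode == "current":
        rhs[src] = drive.amplitude
        if ret is not None:
            fixed[ret] = 0.0
    else:
        fixed[src] = drive.amplitude
        if ret is not None:
            fixed[ret] = 0.0
    for d in system.ground_dofs:
        fixed[int(d)] = 0.0
    if not fixed:
        raise ValueError(
            "singular system: no reference potential; fix a gauge by grounding "
            "the return electrode or muscle surfaces"
        )

    fixed_idx = np.array(sorted(fixed), dtype=np.int64)
    fixed_val = np.array([fixed[i] for i in fixed_idx])
    free_mask = np.ones(ndof, dtype=bool)
    free_mask[fixed_idx] = False
    free_idx = np.nonzero(free_mask)[0]

    Kff = K[free_idx][:, free_idx].tocsc()
    Kfd = K[free_idx][:, fixed_idx]
    b = rhs[free_idx] - Kfd @ fixed_val
    if drive.amplitude == 0:
        x = np.zeros(len(free_idx), dtype=b.dtype)
    else:
        lu = spla.splu(Kff)
        x = lu.solve(b)
        if not np.all(np.isfinite(x)):
            resid = np.linalg.norm(Kff @ x - b)
            raise RuntimeError(f"solver failed to converge; residual {resid:g}")

    v = np.zeros(ndof, dtype=b.dtype)
    v[free_idx] = x
    v[fixed_idx] = fixed_val

    coll_v = [v[d] for d in system.conductor_dofs]
    load_current = _load_current(system, v)
    if drive.mode == "current":
        i_tes = complex(drive.amplitude)
    else:
        i_tes = (K.getrow(src) @ v)[0]  # reaction current at the driven patch
    v_tes = v[src] - (v[ret] if ret is not None else 0.0)

    pot = np.full(system.mesh.n_nodes, np.nan, dtype=v.dtype)
    has_dof = system.dof_of_node >= 0
    pot[has_dof] = v[system.dof_of_node[has_dof]]

    sol = FieldSolution(
        potentials=pot, frequency=f, drive=drive,
        collector_potentials=coll_v, load_current=load_current,
        i_tes=i_tes, v_tes=v_tes, system=system,
    )
    sol._dof_values = v  # internal: reused by flux computations
    return sol


def _load_current(system: AssembledSystem, v: np.ndarray):
    cfg = system.config
    if cfg.load is not None:
        t0, t1 = cfg.load.terminals
        v0 = v[system._terminal_dof(t0)]
        v1 = 0.0 if t1 == "ground" else v[system._terminal_dof(t1)]
        return (v0 - v1) / cfg.load.resistance
    if system.mesh.cuff_patches:
        # full variant: current delivered through the first cuff into the nerve
        patch = system.mesh.cuff_patches[0]
        zc = cfg.collectors[0].contact_impedance
        cdof = system.conductor_dofs[0]
        dofs = system.dof_of_node[patch.nodes]
        return np.sum((v[cdof] - v[dofs]) * patch.areas / zc)
    return 0.0


def compute_metrics(solution: FieldSolution) -> CouplingMetrics:
    """Capture-ratio metrics; deterministic function of the solution."""
    i_tes = abs(solution.i_tes)
    i_nerve = abs(solution.load_current)
    if i_tes == 0:
        return CouplingMetrics(
            v_tes=abs(solution.v_tes), i_tes=0.0, i_nerve=i_nerve * 1e3,
            efficiency=0.0, efficiency_defined=False,
        )
    return CouplingMetrics(
        v_tes=abs(solution.v_tes),
        i_tes=i_tes * 1e3,
        i_nerve=i_nerve * 1e3,
        efficiency=100.0 * i_nerve / i_tes,
    )


def surface_current_density(solution: FieldSolution, electrode_index: int = 0):
    """Per-facet normal current density (A/m^2) under one surface patch.

    Uses element-consistent nodal fluxes from the hydrogel cells touching the
    patch metal, so the facet currents sum exactly to the current injected at
    that electrode.  Returns (centers (N,2), densities (N,), areas (N,)).
    """
    system = solution.system
    mesh = system.mesh
    config = system.config
    if electrode_index >= len(config.electrodes):
        raise ValueError(f"electrode {electrode_index} not in configuration")
    e = config.electrodes[electrode_index]
    x0, x1, y0, y1 = e.bounds()
    gel_id = mesh.material_names.index("hydrogel")
    xc = 0.5 * (mesh.x[:-1] + mesh.x[1:])
    yc = 0.5 * (mesh.y[:-1] + mesh.y[1:])
    ii, jj, kk = np.nonzero(mesh.material_id == gel_id)
    top = kk == 0
    sel = top & (xc[ii] > x0 - 1e-9) & (xc[ii] < x1 + 1e-9) \
        & (yc[jj] > y0 - 1e-9) & (yc[jj] < y1 + 1e-9)
    ii, jj, kk = ii[sel], jj[sel], kk[sel]
    sig = config.electrodes[electrode_index].hydrogel_material.admittivity(
        solution.frequency
    )
    dxs, dys, dzs = np.diff(mesh.x), np.diff(mesh.y), np.diff(mesh.z)
    v = solution.potentials
    centers = np.column_stack([xc[ii], yc[jj]])
    areas = dxs[ii] * dys[jj]
    dens = np.empty(len(ii), dtype=v.dtype)
    for n, (i, j, k) in enumerate(zip(ii, jj, kk)):
        conn = mesh.node_index(
            np.array([i, i + 1, i, i + 1, i, i + 1, i, i + 1]),
            np.array([j, j, j + 1, j + 1, j, j, j + 1, j + 1]),
            np.array([k, k, k, k, k + 1, k + 1, k + 1, k + 1]),
        )
        dx, dy, dz = dxs[i], dys[j], dzs[k]
        Ke = sig * (dy * dz / dx * _KX + dx * dz / dy * _KY + dx * dy / dz * _KZ)
        flux = Ke @ v[conn]
        dens[n] = flux[:4].sum() / areas[n]  # top-face nodal fluxes
    return centers, dens, areas


def boundary_current_imbalance(solution: FieldSolution) -> float:
    """|sum of drive-terminal currents| relative to |I_TES| (conservation)."""
    system = solution.system
    K = system.matrix(solution.frequency)
    v = solution._dof_values
    r = K @ v
    # residual at non-driven free DOFs should vanish; net injected current
    # over all Dirichlet/driven DOFs must cancel
    drive_dofs = list(system.electrode_dofs) + list(map(int, system.ground_dofs))
    net = sum(r[d] for d in drive_dofs)
    return float(abs(net) / max(abs(solution.i_tes), 1e-300))


# ---------------------------------------------------------------------------
# transient (backward Euler) study
# ---------------------------------------------------------------------------

def transient_response(config: ModelConfiguration, mesh: VolumeMesh, waveform,
                       dt: Optional[float] = None, t_end: Optional[float] = None):
    """Backward-Euler time stepping of the full field problem.

    `waveform` is a ``Waveform`` (voltage or current mode).  One sparse
    factorization is reused for every step.  Returns a ``TimeTraceSet``.
    """
    from .waveforms import TimeTraceSet

    system = assemble(mesh, config)
    Kc = system.K_cond
    Ke = system.K_eps
    ndof = system.ndof
    dt = waveform.sample_interval if dt is None else dt
    t_end = waveform.duration if t_end is None else t_end
    times = np.arange(0.0, t_end + 0.5 * dt, dt)
    drive = waveform.sample(times)

    src = system.electrode_dofs[0]
    ret = system.electrode_dofs[1] if len(system.electrode_dofs) > 1 else None
    fixed_idx = []
    if waveform.mode == "voltage":
        fixed_idx.append(src)
    if ret is not None:
        fixed_idx.append(ret)
    fixed_idx.extend(map(int, system.ground_dofs))
    fixed_idx = np.unique(np.array(fixed_idx, dtype=np.int64))
    free_mask = np.ones(ndof, dtype=bool)
    free_mask[fixed_idx] = False
    free_idx = np.nonzero(free_mask)[0]

    A = (Kc + Ke / dt)
    lu = spla.splu(A[free_idx][:, free_idx].tocsc())
    Kc_fd = Kc[free_idx][:, fixed_idx]
    Ke_fd = Ke[free_idx][:, fixed_idx]
    Ke_ff = Ke[free_idx][:, free_idx]

    v = np.zeros(ndof)
    vd_prev = np.zeros(len(fixed_idx))
    t0, t1 = (config.load.terminals if config.load is not None else (None, None))
    i_nerve = np.zeros(len(times))
    i_tes = np.zeros(len(times))
    v_tes = np.zeros(len(times))
    for n, (t, d) in enumerate(zip(times, drive)):
        vd = np.zeros(len(fixed_idx))
        rhs_free = Ke_ff @ (v[free_idx] / dt)
        if waveform.mode == "voltage":
            vd[fixed_idx == src] = d
        else:
            rhs_free = rhs_free.copy()
            rhs_free[free_idx == src] += d
        b = rhs_free - Kc_fd @ vd - Ke_fd @ ((vd - vd_prev) / dt)
        v_prev = v.copy()
        v[free_idx] = lu.solve(b)
        v[fixed_idx] = vd
        vd_prev = vd
        if config.load is not None:
            v0 = v[system._terminal_dof(t0)]
            v1 = 0.0 if t1 == "ground" else v[system._terminal_dof(t1)]
            i_nerve[n] = (v0 - v1) / config.load.resistance
        if waveform.mode == "voltage":
            i_tes[n] = (Kc.getrow(src) @ v)[0] + (Ke.getrow(src) @ (v - v_prev))[0] / dt
            v_tes[n] = d
        else:
            i_tes[n] = d
            v_tes[n] = v[src] - (v[ret] if ret is not None else 0.0)
    return TimeTraceSet(
        time=times, v_tes=v_tes, i_tes=i_tes * 1e3, i_nerve=i_nerve * 1e3
    )


def displacement_charge_fraction(
    config: ModelConfiguration, waveform, resolution: str = "coarse",
) -> float:
    """Percent of rectified nerve charge retained when skin conducts nothing.

    Runs the transient pipeline twice -- with the configured skin conductivity
    and with skin sigma = 0 S/m (permittivity unchanged) -- and returns
    100 * q(sigma_skin=0) / q(normal), q = integral of |I_Nerve| dt.
    """
    from .mesh import generate_mesh

    skin = config.materials["skin"]
    cfg0 = config.with_materials(skin=skin.with_conductivity(0.0))
    mesh = generate_mesh(config, resolution)
    tr_n = transient_response(config, mesh, waveform)
    tr_0 = transient_response(cfg0, generate_mesh(cfg0, resolution), waveform)
    qn = np.trapezoid(np.abs(tr_n.i_nerve), tr_n.time)
    q0 = np.trapezoid(np.abs(tr_0.i_nerve), tr_0.time)
    if qn == 0:
        return 0.0
    return 100.0 * q0 / qn
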