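"""Double-cable myelinated axon model (MRG parametrization) and integrator.

Morphologies follow the McIntyre-Richardson-Grill construction: explicit
nodes of Ranvier, paranodal myelin attachment (MYSA), juxtaparanodal (FLUT),
and six equal internodal (STIN) compartments per internode, with a periaxonal
conduction space under the myelin.  Nodal membrane dynamics use the MRG
channel set (fast Na+, persistent Na+, slow K+, leak); the channel parameter
set is pluggable.

Geometric parameters are tabulated for the published fiber diameters and
log-log extrapolated below the published range (the 2.0 um Adelta fiber);
:func:`mrg_extrapolation_table` emits the extrapolated values for audit.

The integrator advances intracellular and periaxonal potentials implicitly
(backward Euler, default time step 5 us) with gating variables updated by the
standard linearized implicit rule.  The linear solve is an exact block
elimination over the compartment tree (2x2 blocks: intracellular and
periaxonal potential per compartment), vectorized across a batch of fibers
that share one morphology -- threshold searches for whole fiber populations
run in lockstep.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

# ---------------------------------------------------------------------------
# MRG geometric parametrization
# ---------------------------------------------------------------------------

# fiber diameter -> (axon_d, node_d, para1_d, para2_d, deltax, flut_len, n_lamella)
MRG_TABLE: dict[float, tuple[float, float, float, float, float, float, int]] = {
    5.7: (3.4, 1.9, 1.9, 3.4, 500.0, 35.0, 80),
    7.3: (4.6, 2.4, 2.4, 4.6, 750.0, 38.0, 100),
    8.7: (5.8, 2.8, 2.8, 5.8, 1000.0, 40.0, 110),
    10.0: (6.9, 3.3, 3.3, 6.9, 1150.0, 46.0, 120),
    11.5: (8.1, 3.7, 3.7, 8.1, 1250.0, 50.0, 130),
    12.8: (9.2, 4.2, 4.2, 9.2, 1350.0, 54.0, 135),
    14.0: (10.4, 4.7, 4.7, 10.4, 1400.0, 56.0, 140),
    15.0: (11.5, 5.0, 5.0, 11.5, 1450.0, 58.0, 145),
    16.0: (12.7, 5.5, 5.5, 12.7, 1500.0, 60.0, 150),
}

NODE_LENGTH_UM = 1.0
MYSA_LENGTH_UM = 3.0
RHO_AXIAL_OHM_UM = 0.7e6  # axoplasmic and periaxonal resistivity
MYELIN_CM_PER_LAMELLA = 0.1  # uF/cm^2 per lamella membrane
MYELIN_GM_PER_LAMELLA = 0.001  # S/cm^2 per lamella membrane
SPACE_NODE_UM = 0.002
SPACE_MYSA_UM = 0.002
SPACE_FLUT_UM = 0.004
SPACE_STIN_UM = 0.004

KIND_NODE, KIND_MYSA, KIND_FLUT, KIND_STIN, KIND_PASSIVE_NODE, KIND_BRANCH = range(6)

_PINNED_MYELIN_MS = 1.0e8  # "no myelin": periaxonal potential pinned to Ve


@dataclass(frozen=True)
class MRGGeometry:
    fiber_diameter: float  # um
    axon_diameter: float
    node_diameter: float
    para1_diameter: float
    para2_diameter: float
    internode_length: float  # node-to-node spacing (deltax), um
    flut_length: float
    n_lamella: int
    extrapolated: bool = False

    @property
    def stin_length(self) -> float:
        return (self.internode_length - NODE_LENGTH_UM - 2 * MYSA_LENGTH_UM
                - 2 * self.flut_length) / 6.0


def mrg_geometry(fiber_diameter: float, extrapolate: bool = False) -> MRGGeometry:
    """Tabulated MRG geometry, log-log extrapolated off the published grid.

    2.0 um (the Adelta fiber) is always allowed via the documented
    extrapolation rule; any other off-table diameter requires
    ``extrapolate=True``.
    """
    if fiber_diameter in MRG_TABLE:
        return MRGGeometry(fiber_diameter, *MRG_TABLE[fiber_diameter])
    if not (extrapolate or fiber_diameter == 2.0):
        raise ValueError(
            f"fiber diameter {fiber_diameter} um is not in the published set; "
            "pass extrapolate=True to use the log-log rule"
        )
    if not 1.0 <= fiber_diameter <= 16.0:
        raise ValueError("extrapolation limited to 1-16 um fiber diameters")
    d = np.array(sorted(MRG_TABLE))
    logd = np.log(d)
    vals = []
    for col in range(7):
        y = np.array([MRG_TABLE[k][col] for k in sorted(MRG_TABLE)], dtype=float)
        coef = np.polyfit(logd, np.log(y), 1)
        vals.append(float(np.exp(np.polyval(coef, np.log(fiber_diameter)))))
    return MRGGeometry(
        fiber_diameter, vals[0], vals[1], vals[2], vals[3], vals[4], vals[5],
        max(int(round(vals[6])), 2), extrapolated=True,
    )


def mrg_extrapolation_table(diameters=(2.0, 4.0)) -> "object":
    """Audit table of extrapolated geometric parameters (pandas DataFrame)."""
    import pandas as pd

    rows = []
    for d in diameters:
        g = mrg_geometry(d, extrapolate=True)
        rows.append({
            "fiber_diameter_um": d,
            "axon_diameter_um": g.axon_diameter,
            "node_diameter_um": g.node_diameter,
            "para1_diameter_um": g.para1_diameter,
            "para2_diameter_um": g.para2_diameter,
            "internode_length_um": g.internode_length,
            "flut_length_um": g.flut_length,
            "n_lamella": g.n_lamella,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ChannelSet:
    """Nodal membrane parameter set (MRG defaults; pluggable via config).

    Conductances in S/cm^2, potentials in mV, capacitance in uF/cm^2.
    """

    g_naf: float = 3.0
    g_nap: float = 0.01
    g_ks: float = 0.08
    g_leak: float = 0.007
    e_na: float = 50.0
    e_k: float = -90.0
    e_leak: float = -90.0
    cm: float = 2.0
    celsius: float = 37.0
    v_rest: float = -80.0


@dataclass(frozen=True)
class BranchingRecipe:
    """Unmyelinated passive terminal arbor for cutaneous Adelta fibers.

    A symmetric tree: ``levels`` generations, each parent sprouting
    ``branches`` children; every branch is ``compartments_per_branch``
    equal cylinders of ``branch_length_um`` total length.
    """

    levels: int = 2
    branches: int = 2
    branch_length_um: float = 150.0
    compartments_per_branch: int = 3
    diameter_um: float = 1.2

    @property
    def n_compartments(self) -> int:
        total_branches = sum(self.branches ** l for l in range(1, self.levels + 1))
        return total_branches * self.compartments_per_branch


@dataclass
class AxonMorphology:
    """Compartment-resolved axon (index 0 at the terminal/first node)."""

    fiber_diameter: float
    geometry: MRGGeometry
    kind: np.ndarray  # int8 per compartment
    length_um: np.ndarray
    diameter_um: np.ndarray  # axial (axolemma) diameter
    parent: np.ndarray  # parent[i] < i; parent[0] = -1
    arc_um: np.ndarray  # signed midpoint arc coordinate (branch arbor < 0)
    node_indices: np.ndarray
    terminal: str = "none"
    recipe: Optional[BranchingRecipe] = None

    @property
    def n_compartments(self) -> int:
        return len(self.kind)

    @property
    def n_nodes(self) -> int:
        return len(self.node_indices)

    @property
    def length_total_um(self) -> float:
        return float(self.arc_um.max() - max(self.arc_um.min(), 0.0))


def build_axon(fiber_diameter: float, n_nodes: int, terminal: str = "none",
               recipe: Optional[BranchingRecipe] = None,
               extrapolate: bool = False) -> AxonMorphology:
    """Construct an MRG morphology with an optional cutaneous terminal.

    terminal:
      * ``"none"`` -- plain axon, active nodes at both ends.
      * ``"passive_node"`` -- the terminal node (index 0) carries only
        capacitance and leak (cutaneous Abeta ending).
      * ``"branching"`` -- an unmyelinated passive arbor (per `recipe`)
        attached to the terminal node (cutaneous Adelta ending).
    """
    if n_nodes < 2:
        raise ValueError("need at least two nodes of Ranvier")
    if terminal not in ("none", "passive_node", "branching"):
        raise ValueError(f"unknown terminal variant {terminal!r}")
    geo = mrg_geometry(fiber_diameter, extrapolate=extrapolate)

    kinds, lengths, diams, parents = [], [], [], []

    def add(kind, length, diam, parent):
        kinds.append(kind)
        lengths.append(length)
        diams.append(diam)
        parents.append(parent)
        return len(kinds) - 1

    internode = (
        [(KIND_MYSA, MYSA_LENGTH_UM, geo.para1_diameter),
         (KIND_FLUT, geo.flut_length, geo.para2_diameter)]
        + [(KIND_STIN, geo.stin_length, geo.axon_diameter)] * 6
        + [(KIND_FLUT, geo.flut_length, geo.para2_diameter),
           (KIND_MYSA, MYSA_LENGTH_UM, geo.para1_diameter)]
    )
    first_kind = KIND_PASSIVE_NODE if terminal == "passive_node" else KIND_NODE
    prev = add(first_kind, NODE_LENGTH_UM, geo.node_diameter, -1)
    node_idx = [prev]
    for _ in range(n_nodes - 1):
        for kind, length, diam in internode:
            prev = add(kind, length, diam, prev)
        prev = add(KIND_NODE, NODE_LENGTH_UM, geo.node_diameter, prev)
        node_idx.append(prev)

    # signed arc coordinate of compartment midpoints (terminal node at 0)
    arc = np.zeros(len(kinds))
    s = 0.0
    for i, L in enumerate(lengths):
        arc[i] = s + L / 2.0
        s += L

    if terminal == "branching":
        rec = recipe or BranchingRecipe()
        frontier = [(0, 0.0)]  # (attachment compartment, arc depth)
        seg = rec.branch_length_um / rec.compartments_per_branch
        for _ in range(rec.levels):
            new_frontier = []
            for parent_comp, depth in frontier:
                for _b in range(rec.branches):
                    p = parent_comp
                    d0 = depth
                    for _c in range(rec.compartments_per_branch):
                        p = add(KIND_BRANCH, seg, rec.diameter_um, p)
                        d0 += seg
                        arc = np.append(arc, -(d0 - seg / 2.0))
                    new_frontier.append((p, d0))
            frontier = new_frontier
    else:
        rec = None

    return AxonMorphology(
        fiber_diameter=fiber_diameter, geometry=geo,
        kind=np.array(kinds, dtype=np.int8),
        length_um=np.array(lengths), diameter_um=np.array(diams),
        parent=np.array(parents, dtype=np.int64), arc_um=arc,
        node_indices=np.array(node_idx, dtype=np.int64),
        terminal=terminal, recipe=rec,
    )


# ---------------------------------------------------------------------------
# electrical cable construction
# ---------------------------------------------------------------------------

_SPACE_BY_KIND = {
    KIND_NODE: SPACE_NODE_UM, KIND_PASSIVE_NODE: SPACE_NODE_UM,
    KIND_MYSA: SPACE_MYSA_UM, KIND_FLUT: SPACE_FLUT_UM,
    KIND_STIN: SPACE_STIN_UM, KIND_BRANCH: SPACE_NODE_UM,
}
_GPAS_BY_KIND = {
    KIND_MYSA: 0.001, KIND_FLUT: 0.0001, KIND_STIN: 0.0001,
    KIND_BRANCH: 0.0001,
}
_BRANCH_CM = 1.0  # uF/cm^2, unmyelinated terminal arbor


@dataclass
class CableModel:
    """Per-compartment electrical arrays ready for batched integration.

    Units: mV, ms, uF, mS, uA (so G*V -> uA and C*V/ms -> uA).
    """

    morphology: AxonMorphology
    channels: ChannelSet
    g_ax: np.ndarray  # mS to parent (index 0 unused)
    g_pax: np.ndarray  # mS periaxonal to parent
    cm: np.ndarray  # uF axolemma
    g_pas: np.ndarray  # mS passive axolemma
    e_pas: np.ndarray  # mV
    cmy: np.ndarray  # uF myelin
    gmy: np.ndarray  # mS myelin (huge where the sheath is absent)
    node_mask: np.ndarray
    gbar_naf: np.ndarray  # mS at nodes (0 elsewhere)
    gbar_nap: np.ndarray
    gbar_ks: np.ndarray

    @property
    def n_compartments(self) -> int:
        return len(self.cm)


def build_cable(morph: AxonMorphology,
                channels: ChannelSet = ChannelSet()) -> CableModel:
    n = morph.n_compartments
    kind = morph.kind
    L = morph.length_um
    d = morph.diameter_um
    area_um2 = np.pi * d * L
    area_cm2 = area_um2 * 1e-8
    fiber_area_cm2 = np.pi * morph.geometry.fiber_diameter * L * 1e-8

    # axial resistances (ohm) and couplings to parent
    r_half = 0.5 * RHO_AXIAL_OHM_UM * L / (np.pi * (d / 2.0) ** 2)
    space = np.array([_SPACE_BY_KIND[int(k)] for k in kind])
    peri_area = np.pi * ((d / 2.0 + space) ** 2 - (d / 2.0) ** 2)
    rp_half = 0.5 * RHO_AXIAL_OHM_UM * L / peri_area
    g_ax = np.zeros(n)
    g_pax = np.zeros(n)
    for i in range(1, n):
        p = morph.parent[i]
        g_ax[i] = 1e3 / (r_half[i] + r_half[p])
        g_pax[i] = 1e3 / (rp_half[i] + rp_half[p])

    ch = channels
    cm = np.where(kind == KIND_BRANCH, _BRANCH_CM, ch.cm) * area_cm2
    g_pas = np.zeros(n)
    e_pas = np.full(n, ch.v_rest)
    gbar_naf = np.zeros(n)
    gbar_nap = np.zeros(n)
    gbar_ks = np.zeros(n)
    for i in range(n):
        k = int(kind[i])
        if k == KIND_NODE:
            g_pas[i] = ch.g_leak * area_cm2[i] * 1e3
            e_pas[i] = ch.e_leak
            gbar_naf[i] = ch.g_naf * area_cm2[i] * 1e3
            gbar_nap[i] = ch.g_nap * area_cm2[i] * 1e3
            gbar_ks[i] = ch.g_ks * area_cm2[i] * 1e3
        elif k == KIND_PASSIVE_NODE:
            # capacitance + leak only; leak reversal at rest so the ending
            # neither sources nor sinks current at rest
            g_pas[i] = ch.g_leak * area_cm2[i] * 1e3
            e_pas[i] = ch.v_rest
        else:
            g_pas[i] = _GPAS_BY_KIND[k] * area_cm2[i] * 1e3
            e_pas[i] = ch.v_rest

    bare = (kind == KIND_NODE) | (kind == KIND_PASSIVE_NODE) | (kind == KIND_BRANCH)
    gm_per_cm2 = MYELIN_GM_PER_LAMELLA / (2.0 * morph.geometry.n_lamella)
    cm_per_cm2 = MYELIN_CM_PER_LAMELLA / (2.0 * morph.geometry.n_lamella)
    gmy = np.where(bare, _PINNED_MYELIN_MS, gm_per_cm2 * fiber_area_cm2 * 1e3)
    cmy = np.where(bare, 0.0, cm_per_cm2 * fiber_area_cm2)

    return CableModel(
        morphology=morph, channels=ch, g_ax=g_ax, g_pax=g_pax,
        cm=cm, g_pas=g_pas, e_pas=e_pas, cmy=cmy, gmy=gmy,
        node_mask=kind == KIND_NODE,
        gbar_naf=gbar_naf, gbar_nap=gbar_nap, gbar_ks=gbar_ks,
    )


# ---------------------------------------------------------------------------
# nodal gating kinetics (rates at `celsius`; q10 corrections folded in)
# ---------------------------------------------------------------------------

def _vtrap(x, y):
    """x / (1 - exp(-x/y)), continuous through x = 0."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x / y) < 1e-6
    safe = np.where(small, 1.0, x)
    with np.errstate(over="ignore"):
        out = safe / (1.0 - np.exp(-safe / y))
    return np.where(small, y * (1.0 + x / (2.0 * y)), out)


# ---------------------------------------------------------------------------
# block-tridiagonal tree elimination (2x2 blocks), optionally numba-compiled
# ---------------------------------------------------------------------------

def _solve_blocks_py(parent, g_ax, g_pax, d11, d12, d22, b1, b2,
                     i11, i12, i22, x1, x2):
    n = len(parent)
    for i in range(n - 1, 0, -1):
        pi = parent[i]
        det = d11[:, i] * d22[:, i] - d12[:, i] * d12[:, i]
        j11 = d22[:, i] / det
        j12 = -d12[:, i] / det
        j22 = d11[:, i] / det
        i11[:, i] = j11
        i12[:, i] = j12
        i22[:, i] = j22
        ga = g_ax[i]
        gp = g_pax[i]
        d11[:, pi] -= ga * ga * j11
        d12[:, pi] -= ga * gp * j12
        d22[:, pi] -= gp * gp * j22
        b1[:, pi] += ga * (j11 * b1[:, i] + j12 * b2[:, i])
        b2[:, pi] += gp * (j12 * b1[:, i] + j22 * b2[:, i])
    det = d11[:, 0] * d22[:, 0] - d12[:, 0] * d12[:, 0]
    x1[:, 0] = (d22[:, 0] * b1[:, 0] - d12[:, 0] * b2[:, 0]) / det
    x2[:, 0] = (d11[:, 0] * b2[:, 0] - d12[:, 0] * b1[:, 0]) / det
    for i in range(1, n):
        pi = parent[i]
        r1 = b1[:, i] + g_ax[i] * x1[:, pi]
        r2 = b2[:, i] + g_pax[i] * x2[:, pi]
        x1[:, i] = i11[:, i] * r1 + i12[:, i] * r2
        x2[:, i] = i12[:, i] * r1 + i22[:, i] * r2


try:  # pragma: no cover - exercised when numba is installed
    import numba as _nb

    @_nb.njit(cache=False)
    def _solve_blocks_nb(parent, g_ax, g_pax, d11, d12, d22, b1, b2,
                         i11, i12, i22, x1, x2):  # pragma: no cover
        B = d11.shape[0]
        n = len(parent)
        for i in range(n - 1, 0, -1):
            pi = parent[i]
            ga = g_ax[i]
            gp = g_pax[i]
            for b in range(B):
                det = d11[b, i] * d22[b, i] - d12[b, i] * d12[b, i]
                j11 = d22[b, i] / det
                j12 = -d12[b, i] / det
                j22 = d11[b, i] / det
                i11[b, i] = j11
                i12[b, i] = j12
                i22[b, i] = j22
                d11[b, pi] -= ga * ga * j11
                d12[b, pi] -= ga * gp * j12
                d22[b, pi] -= gp * gp * j22
                b1[b, pi] += ga * (j11 * b1[b, i] + j12 * b2[b, i])
                b2[b, pi] += gp * (j12 * b1[b, i] + j22 * b2[b, i])
        for b in range(B):
            det = d11[b, 0] * d22[b, 0] - d12[b, 0] * d12[b, 0]
            x1[b, 0] = (d22[b, 0] * b1[b, 0] - d12[b, 0] * b2[b, 0]) / det
            x2[b, 0] = (d11[b, 0] * b2[b, 0] - d12[b, 0] * b1[b, 0]) / det
        for i in range(1, n):
            pi = parent[i]
            for b in range(B):
                r1 = b1[b, i] + g_ax[i] * x1[b, pi]
                r2 = b2[b, i] + g_pax[i] * x2[b, pi]
                x1[b, i] = i11[b, i] * r1 + i12[b, i] * r2
                x2[b, i] = i12[b, i] * r1 + i22[b, i] * r2

    _solve_blocks = _solve_blocks_nb
except Exception:  # pragma: no cover
    _solve_blocks = _solve_blocks_py


def gating_rates(v, celsius: float = 37.0):
    """MRG nodal rate constants (1/ms) at membrane potential v (mV)."""
    q10_mp = 2.2 ** ((celsius - 20.0) / 10.0)
    q10_h = 2.9 ** ((celsius - 20.0) / 10.0)
    q10_s = 3.0 ** ((celsius - 36.0) / 10.0)
    with np.errstate(over="ignore"):  # logistic tails saturate harmlessly
        am = q10_mp * 6.57 * _vtrap(v + 20.4, 10.3)
        bm = q10_mp * 0.304 * _vtrap(-(v + 25.7), 9.16)
        ah = q10_h * 0.34 * _vtrap(-(v + 114.0), 11.0)
        bh = q10_h * 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
        ap = q10_mp * 0.0353 * _vtrap(v + 27.0, 10.2)
        bp = q10_mp * 0.000883 * _vtrap(-(v + 34.0), 10.0)
        as_ = q10_s * 0.3 / (1.0 + np.exp(-(v + 53.0) / 5.0))
        bs = q10_s * 0.03 / (1.0 + np.exp(-(v + 90.0) / 1.0))
    return (am, bm), (ah, bh), (ap, bp), (as_, bs)


def steady_gates(v, celsius: float = 37.0):
    rates = gating_rates(v, celsius)
    return tuple(a / (a + b) for a, b in rates)


# ---------------------------------------------------------------------------
# extracellular drive and batched backward-Euler integration
# ---------------------------------------------------------------------------

@dataclass
class ExtracellularDrive:
    """Unit-stimulus extracellular potentials at compartment midpoints.

    ``ve_unit`` is in mV per mA of stimulus current (equivalently V/A); the
    time course is a train of square pulses of ``pulse_width_ms`` starting
    at ``pulse_starts_ms`` (a single pulse at t = 0 by default).
    """

    ve_unit: np.ndarray  # (n_comp,) or (batch, n_comp)
    pulse_width_ms: float = 0.3
    pulse_starts_ms: tuple = (0.0,)

    def envelope(self, t: float) -> float:
        for t0 in self.pulse_starts_ms:
            if t0 < t <= t0 + self.pulse_width_ms + 1e-12:
                return 1.0
        return 0.0

    def batched(self) -> np.ndarray:
        v = np.atleast_2d(np.asarray(self.ve_unit, dtype=float))
        return v


@dataclass
class MembraneTrajectory:
    """Recorded nodal response of one integration."""

    time: np.ndarray  # ms
    crossing_time: np.ndarray  # (batch, n_nodes) ms of first 0 mV crossing (nan)
    peak_vm: np.ndarray  # (batch, n_nodes) mV
    vm_nodes: Optional[np.ndarray] = None  # (n_steps, batch, n_nodes)
    vm_full: Optional[np.ndarray] = None  # (n_steps, batch, n_comp)
    amplitude_ma: Optional[np.ndarray] = None


def integrate(cable: CableModel, drive: ExtracellularDrive,
              amplitude_ma, dt_ms: float = 5e-3, t_end_ms: float = 3.3,
              record: str = "crossings",
              istim: Optional[tuple] = None,
              early_stop: bool = False,
              detection_level_mv: float = 0.0) -> MembraneTrajectory:
    """Backward-Euler integration of the double cable under a square pulse.

    ``amplitude_ma`` may be a scalar or an array (one amplitude per batch
    fiber; `drive.ve_unit` then carries a matching batch dimension).
    ``istim`` = (compartment, current_uA, t0_ms, t1_ms) injects an
    intracellular test current.  ``record`` is "crossings" (cheap) or
    "nodes"/"full" (store voltage histories).
    """
    morph = cable.morphology
    n = cable.n_compartments
    ve_unit = drive.batched()
    amp = np.atleast_1d(np.asarray(amplitude_ma, dtype=float))
    B = max(len(amp), ve_unit.shape[0])
    if ve_unit.shape[0] == 1 and B > 1:
        ve_unit = np.broadcast_to(ve_unit, (B, n))
    if len(amp) == 1 and B > 1:
        amp = np.broadcast_to(amp, (B,))
    if ve_unit.shape[1] != n:
        raise ValueError("drive length does not match compartment count")

    ch = cable.channels
    parent = morph.parent
    g_ax = cable.g_ax
    g_pax = cable.g_pax
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(1, n):
        children[parent[i]].append(i)
    sum_gax = g_ax.copy()
    sum_gpax = g_pax.copy()
    for i in range(n):
        for c in children[i]:
            sum_gax[i] += g_ax[c]
            sum_gpax[i] += g_pax[c]
    sum_gax[0] -= 0.0  # root has no parent term
    # note: g_ax[0] = 0 so the root sums are correct

    nsteps = int(np.round(t_end_ms / dt_ms))
    times = (np.arange(nsteps) + 1) * dt_ms

    vm = np.full((B, n), ch.v_rest)
    vp = np.zeros((B, n))
    nodes = morph.node_indices
    act = cable.node_mask
    m0, h0, p0, s0 = steady_gates(ch.v_rest, ch.celsius)
    m = np.full((B, n), m0)
    h = np.full((B, n), h0)
    p = np.full((B, n), p0)
    s = np.full((B, n), s0)

    cm_dt = cable.cm / dt_ms
    cmy_dt = cable.cmy / dt_ms
    gmy = cable.gmy

    d11s = np.empty((B, n))
    d12s = np.empty((B, n))
    d22s = np.empty((B, n))
    b1 = np.empty((B, n))
    b2 = np.empty((B, n))
    i11 = np.empty((B, n))
    i12 = np.empty((B, n))
    i22 = np.empty((B, n))
    x1 = np.empty((B, n))
    x2 = np.empty((B, n))

    crossing = np.full((B, len(nodes)), np.nan)
    peak = np.full((B, len(nodes)), ch.v_rest)
    rec_nodes = [] if record in ("nodes", "full") else None
    rec_full = [] if record == "full" else None

    ve_prev = np.zeros((B, n))
    pulse_w = drive.pulse_width_ms

    pulse_end = max(drive.pulse_starts_ms) + pulse_w
    for step, t in enumerate(times):
        on = drive.envelope(t)
        ve = (amp[:, None] * on) * ve_unit

        # gating (implicit linearized update, rates at current Vm)
        vmn = vm[:, nodes]
        (am, bm), (ah, bh), (ap, bp), (as_, bs) = gating_rates(vmn, ch.celsius)
        m[:, nodes] = (m[:, nodes] + dt_ms * am) / (1.0 + dt_ms * (am + bm))
        h[:, nodes] = (h[:, nodes] + dt_ms * ah) / (1.0 + dt_ms * (ah + bh))
        p[:, nodes] = (p[:, nodes] + dt_ms * ap) / (1.0 + dt_ms * (ap + bp))
        s[:, nodes] = (s[:, nodes] + dt_ms * as_) / (1.0 + dt_ms * (as_ + bs))

        g_active = (cable.gbar_naf * (m ** 3 * h) + cable.gbar_nap * (p ** 3))
        g_active = g_active + cable.gbar_ks * s
        ie = (cable.gbar_naf * (m ** 3 * h) + cable.gbar_nap * p ** 3) * ch.e_na
        ie = ie + cable.gbar_ks * s * ch.e_k + cable.g_pas * cable.e_pas
        gtot = g_active + cable.g_pas

        a = cm_dt + gtot  # (B, n)
        d11s[:] = a + sum_gax
        d12s[:] = -a
        d22s[:] = a + sum_gpax + cmy_dt + gmy
        r = cm_dt * vm + ie
        if istim is not None:
            comp, cur, t0_, t1_ = istim
            if t0_ < t <= t1_:
                r[:, comp] += cur
        b1[:] = r
        b2[:] = -r + cmy_dt * (vp - ve_prev) + (cmy_dt + gmy) * ve

        # block elimination leaves -> root (parent[i] < i)
        _solve_blocks(parent, g_ax, g_pax, d11s, d12s, d22s, b1, b2,
                      i11, i12, i22, x1, x2)

        vm = x1 - x2
        vp = x2  # alias is safe: read only before the next in-place solve
        ve_prev = ve
        if not np.all(np.isfinite(vm)):
            bad = np.argwhere(~np.isfinite(vm))[0]
            raise FloatingPointError(
                f"membrane state NaN at compartment {bad[1]}, t = {t:.4f} ms"
            )

        vmn = vm[:, nodes]
        peak = np.maximum(peak, vmn)
        newly = (vmn > detection_level_mv) & np.isnan(crossing)
        if newly.any():
            crossing[newly] = t
        if rec_nodes is not None:
            rec_nodes.append(vmn.copy())
        if rec_full is not None:
            rec_full.append(vm.copy())

        if early_stop and t > pulse_end + 0.5 and step % 25 == 0:
            fired = ~np.isnan(crossing).all(axis=1)
            quiet = vm.max(axis=1) < -60.0
            if np.all(fired | quiet):
                times = times[: step + 1]
                break

    return MembraneTrajectory(
        time=times, crossing_time=crossing, peak_vm=peak,
        vm_nodes=np.array(rec_nodes) if rec_nodes is not None else None,
        vm_full=np.array(rec_full) if rec_full is not None else None,
        amplitude_ma=np.asarray(amp),
    )


def focus_node(morph: AxonMorphology, ve_unit: np.ndarray) -> int:
    """Node of maximal depolarizing drive: peak discrete activating function
    (second spatial difference of the extracellular potential over nodes)."""
    ve = np.asarray(ve_unit, dtype=float)
    vn = ve[..., morph.node_indices]
    if vn.ndim > 1:
        vn = vn[0]
    f = np.empty_like(vn)
    f[1:-1] = vn[:-2] - 2 * vn[1:-1] + vn[2:]
    f[0] = vn[1] - vn[0]
    f[-1] = vn[-2] - vn[-1]
    return int(np.argmax(f))


def detect_propagation(traj: MembraneTrajectory, morph: AxonMorphology,
                       focus: int, standoff: int = 5,
                       batch_index: int = 0) -> bool:
    """True iff a 0 mV crossing occurred at a sentinel node >= `standoff`
    internodes from the maximally polarized node within the window."""
    idx = np.arange(morph.n_nodes)
    sentinels = np.abs(idx - focus) >= standoff
    if not sentinels.any():
        sentinels = idx == np.argmax(np.abs(idx - focus))
    return bool(np.any(np.isfinite(traj.crossing_time[batch_index, sentinels])))


def detect_propagation_batch(traj: MembraneTrajectory, morph: AxonMorphology,
                             focus: np.ndarray, standoff: int = 5) -> np.ndarray:
    idx = np.arange(morph.n_nodes)
    sent = np.abs(idx[None, :] - np.asarray(focus)[:, None]) >= standoff
    none = ~sent.any(axis=1)
    if none.any():
        far = np.argmax(np.abs(idx[None, :] - np.asarray(focus)[:, None]), axis=1)
        sent[none, far[none]] = True
    return np.any(np.isfinite(traj.crossing_time) & sent, axis=1)
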