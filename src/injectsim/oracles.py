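"""Analytic ground truths and synthetic measurement fixtures.

Two independent oracles verify the field and waveform pipelines:

* :class:`SlabOracle` -- exact complex impedance of a 1D layered slab between
  full-face plates, Z(w) = sum_i d_i / (sigma*_i A).
* :class:`LumpedRCOracle` -- a first-order surrogate circuit (electrode/skin
  interface resistance parallel to an interface capacitance, in series with a
  tissue resistance and the deep load) with closed-form piecewise-exponential
  responses to trapezoidal drives.

:func:`make_synthetic_traces` produces reproducible noisy voltage/current
traces with the qualitative shape of bench measurements (exponentially
charging electrode current under trapezoidal voltage drive), for testing
trace comparison and I/O code without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import TissueMaterial
from .waveforms import LinearResponseModel, TimeTraceSet, Waveform


@dataclass(frozen=True)
class SlabOracle:
    """1D series stack of tissue layers between full-face plates."""

    thicknesses: tuple[float, ...]  # m
    materials: tuple[TissueMaterial, ...]
    plate_area: float  # m^2

    def impedance(self, frequency: float) -> complex:
        return sum(
            d / (m.admittivity(frequency) * self.plate_area)
            for d, m in zip(self.thicknesses, self.materials)
        )


def slab_impedance(oracle: SlabOracle, frequency: float) -> complex:
    """Exact series impedance of the layered slab at `frequency` (Hz)."""
    return oracle.impedance(frequency)


@dataclass(frozen=True)
class LumpedRCOracle:
    """First-order surrogate: (R_int || C_int) + R_series + R_load.

    ``nerve_share`` is the fixed fraction of the drive current attributed to
    the deep-load branch when emitting I_Nerve traces (the surrogate has a
    single series path; the share only scales the nerve trace).
    """

    interface_resistance: float  # ohm
    interface_capacitance: float  # F
    series_tissue_resistance: float  # ohm
    load_resistance: float = 1000.0
    nerve_share: float = 0.1

    @property
    def r_downstream(self) -> float:
        return self.series_tissue_resistance + self.load_resistance

    def impedance(self, frequency: float) -> complex:
        r1, c = self.interface_resistance, self.interface_capacitance
        zint = r1 / (1.0 + 2j * np.pi * frequency * r1 * c)
        return zint + self.r_downstream

    # LinearResponseModel-compatible transfer factors
    def frequency_response(self, frequency: float, mode: str):
        z = self.impedance(frequency)
        if mode == "voltage":
            return 1.0, 1.0 / z, self.nerve_share / z
        return z, 1.0, self.nerve_share


class LumpedRCModel(LinearResponseModel):
    """Adapter letting the surrogate circuit drive waveform synthesis."""

    def __init__(self, oracle: LumpedRCOracle):
        self.oracle = oracle

    def frequency_response(self, frequency: float, mode: str):
        return self.oracle.frequency_response(frequency, mode)


def _segments(w: Waveform):
    """Breakpoints and (value, slope) of the piecewise-linear drive."""
    a, width, r, f = w.amplitude, w.pulse_width, w.rise_time, w.fall_time
    segs = []
    if r > 0:
        segs.append((0.0, r, 0.0, a / r))
    segs.append((r, width - f, a, 0.0))
    if f > 0:
        segs.append((width - f, width, a, -a / f))
    segs.append((width, w.duration, 0.0, 0.0))
    return segs


def rc_response(oracle: LumpedRCOracle, waveform: Waveform) -> TimeTraceSet:
    """Closed-form response of the surrogate circuit to a trapezoid drive.

    Voltage mode: solves (R1+R2) I + R1 R2 C dI/dt = V + R1 C dV/dt piecewise
    (particular linear solution + homogeneous exponential, continuity of I at
    segment boundaries).  Current mode: the interface voltage obeys
    C dU/dt + U/R1 = I with the same structure.
    """
    if waveform.frequency > 0:
        raise ValueError("rc_response expects a trapezoid waveform")
    r1 = oracle.interface_resistance
    c = oracle.interface_capacitance
    r2 = oracle.r_downstream
    dt = waveform.sample_interval
    t = np.arange(int(round(waveform.duration / dt)) + 1) * dt
    out = np.zeros_like(t)

    if waveform.mode == "voltage":
        tau = r1 * r2 * c / (r1 + r2)

        def particular(v0, a):
            beta = a / (r1 + r2)
            alpha = (v0 + r1 * c * a - r1 * r2 * c * beta) / (r1 + r2)
            return alpha, beta
    else:
        tau = r1 * c

        def particular(i0, a):
            beta = a * r1
            alpha = r1 * i0 - r1 * c * beta
            return alpha, beta

    state = 0.0  # I (voltage mode) or U (current mode), continuous
    segs = [s for s in _segments(waveform) if s[1] > s[0]]
    for n, (t0, t1, v0, slope) in enumerate(segs):
        alpha, beta = particular(v0, slope)
        k = state - alpha
        if n == len(segs) - 1:
            sel = t >= t0 - 0.25 * dt
        else:
            sel = (t >= t0 - 0.25 * dt) & (t < t1 - 0.25 * dt)
        u = t[sel] - t0
        out[sel] = alpha + beta * u + k * np.exp(-u / tau)
        state = alpha + beta * (t1 - t0) + k * np.exp(-(t1 - t0) / tau)

    v = waveform.sample(t)
    if waveform.mode == "voltage":
        i = out
        v_tes = v
    else:
        i = v  # the enforced current
        v_tes = out + i * r2
    return TimeTraceSet(
        time=t, v_tes=v_tes, i_tes=i * 1e3,
        i_nerve=i * oracle.nerve_share * 1e3,
    )


@dataclass
class SyntheticTraceSet:
    """Reproducible noisy replicates of a surrogate-circuit response."""

    traces: list[TimeTraceSet]
    clean: TimeTraceSet
    noise_sd: float
    seed: int


def make_synthetic_traces(oracle: LumpedRCOracle, waveform: Waveform,
                          noise_sd: float, seed: int,
                          n_replicates: int = 1) -> SyntheticTraceSet:
    """Noisy measurement-like traces; noise_sd in the units of each trace."""
    clean = rc_response(oracle, waveform)
    rng = np.random.default_rng(seed)
    traces = []
    for _ in range(n_replicates):
        traces.append(TimeTraceSet(
            time=clean.time,
            v_tes=clean.v_tes + noise_sd * rng.standard_normal(len(clean.time)),
            i_tes=clean.i_tes + noise_sd * rng.standard_normal(len(clean.time)),
            i_nerve=clean.i_nerve + noise_sd * rng.standard_normal(len(clean.time)),
        ))
    return SyntheticTraceSet(traces=traces, clean=clean, noise_sd=noise_sd,
                             seed=seed)


def fit_lumped_to_fem(config, resolution: str = "coarse",
                      fit_frequency: float = 1e4) -> LumpedRCOracle:
    """Fit the surrogate to the field model's DC resistance and AC impedance.

    R_int + R_down matches the DC input resistance; (R_down, C_int) are then
    least-squares fitted to the complex input impedance at `fit_frequency`.
    The load resistance is taken from the configuration; the DC capture ratio
    sets ``nerve_share``.
    """
    from scipy.optimize import least_squares

    from .mesh import generate_mesh
    from .solver import DriveSpec, assemble, compute_metrics, solve

    mesh = generate_mesh(config, resolution)
    system = assemble(mesh, config)
    dc = solve(system, DriveSpec("current", 1.0, 0.0, config.mode))
    r_dc = float(np.real(dc.v_tes / dc.i_tes))
    share = compute_metrics(dc).efficiency / 100.0
    ac = solve(system, DriveSpec("current", 1.0, fit_frequency, config.mode))
    z_ac = complex(ac.v_tes / ac.i_tes)

    def resid(p):
        r2, logc = p
        r1 = r_dc - r2
        zint = r1 / (1.0 + 2j * np.pi * fit_frequency * r1 * 10.0**logc)
        z = zint + r2
        return [z.real - z_ac.real, z.imag - z_ac.imag]

    sol = least_squares(resid, x0=[max(z_ac.real, 1.0), -7.0],
                        bounds=([1e-3, -12.0], [r_dc * 0.999, -3.0]))
    r2, logc = sol.x
    rload = config.load.resistance if config.load is not None else 1000.0
    return LumpedRCOracle(
        interface_resistance=r_dc - r2,
        interface_capacitance=10.0**logc,
        series_tissue_resistance=max(r2 - rload, 0.0),
        load_resistance=rload,
        nerve_share=share,
    )
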