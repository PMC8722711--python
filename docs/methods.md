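# Methods

`injectsim` models transcutaneous electrical stimulation (TES) delivered
through skin-surface patch electrodes to an injectable conductive electrode
system: a subcutaneous disc-shaped *collector* under each patch, an insulated
lead, and a cuff-like interface on a deep target nerve. Two questions drive
the design: how much of the surface current is captured into the deep path
(transcutaneous coupling), and how selectively the deep on-target axons are
recruited relative to off-target cutaneous afferents (field-cable
biophysics).

## Electroquasistatic volume conductor

The tissue is a three-layer slab — skin (1 mm), fat (5 mm), muscle (40 mm) —
on a 21 × 11 cm footprint, with square hydrogel-backed surface patches
(default 5 × 5 cm, 2 cm edge-to-edge) and 2.1 cm collector discs centered
under the patches at the skin–fat boundary. The potential solves the
electroquasistatic equation

    div( (sigma + j*omega*eps0*eps_r) grad V ) = 0,

retaining ohmic and displacement (capacitive) currents and neglecting
induction. Material properties (conductivity and relative permittivity of
skin, fat, muscle, epineurium, hydrogel) are fixed, non-dispersive values
appropriate for the 0–25 kHz range; dispersion is deliberately not modeled.
Boundaries carry zero normal current, except the five outer muscle surfaces,
which are grounded in the monopolar configuration.

Discretization is a trilinear hexahedral FEM on a graded tensor-product
grid. All geometric features (patch edges, collector extents and depths,
layer boundaries, the nerve bounding box, cuff windows) are snapped onto
grid planes; disc and cylinder footprints are staircase approximations with
coverage-weighted boundary facets and a total-area normalization to the
exact analytic area. Three resolution levels are provided (`coarse` ≈ 10k
nodes, `standard` ≈ 45k, `fine` ≈ 85k); the capture ratio changes by < 1 %
between `standard` and `fine`, and z-refinement beyond `standard` changes it
by < 0.01 %, so `coarse` is the default working resolution and is what the
shipped analyses use.

Conductors are *not* meshed volumes. Each surface patch is an equipotential
node set; each collector(+lead+cuff) is a single floating equipotential
degree of freedom coupled to coincident tissue nodes through the measured
contact impedance (6.9 × 10⁻² Ω·m², purely resistive; surface current
density = ΔV / Zc). The collector disc is impermeable: mesh nodes on the
disc plane are duplicated so tissue above and below communicates only
through the conductor, and both faces couple through the contact impedance —
the behaviour of a metal disc. The simplified variant couples the two
collectors with a lumped 1 kΩ resistor stamped directly between the
conductor DOFs (one sparse solve, no iteration); the full biophysical
variant replaces the resistor with a 3 mm epineurium cylinder carrying a
5 mm cuff window under each patch, with ideal insulated leads (the collector,
lead, and cuff share one equipotential DOF).

Solves use a direct sparse LU factorization. DC, frequency-domain (complex
admittivity), and backward-Euler transient studies share one assembly: the
conduction and displacement matrices are built once and combined per
frequency / time step.

**Nerve depth.** The source geometry never states the nerve depth
numerically and shows it schematically at mid-muscle. The default places the
nerve axis at 26 mm below the skin surface — the mid-depth of the muscle
layer, within the range of the human cervical vagus. At shallower
placements (e.g. 15 mm) the surface-only vagal thresholds fall several-fold
below every reported value, so mid-muscle is also the placement consistent
with the reported recruitment results. It is configurable
(`NerveSpec.depth_below_surface`).

## Waveforms

Stimuli are symmetric trapezoids (amplitude, envelope width, rise/fall
times) or sinusoids, in current- or voltage-controlled mode. Because the
system is linear and time-invariant, time-domain responses are synthesized
by harmonic superposition: the drive is zero-padded to 10× its pulse width,
Fourier-decomposed, each retained harmonic is propagated through the complex
frequency response, and the terms are superposed. A backward-Euler
time-stepping path (one factorization, reused every step) serves as the
independent transient reference and is used for the displacement-current
experiment: skin conductivity is set to 0 S/m (permittivity unchanged) and
the fraction of rectified nerve charge retained under the fastest-rise 28 V
pulse is reported.

## Axon biophysics

Myelinated fibers follow the McIntyre–Richardson–Grill (MRG) double-cable
construction: explicit nodes of Ranvier, MYSA and FLUT paranodal sections,
six equal STIN internodal compartments, a finite-conductance myelin sheath,
and a periaxonal conduction space. Geometric parameters are tabulated for
the published diameters; the 2.0 µm Aδ fiber uses a log-log extrapolation of
every tabulated parameter (audit table available via
`mrg_extrapolation_table`). Nodal membrane dynamics default to the MRG
channel set — fast Na⁺, persistent Na⁺, slow K⁺, leak — at 37 °C, with the
parameter set pluggable (`ChannelSet`). The specific low/high-threshold
mechanoreceptor channel variants used by the source study are cited there
but not printed, so thresholds are expected to agree only approximately;
see Limitations.

Fiber classes: vagal Aβ (10 µm, plain axon), cutaneous Aβ (10 µm,
terminated in a passive node of Ranvier), cutaneous Aδ (2 µm, terminated in
an unmyelinated passive branching arbor — default two generations of two
150 µm branches — spreading horizontally under the epidermis).

Integration is backward Euler at 5 µs with the standard linearized implicit
gating update. The linear solve per step is an exact 2×2-block elimination
over the compartment tree (intracellular and periaxonal potential per
compartment), vectorized across a batch of fibers sharing one morphology; a
numba-compiled kernel accelerates the elimination when available, with an
identical pure-NumPy path otherwise. The simulation window is a 300 µs
square pulse plus 3 ms observation; integration ends early once every fiber
in the batch has either fired or relaxed below −60 mV after the pulse.

Propagation is detected as a 0 mV crossing at a sentinel node at least five
internodes from the node of maximal activating function (the second spatial
difference of the extracellular potential over nodes), which is robust to
the stimulus artifact at the polarization focus. Sealed-end nodes amplify
arriving spikes, so end nodes within the sentinel set provide a reliable
propagation witness even when mid-axon peaks sit near the detection level.

## Populations and field sampling

Populations are deterministic functions of the geometry: vagal axons on a
100 µm grid across the nerve cross-section (straight, full nerve length);
cutaneous terminals on a 1.5 mm grid over the active (cathodic) patch plus a
5 mm margin, at 900 µm (Aβ) or 500 µm (Aδ) depth, each fiber descending
obliquely to a horizontal run at 4 mm depth parallel to the nerve.
`spacing_scale` multiplies the grid spacings; the shipped analyses use ×3
(desk scale, tens to hundreds of fibers per class).

Extracellular potentials are sampled at compartment midpoints arc-mapped
along each trajectory, from the unit-drive DC solution (exact amplitude
scaling by linearity). Sampling uses tensor-product PCHIP interpolation: a
C0 (trilinear) interpolant has slope kinks at every cell face that masquerade
as activating-function spikes and can dominate thresholds on graded meshes,
while ordinary cubic splines ring at the genuine derivative jumps across
layer interfaces; shape-preserving C1 interpolation avoids both. At desk
scale a fixed-length morphology (41 nodes for vagal fibers — medians change
< 1 % versus 61 nodes — and 21 nodes for cutaneous fibers) is centered on
the activation site of the full-length trajectory (maximum activating
function); cutaneous fibers are anchored at their terminal.

## Thresholds and recruitment statistics

Per-fiber thresholds use bracket doubling from 0.1 mA (cap 500 mA) followed
by bisection to 1 µA, with the whole population searched in lockstep (each
fiber testing its own candidate amplitude inside one batched integration).
Results are keyed and sorted by fiber id, so output order is deterministic.
Summaries report per-class medians over converged fibers, and the
vagus-to-cutaneous Aβ ratio of medians over the ten most excitable fibers
per class (flagged if fewer than ten converge). The surface-only condition
("TES alone") removes collectors, leads, and cuffs from the identical
geometry and re-evaluates the same populations.

## Numerical choices and degenerate inputs

* Direct LU for every resolution; complex solves only when ω > 0 (the DC
  matrix is exactly real).
* Zero-amplitude drives return identically zero fields with the efficiency
  flagged undefined rather than raising.
* Contact impedance is purely resistive; interface capacitance is not
  modeled.
* Gating rate functions use series-expanded forms near removable
  singularities; extreme voltages saturate rather than overflow.
* Threshold search is bitwise repeatable; brackets satisfy sub-fails /
  supra-fires / gap ≤ 1 µA for every converged fiber.

## What the synthetic oracles emulate — and what they do not

`SlabOracle` (exact 1D layered impedance) and `LumpedRCOracle` (first-order
interface circuit with closed-form trapezoid responses) verify the solver
and the waveform synthesis independently. `make_synthetic_traces` adds
seeded Gaussian noise to the surrogate-circuit response, emulating the
*shape* of bench voltage/current recordings (exponentially charging
electrode current under trapezoidal drive) for testing trace I/O and
comparison code. They do not emulate electrode drift, electroporation,
dispersive tissue, or inter-subject variability — passing tests against them
validates the numerics, not the physiology.

## Limitations

* The cutaneous afferent channel sets are the MRG defaults, not the
  specific mechanoreceptor variants of the source study; measured against
  the reported values, our cutaneous classes are uniformly about 2× less
  excitable, which propagates into the absolute cutaneous medians and the
  selectivity ratios while leaving the vagal-side results and all trends
  intact.
* A thin impermeable disc with DC series-resistance physics roughly doubles
  the capture ratio when the collector sits mid-skin; the reported
  mid-skin value (14.5 %) is much lower, suggesting a thick disc or a
  different depth datum in the original sweep. The 1.0–5 mm portion of the
  depth sweep reproduces quantitatively.
* Enlarging the lateral domain by 50 % changes the nerve current by ~2 %
  (insulating boundaries 2 cm from the patch edges), slightly more than the
  1 % insensitivity asserted for the original model.
* Geometry is idealized (planar layers, straight nerve, isotropic muscle);
  no dispersion, no electroporation, no electrode electrochemistry beyond
  the fixed contact impedance.
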