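"""Shared test helpers."""

import numpy as np


def point_source_drive(morph, distance_m=2e-3, node=None, sigma=0.2):
    """Extracellular potentials of a cathodic point source above one node."""
    from injectsim.axon import ExtracellularDrive

    node = morph.n_nodes // 2 if node is None else node
    s0 = morph.arc_um[morph.node_indices[node]] * 1e-6
    r = np.sqrt((morph.arc_um * 1e-6 - s0) ** 2 + distance_m**2)
    ve = -1.0 / (4 * np.pi * sigma * r)  # mV per mA (cathodic)
    return ExtracellularDrive(ve_unit=ve)
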