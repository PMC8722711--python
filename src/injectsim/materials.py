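"""Tissue and interface materials for the electroquasistatic model.

Each material carries a (frequency-independent) conductivity and relative
permittivity; the complex admittivity sigma* = sigma + j*omega*eps0*eps_r is
formed at assembly time.  Dispersive (frequency-dependent) properties are out
of scope; the model is intended for the 0-25 kHz range where skin, fat, and
muscle conductivities are essentially flat.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

EPS0 = 8.8541878128e-12  # vacuum permittivity, F/m


@dataclass(frozen=True)
class TissueMaterial:
    """Electrical properties of one tissue or device material.

    Parameters
    ----------
    name : str
        Label used for mesh material bookkeeping and serialization.
    conductivity : float
        Bulk conductivity in S/m.  Zero is permitted only when
        ``allow_nonphysical`` is set (mechanism experiments such as the
        displacement-current decomposition turn skin conduction off).
    relative_permittivity : float
        Dimensionless relative permittivity; must be >= 1 for physical
        materials.
    allow_nonphysical : bool
        Flags materials deliberately outside the physical range.
    """

    name: str
    conductivity: float
    relative_permittivity: float = 1.0
    allow_nonphysical: bool = False

    def __post_init__(self) -> None:
        if self.conductivity < 0:
            raise ValueError(f"{self.name}: conductivity must be >= 0")
        if self.conductivity == 0 and not self.allow_nonphysical:
            raise ValueError(
                f"{self.name}: zero conductivity requires allow_nonphysical=True"
            )
        if self.relative_permittivity < 1 and not self.allow_nonphysical:
            raise ValueError(
                f"{self.name}: relative permittivity must be >= 1 "
                "(or flag the material allow_nonphysical)"
            )

    def admittivity(self, frequency: float) -> complex:
        """Complex admittivity sigma + j*2*pi*f*eps0*eps_r at `frequency` (Hz).

        At frequency 0 the imaginary part is exactly zero and a real number
        is returned.
        """
        if frequency == 0:
            return self.conductivity
        return self.conductivity + 1j * 2.0 * np.pi * frequency * EPS0 * (
            self.relative_permittivity
        )

    def with_conductivity(self, sigma: float) -> "TissueMaterial":
        """Copy with a different conductivity (non-physical values allowed)."""
        return replace(self, conductivity=sigma, allow_nonphysical=True)


# Reference material library: human/animal tissue at 37 degC, 1 kHz, plus the
# device materials (hydrogel under the surface patches; the injectable
# conductor itself, modelled as a generic highly conductive metal).
SKIN = TissueMaterial("skin", 1.80e-4, 1.17e3)
FAT = TissueMaterial("fat", 2.46e-2, 2.08e4)
MUSCLE = TissueMaterial("muscle", 5.23e-1, 1.24e6)
# Epineurium permittivity is not reported in the source database; the nerve
# bulk is used in DC-dominant solves, so eps_r = 1 is adopted.
EPINEURIUM = TissueMaterial("epineurium", 1.59e-1, 1.0)
HYDROGEL = TissueMaterial("hydrogel", 1.6e-2, 1.4e6)
INJECTRODE_METAL = TissueMaterial("injectrode", 3.774e7, 1.0)

MATERIAL_LIBRARY = {
    m.name: m
    for m in (SKIN, FAT, MUSCLE, EPINEURIUM, HYDROGEL, INJECTRODE_METAL)
}
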