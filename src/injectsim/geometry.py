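"""Layered tissue geometry, electrode/collector layout, and model configuration.

Coordinate convention (SI meters throughout): the origin sits at a corner of
the rectangular domain on the skin surface, x along the long (21 cm) edge,
y along the short (11 cm) edge, and z positive *downward* into tissue.  The
hydrogel layer under each surface patch occupies z in [-hydrogel_thickness, 0].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

from .materials import (
    EPINEURIUM,
    FAT,
    HYDROGEL,
    MATERIAL_LIBRARY,
    MUSCLE,
    SKIN,
    TissueMaterial,
)

Variant = Literal["simplified", "full_biophysical"]
Mode = Literal["bipolar", "monopolar"]


@dataclass(frozen=True)
class LayeredGeometry:
    """Three-layer slab: skin on top, then fat, then muscle."""

    domain_length: float = 0.21  # x extent, m
    domain_width: float = 0.11  # y extent, m
    skin_thickness: float = 1e-3
    fat_thickness: float = 5e-3
    muscle_thickness: float = 40e-3

    def __post_init__(self) -> None:
        for name in (
            "domain_length",
            "domain_width",
            "skin_thickness",
            "fat_thickness",
            "muscle_thickness",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def total_thickness(self) -> float:
        return self.skin_thickness + self.fat_thickness + self.muscle_thickness

    @property
    def fat_top(self) -> float:
        return self.skin_thickness

    @property
    def muscle_top(self) -> float:
        return self.skin_thickness + self.fat_thickness


@dataclass(frozen=True)
class SurfaceElectrode:
    """Square TES patch on the skin surface with a thin hydrogel interlayer."""

    side_length: float
    center_xy: tuple[float, float]
    polarity: Literal["source", "return"]
    hydrogel_thickness: float = 1e-3
    hydrogel_material: TissueMaterial = HYDROGEL

    def bounds(self) -> tuple[float, float, float, float]:
        cx, cy = self.center_xy
        h = self.side_length / 2.0
        return (cx - h, cx + h, cy - h, cy + h)


@dataclass(frozen=True)
class Collector:
    """Subcutaneous conductive disc coupled to tissue via a contact impedance."""

    diameter: float = 0.021
    depth_below_surface: float = 1e-3
    center_xy: tuple[float, float] = (0.0, 0.0)
    contact_impedance: float = 6.9e-2  # ohm * m^2
    material: TissueMaterial = field(
        default_factory=lambda: MATERIAL_LIBRARY["injectrode"]
    )


@dataclass(frozen=True)
class CircuitLoad:
    """Lumped two-terminal load standing in for the deep nerve path."""

    resistance: float = 1000.0
    terminals: tuple[str, str] = ("collector_0", "collector_1")

    def __post_init__(self) -> None:
        if self.resistance <= 0:
            raise ValueError("load resistance must be > 0")
        if len(self.terminals) != 2:
            raise ValueError("load must have exactly two terminals")


@dataclass(frozen=True)
class NerveSpec:
    """Deep target nerve: epineurium cylinder running along x in muscle."""

    diameter: float = 3e-3
    # default: mid-depth of the muscle layer (cervical vagus range)
    depth_below_surface: float = 26e-3  # depth of the cylinder axis
    axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    material: TissueMaterial = field(default_factory=lambda: EPINEURIUM)
    cuff_length: float = 5e-3

    def __post_init__(self) -> None:
        if self.axis != (1.0, 0.0, 0.0):
            raise ValueError("only nerves running along +x are supported")


@dataclass(frozen=True)
class ModelConfiguration:
    """Complete geometry + electrical layout of one simulation.

    The ``simplified`` variant couples the two collectors through a
    ``CircuitLoad``; the ``full_biophysical`` variant replaces the load by a
    nerve cylinder with ideal insulated leads running from each collector to
    a cuff on the nerve surface.  ``mode`` = monopolar grounds the five outer
    muscle surfaces and returns the load to ground.
    """

    geometry: LayeredGeometry
    materials: dict[str, TissueMaterial]
    electrodes: tuple[SurfaceElectrode, ...]
    collectors: tuple[Collector, ...]
    load: Optional[CircuitLoad] = None
    nerve: Optional[NerveSpec] = None
    mode: Mode = "bipolar"
    variant: Variant = "simplified"

    def __post_init__(self) -> None:
        if self.mode == "bipolar":
            if len(self.electrodes) != 2:
                raise ValueError("bipolar configuration needs 2 electrodes")
        elif len(self.electrodes) != 1:
            raise ValueError("monopolar configuration needs 1 electrode")
        if self.variant == "simplified":
            if self.nerve is not None:
                raise ValueError("simplified variant uses a CircuitLoad, not a nerve")
        else:
            if self.nerve is None:
                raise ValueError("full_biophysical variant requires a NerveSpec")
            if self.load is not None:
                raise ValueError("full_biophysical variant replaces the load")
        for i, a in enumerate(self.electrodes):
            for b in self.electrodes[i + 1:]:
                ax0, ax1, ay0, ay1 = a.bounds()
                bx0, bx1, by0, by1 = b.bounds()
                if ax0 < bx1 and bx0 < ax1 and ay0 < by1 and by0 < ay1:
                    raise ValueError("surface patches overlap")
        g = self.geometry
        for c in self.collectors:
            r = c.diameter / 2.0
            cx, cy = c.center_xy
            if (
                cx - r < 0
                or cx + r > g.domain_length
                or cy - r < 0
                or cy + r > g.domain_width
                or not 0 < c.depth_below_surface < g.total_thickness
            ):
                raise ValueError("collector disc lies outside the domain")
        if self.nerve is not None:
            zc = self.nerve.depth_below_surface
            r = self.nerve.diameter / 2.0
            if not (g.muscle_top + r <= zc <= g.total_thickness - r):
                raise ValueError("nerve cylinder must be contained in muscle")

    def source_electrode(self) -> SurfaceElectrode:
        return next(e for e in self.electrodes if e.polarity == "source")

    def return_electrode(self) -> Optional[SurfaceElectrode]:
        for e in self.electrodes:
            if e.polarity == "return":
                return e
        return None

    def with_materials(self, **overrides: TissueMaterial) -> "ModelConfiguration":
        mats = dict(self.materials)
        mats.update(overrides)
        return replace(self, materials=mats)


def build_default_configuration(
    variant: Variant = "simplified",
    *,
    patch_side: float = 0.05,
    separation: float = 0.02,
    collector_diameter: float = 0.021,
    collector_depth: float = 1e-3,
    mode: Mode = "bipolar",
    load_resistance: float = 1000.0,
    nerve_depth: float = 26e-3,
    hydrogel_thickness: float = 1e-3,
) -> ModelConfiguration:
    """The standard model configuration.

    1/5/40 mm skin/fat/muscle layers on a 21 x 11 cm footprint; square 5 x 5 cm
    hydrogel-backed patches at 2 cm edge-to-edge separation, each centered over
    a 2.1 cm collector disc at the skin-fat boundary; a 1 kohm load between the
    collectors (simplified) or a 3 mm epineurium nerve cylinder with ideal
    leads and 5 mm cuffs (full_biophysical).  Monopolar mode keeps a single
    centered patch/collector pair with the load returned to ground.
    """
    geom = LayeredGeometry()
    cx = geom.domain_length / 2.0
    cy = geom.domain_width / 2.0
    materials = {
        "skin": SKIN,
        "fat": FAT,
        "muscle": MUSCLE,
    }
    if mode == "monopolar":
        centers = [(cx, cy)]
        polarities = ["source"]
    else:
        off = patch_side / 2.0 + separation / 2.0
        centers = [(cx - off, cy), (cx + off, cy)]
        polarities = ["source", "return"]
    electrodes = tuple(
        SurfaceElectrode(
            side_length=patch_side,
            center_xy=c,
            polarity=p,
            hydrogel_thickness=hydrogel_thickness,
        )
        for c, p in zip(centers, polarities)
    )
    collectors = tuple(
        Collector(
            diameter=collector_diameter,
            depth_below_surface=collector_depth,
            center_xy=c,
        )
        for c in centers
    )
    load = None
    nerve = None
    if variant == "simplified":
        terminals = (
            ("collector_0", "ground")
            if mode == "monopolar"
            else ("collector_0", "collector_1")
        )
        load = CircuitLoad(resistance=load_resistance, terminals=terminals)
        materials = dict(materials)
    else:
        nerve = NerveSpec(depth_below_surface=nerve_depth)
        materials = dict(materials)
        materials["epineurium"] = EPINEURIUM
    return ModelConfiguration(
        geometry=geom,
        materials=materials,
        electrodes=electrodes,
        collectors=collectors,
        load=load,
        nerve=nerve,
        mode=mode,
        variant=variant,
    )
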