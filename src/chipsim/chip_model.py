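"""Geometry of the 7-channel tri-culture chip and its Transwell comparator.

The chip cross-section is a mirror-symmetric sequence of seven parallel
channels: outer endothelial medium channels (#1/#7), astrocyte-laden collagen
channels (#2/#6), communication medium channels (#3/#5) and the central tumor
collagen channel (#4).  Each medium channel is fed from reservoir ports at
its ends; those reservoirs hold nearly all of the liquid volume (a channel
is ~1.2 uL, a reservoir load is 60-120 uL).

The Transwell comparator is a static insert-in-well column holding the same
cells and the same total medium volume, used to quantify how much the
microscale confinement of the chip enriches secreted factors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum

from .errors import ConfigError
from .hydrodynamics import GelSpec


class ChannelRole(str, Enum):
    MEDIUM = "medium"
    GEL = "gel"


#: Channel roles in cross-section order; gel and medium strictly alternate.
CHANNEL_ROLES: tuple[ChannelRole, ...] = (
    ChannelRole.MEDIUM,  # 1 endothelial
    ChannelRole.GEL,     # 2 astrocyte collagen
    ChannelRole.MEDIUM,  # 3 communication
    ChannelRole.GEL,     # 4 tumor collagen (symmetry center)
    ChannelRole.MEDIUM,  # 5 communication
    ChannelRole.GEL,     # 6 astrocyte collagen
    ChannelRole.MEDIUM,  # 7 endothelial
)

VALID_CELL_TYPES = ("tumor", "astrocyte", "bEC")

#: Compartments each cell type is allowed to occupy.
_ALLOWED_COMPARTMENTS = {
    "tumor": (4,),
    "astrocyte": (2, 6),
    "bEC": (1, 7),
}


@dataclass(frozen=True)
class CellPopulation:
    """A cell population placed in one channel compartment.

    ``count`` is the absolute number of cells in that compartment (gel-embedded
    cells from density x gel volume; adherent endothelial cells from the
    seeding suspension volume x density).
    """

    cell_type: str
    count: float
    compartment: int

    def __post_init__(self) -> None:
        if self.cell_type not in VALID_CELL_TYPES:
            raise ConfigError(f"unknown cell type {self.cell_type!r}")
        if self.count < 0:
            raise ConfigError(f"cell count must be >= 0, got {self.count}")
        if self.compartment not in _ALLOWED_COMPARTMENTS[self.cell_type]:
            raise ConfigError(
                f"{self.cell_type} cells cannot be placed in channel #{self.compartment}"
            )

    @classmethod
    def from_density(
        cls, cell_type: str, density_per_ml: float, volume_ul: float, compartment: int
    ) -> "CellPopulation":
        """Gel-embedded population from a cell density and the gel volume."""
        return cls(cell_type, density_per_ml * volume_ul * 1e-3, compartment)

    @classmethod
    def from_seeding(
        cls, cell_type: str, suspension_per_ml: float, seeded_volume_ul: float, compartment: int
    ) -> "CellPopulation":
        """Adherent population from the seeding suspension placed in the channel."""
        return cls(cell_type, suspension_per_ml * seeded_volume_ul * 1e-3, compartment)


@dataclass(frozen=True)
class ChannelCompartment:
    """One channel of the chip cross-section."""

    index: int
    role: ChannelRole
    width_um: float
    height_um: float
    length_mm: float
    gel: GelSpec | None = None
    populations: tuple[CellPopulation, ...] = ()
    reservoir_volume_ul: float = 0.0

    def __post_init__(self) -> None:
        if not 1 <= self.index <= 7:
            raise ConfigError(f"channel index must be 1..7, got {self.index}")
        if min(self.width_um, self.height_um, self.length_mm) <= 0:
            raise ConfigError(f"channel #{self.index} has a non-positive dimension")
        if self.role is ChannelRole.GEL and self.gel is None:
            raise ConfigError(f"gel channel #{self.index} has no GelSpec")
        if self.role is ChannelRole.MEDIUM and self.gel is not None:
            raise ConfigError(f"medium channel #{self.index} carries a GelSpec")
        for pop in self.populations:
            if pop.compartment != self.index:
                raise ConfigError(
                    f"population for channel #{pop.compartment} placed in #{self.index}"
                )

    @property
    def volume_ul(self) -> float:
        return self.width_um * 1e-6 * self.height_um * 1e-6 * self.length_mm * 1e-3 * 1e9

    @property
    def width_m(self) -> float:
        return self.width_um * 1e-6

    @property
    def cross_section_m2(self) -> float:
        """Area normal to the across-width direction (height x length)."""
        return self.height_um * 1e-6 * self.length_mm * 1e-3


@dataclass(frozen=True)
class ChipLayout:
    """Ordered, mirror-symmetric cross-section of the seven channels."""

    channels: tuple[ChannelCompartment, ...]

    def __post_init__(self) -> None:
        if len(self.channels) != 7:
            raise ConfigError(f"expected 7 channels, got {len(self.channels)}")
        for i, ch in enumerate(self.channels, start=1):
            if ch.index != i:
                raise ConfigError("channels must be ordered by index 1..7")
            if ch.role is not CHANNEL_ROLES[i - 1]:
                raise ConfigError(
                    f"channel #{i} must be {CHANNEL_ROLES[i - 1].value}, got {ch.role.value}"
                )

    def compartment(self, index: int) -> ChannelCompartment:
        return self.channels[index - 1]

    @property
    def is_mirror_symmetric(self) -> bool:
        """Compartments i and 8-i agree in dimensions, gel and cell contents."""
        for i in range(1, 4):
            a, b = self.compartment(i), self.compartment(8 - i)
            if (a.width_um, a.height_um, a.length_mm, a.gel) != (
                b.width_um, b.height_um, b.length_mm, b.gel,
            ):
                return False
            if sorted((p.cell_type, p.count) for p in a.populations) != sorted(
                (p.cell_type, p.count) for p in b.populations
            ):
                return False
        return True

    @property
    def medium_volume_ul(self) -> float:
        """Total liquid volume of medium channels plus their reservoirs, uL."""
        return sum(
            ch.volume_ul + ch.reservoir_volume_ul
            for ch in self.channels
            if ch.role is ChannelRole.MEDIUM
        )


@dataclass(frozen=True)
class TranswellLayout:
    """Insert-in-well comparator: bTME cells in the insert, tumor at the well floor.

    Modeled as a 1-D vertical diffusion column of uniform cross-section
    ``well_area_cm2``; the insert membrane sits ``separation_mm`` above the
    well floor and is treated as freely permeable.
    """

    insert_volume_ul: float
    well_volume_ul: float
    insert_cells: dict[str, float]
    well_cells: dict[str, float]
    separation_mm: float = 0.9
    well_area_cm2: float = 1.9

    def __post_init__(self) -> None:
        if self.insert_volume_ul <= 0 or self.well_volume_ul <= 0:
            raise ConfigError("Transwell compartment volumes must be > 0")
        if self.separation_mm <= 0:
            raise ConfigError("Transwell separation must be > 0")

    @property
    def total_volume_ul(self) -> float:
        return self.insert_volume_ul + self.well_volume_ul

    @property
    def column_height_mm(self) -> float:
        """Total liquid column height for the 1-D model, mm."""
        return self.total_volume_ul * 1e-9 / (self.well_area_cm2 * 1e-4) * 1e3

    def cell_counts(self) -> dict[str, float]:
        counts = {t: 0.0 for t in VALID_CELL_TYPES}
        for pool in (self.insert_cells, self.well_cells):
            for cell_type, n in pool.items():
                counts[cell_type] += n
        return counts


# --- defaults -------------------------------------------------------------
# Channel widths are not printed in the source protocol; 1.0 mm channels,
# 200 um height (the photoresist thickness) and 6 mm culture length are the
# shipped calibrated defaults.
DEFAULT_MEDIUM_WIDTH_UM = 1000.0
DEFAULT_GEL_WIDTH_UM = 1000.0
DEFAULT_HEIGHT_UM = 200.0
DEFAULT_LENGTH_MM = 6.0
#: Daily refresh volume per medium channel (held in its reservoir ports), uL.
DEFAULT_RESERVOIR_UL = 120.0
#: Final gel-embedded cell density after the 10x dilution into collagen.
DEFAULT_GEL_CELL_DENSITY_PER_ML = 1.0e6
#: Endothelial seeding: 60 uL of suspension at 8.0e5 cells/mL per outer channel.
DEFAULT_BEC_SUSPENSION_PER_ML = 8.0e5
DEFAULT_BEC_SEED_VOLUME_UL = 60.0


def build_chip(config: dict | None = None) -> ChipLayout:
    """Build the default (or config-overridden) 7-channel layout.

    Recognized config keys (all optional): ``medium_channel_width_um``,
    ``gel_channel_width_um``, ``height_um``, ``length_mm``,
    ``reservoir_volume_ul``, ``gel`` (GelSpec or mapping),
    ``gel_cell_density_per_ml``, ``bec_suspension_per_ml``,
    ``bec_seed_volume_ul``, ``populate`` (bool, default True).
    """
    cfg = dict(config or {})
    unknown = set(cfg) - {
        "medium_channel_width_um", "gel_channel_width_um", "height_um", "length_mm",
        "reservoir_volume_ul", "gel", "gel_cell_density_per_ml",
        "bec_suspension_per_ml", "bec_seed_volume_ul", "populate",
    }
    if unknown:
        raise ConfigError(f"unknown geometry config keys: {sorted(unknown)}")

    medium_w = float(cfg.get("medium_channel_width_um", DEFAULT_MEDIUM_WIDTH_UM))
    gel_w = float(cfg.get("gel_channel_width_um", DEFAULT_GEL_WIDTH_UM))
    height = float(cfg.get("height_um", DEFAULT_HEIGHT_UM))
    length = float(cfg.get("length_mm", DEFAULT_LENGTH_MM))
    reservoir = float(cfg.get("reservoir_volume_ul", DEFAULT_RESERVOIR_UL))
    gel = cfg.get("gel", GelSpec())
    if isinstance(gel, dict):
        gel = GelSpec(**gel)
    gel_density = float(cfg.get("gel_cell_density_per_ml", DEFAULT_GEL_CELL_DENSITY_PER_ML))
    bec_density = float(cfg.get("bec_suspension_per_ml", DEFAULT_BEC_SUSPENSION_PER_ML))
    bec_volume = float(cfg.get("bec_seed_volume_ul", DEFAULT_BEC_SEED_VOLUME_UL))
    populate = bool(cfg.get("populate", True))

    channels = []
    for index, role in enumerate(CHANNEL_ROLES, start=1):
        width = medium_w if role is ChannelRole.MEDIUM else gel_w
        ch = ChannelCompartment(
            index=index,
            role=role,
            width_um=width,
            height_um=height,
            length_mm=length,
            gel=gel if role is ChannelRole.GEL else None,
            reservoir_volume_ul=reservoir if role is ChannelRole.MEDIUM else 0.0,
        )
        if populate:
            pops: list[CellPopulation] = []
            if index == 4:
                pops.append(
                    CellPopulation.from_density("tumor", gel_density, ch.volume_ul, index)
                )
            elif index in (2, 6):
                pops.append(
                    CellPopulation.from_density("astrocyte", gel_density, ch.volume_ul, index)
                )
            elif index in (1, 7):
                pops.append(
                    CellPopulation.from_seeding("bEC", bec_density, bec_volume, index)
                )
            ch = replace(ch, populations=tuple(pops))
        channels.append(ch)
    return ChipLayout(tuple(channels))


def cell_counts(layout: ChipLayout) -> dict[str, float]:
    """Absolute cell numbers per cell type across the whole chip."""
    counts = {t: 0.0 for t in VALID_CELL_TYPES}
    for ch in layout.channels:
        for pop in ch.populations:
            counts[pop.cell_type] += pop.count
    return counts


def build_transwell(
    layout: ChipLayout,
    separation_mm: float = 0.9,
    well_area_cm2: float = 1.9,
) -> TranswellLayout:
    """Derive the volume- and cell-matched Transwell comparator from a chip.

    The total medium volume equals the chip's medium channels plus reservoirs;
    the well holds the liquid below the membrane (area x separation) with the
    tumor cells at its floor, and the insert holds the remainder with the
    bTME cells (astrocytes + bECs) at the membrane.
    """
    total_ul = layout.medium_volume_ul
    well_ul = well_area_cm2 * 1e-4 * separation_mm * 1e-3 * 1e9
    if well_ul >= total_ul:
        raise ConfigError(
            f"chip medium volume {total_ul:.1f} uL cannot fill a "
            f"{separation_mm} mm deep well of {well_area_cm2} cm^2"
        )
    counts = cell_counts(layout)
    insert_cells = {"astrocyte": counts["astrocyte"], "bEC": counts["bEC"]}
    well_cells = {"tumor": counts["tumor"]}
    return TranswellLayout(
        insert_volume_ul=total_ul - well_ul,
        well_volume_ul=well_ul,
        insert_cells=insert_cells,
        well_cells=well_cells,
        separation_mm=separation_mm,
        well_area_cm2=well_area_cm2,
    )
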