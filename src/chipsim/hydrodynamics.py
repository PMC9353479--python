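"""Hindered protein diffusion in collagen hydrogels.

Solute transport in the chip is diffusion dominated, so everything downstream
hinges on getting per-protein diffusion coefficients right.  Three small
empirical/physical relations are composed:

1. An effective hydrodynamic radius from molecular weight,
   ``r = 0.66 * M**(1/3)`` with ``M`` in Dalton and ``r`` in Angstrom.  This
   compact-globule scaling is the standard estimate when no measured Stokes
   radius is available.
2. The Stokes-Einstein free diffusivity in water,
   ``D_water = k_B * T / (6 * pi * mu * r)``.
3. An Ogston-type obstruction (hindrance) factor for a random fiber gel,
   ``D_gel / D_water = exp(-sqrt(phi) * r / r_f)``, where ``phi`` is the
   fiber volume fraction and ``r_f`` the fiber radius.  For 2 mg/mL type 1
   collagen (``phi = 0.125``, ``r_f = 200 nm``) the factor is close to 1 for
   proteins, i.e. collagen barely slows them down.

Units are deliberately explicit in every signature: molecular weight in Da,
radii in Angstrom, temperatures in K, viscosity in Pa*s, diffusivities in
m^2/s.  Mass/molar conversions for gel-dissolving enzyme solutions are also
housed here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import InvalidInputError

#: Boltzmann constant, J/K (CODATA, fixed by definition of the kelvin).
BOLTZMANN_J_PER_K = 1.380649e-23

#: Empirical prefactor of the radius-from-mass scaling, Angstrom/Da^(1/3).
RADIUS_PREFACTOR_A = 0.66

_A_TO_M = 1e-10
_A_TO_NM = 0.1


@dataclass(frozen=True)
class PhysicalConditions:
    """Temperature and solvent viscosity the Stokes-Einstein relation needs.

    Defaults are cell-culture conditions: 37 C and the dynamic viscosity of
    water near body temperature.
    """

    temperature_k: float = 310.15
    viscosity_pa_s: float = 8.9e-4

    def __post_init__(self) -> None:
        if self.temperature_k <= 0:
            raise InvalidInputError(f"temperature must be > 0 K, got {self.temperature_k}")
        if self.viscosity_pa_s <= 0:
            raise InvalidInputError(f"viscosity must be > 0 Pa*s, got {self.viscosity_pa_s}")


@dataclass(frozen=True)
class GelSpec:
    """Physical description of a fibrous hydrogel compartment.

    Parameters
    ----------
    volume_fraction : float
        Fiber volume fraction ``phi`` of the gel, in (0, 1).
    fiber_radius_nm : float
        Radius of the gel fibers (200 nm for type 1 collagen).
    permeability_m2 : float
        Darcy permeability of the gel, m^2.  1e-13 m^2 is typical for
        2 mg/mL collagen.
    collagen_density_mg_ml : float
        Bulk collagen concentration, for bookkeeping only.
    """

    volume_fraction: float = 0.125
    fiber_radius_nm: float = 200.0
    permeability_m2: float = 1e-13
    collagen_density_mg_ml: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.volume_fraction < 1:
            raise InvalidInputError(
                f"gel volume fraction must be in (0, 1), got {self.volume_fraction}"
            )
        if self.fiber_radius_nm <= 0:
            raise InvalidInputError(f"fiber radius must be > 0, got {self.fiber_radius_nm}")
        if self.permeability_m2 <= 0:
            raise InvalidInputError(f"permeability must be > 0, got {self.permeability_m2}")


@dataclass(frozen=True)
class ProteinSpec:
    """A solute species with its transport-relevant properties.

    ``secretion_rates`` maps a cell type (``"tumor"``, ``"astrocyte"``,
    ``"bEC"``) to a secreted amount per cell per day.  The rates are treated
    as *relative* source strengths (see the transport module); they only need
    to be mutually consistent within one solute.
    """

    name: str
    molecular_weight_da: float
    secretion_rates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.molecular_weight_da <= 0:
            raise InvalidInputError(
                f"molecular weight must be > 0 Da, got {self.molecular_weight_da}"
            )
        for cell_type, rate in self.secretion_rates.items():
            if rate < 0:
                raise InvalidInputError(f"secretion rate for {cell_type!r} is negative: {rate}")

    @property
    def effective_radius_a(self) -> float:
        """Effective hydrodynamic radius in Angstrom."""
        return effective_radius(self.molecular_weight_da)

    def diffusivity_water(self, conditions: PhysicalConditions | None = None) -> float:
        """Free diffusivity in water, m^2/s."""
        return free_diffusivity(self.effective_radius_a, conditions or PhysicalConditions())

    def diffusivity_gel(
        self, gel: GelSpec, conditions: PhysicalConditions | None = None
    ) -> float:
        """Hindered diffusivity inside ``gel``, m^2/s."""
        return self.diffusivity_water(conditions) * hindrance_factor(self.effective_radius_a, gel)


def effective_radius(molecular_weight_da: float) -> float:
    """Effective protein radius in Angstrom from molecular weight in Dalton.

    Uses the compact-globule scaling ``r = 0.66 * M**(1/3)``.

    >>> round(effective_radius(8_000), 1)   # an 8 kDa chemokine
    13.2
    """
    if molecular_weight_da <= 0:
        raise InvalidInputError(f"molecular weight must be > 0 Da, got {molecular_weight_da}")
    return RADIUS_PREFACTOR_A * molecular_weight_da ** (1.0 / 3.0)


def free_diffusivity(radius_a: float, conditions: PhysicalConditions | None = None) -> float:
    """Stokes-Einstein diffusivity in water, m^2/s, for a radius in Angstrom."""
    if radius_a <= 0:
        raise InvalidInputError(f"radius must be > 0 Angstrom, got {radius_a}")
    cond = conditions or PhysicalConditions()
    return BOLTZMANN_J_PER_K * cond.temperature_k / (
        6.0 * math.pi * cond.viscosity_pa_s * radius_a * _A_TO_M
    )


def hindrance_factor(radius_a: float, gel: GelSpec) -> float:
    """Ogston obstruction factor ``D_gel / D_water`` in (0, 1].

    ``exp(-sqrt(phi) * r / r_f)``; the solute radius is converted to the
    fiber-radius unit (nm) internally.
    """
    if radius_a <= 0:
        raise InvalidInputError(f"radius must be > 0 Angstrom, got {radius_a}")
    radius_nm = radius_a * _A_TO_NM
    return math.exp(-math.sqrt(gel.volume_fraction) * radius_nm / gel.fiber_radius_nm)


def mass_to_molar(concentration_mg_ml: float, molecular_weight_da: float) -> float:
    """Convert mg/mL to mol/m^3 for a solute of the given molecular weight.

    mg/mL equals kg/m^3, and ``M`` Da equals ``M / 1000`` kg/mol, so the
    conversion is ``1000 * c / M``.
    """
    if concentration_mg_ml <= 0:
        raise InvalidInputError(f"concentration must be > 0, got {concentration_mg_ml}")
    if molecular_weight_da <= 0:
        raise InvalidInputError(f"molecular weight must be > 0 Da, got {molecular_weight_da}")
    return 1000.0 * concentration_mg_ml / molecular_weight_da


def molar_to_mass(concentration_mol_m3: float, molecular_weight_da: float) -> float:
    """Inverse of :func:`mass_to_molar`; returns mg/mL."""
    if concentration_mol_m3 <= 0:
        raise InvalidInputError(f"concentration must be > 0, got {concentration_mol_m3}")
    if molecular_weight_da <= 0:
        raise InvalidInputError(f"molecular weight must be > 0 Da, got {molecular_weight_da}")
    return concentration_mol_m3 * molecular_weight_da / 1000.0
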