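"""Hydrostatic-head-driven interstitial flow through the astrocyte gel.

During selective gel extraction, the outer reservoirs are loaded with more
liquid (cold PBS) than the communication reservoirs (warm collagenase), and
the resulting head drives a transient Darcy flow from channel #1 across the
collagen in channel #2 into channel #3.  That flow is the protective element
of the extraction protocol: while it is faster than the enzyme's ability to
diffuse upstream, the astrocyte gel stays enzyme-free.

The drainage is modeled as a lumped first-order (RC) relaxation of the head:
``dV(t) = dV0 * exp(-t / tau)``, pressure from the head via the reservoir
port area, and the superficial gel velocity from Darcy's law
``u = kappa * dP / (mu * L)``.  The time constant is a calibrated lumped
parameter rather than being derived from the gel permeability alone, because
the physical device drains through the whole port/channel network, not just
the gel slab.  Reservoir liquid volumes are book-kept by integrating the
Darcy flux through the gel cross-section, so flux continuity between the
velocity history and the reservoir record holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .hydrodynamics import GelSpec, PhysicalConditions

WATER_DENSITY_KG_M3 = 1000.0
GRAVITY_M_S2 = 9.80665

#: Default lumped drainage time constant, s.  Chosen so the head has decayed
#: below 5% of its initial value (the equilibrium criterion) at 600 s.
DEFAULT_TAU_S = 200.0
#: Default reservoir port area, m^2 (a ~1.4 mm punched port).  Together with
#: a 60 uL head and kappa = 1e-13 m^2 this puts the initial gel velocity at
#: 4.0e-2 mm/s.
DEFAULT_RESERVOIR_AREA_M2 = 1.65e-6
#: Fraction of the initial pressure below which the head counts as equilibrated.
EQUILIBRIUM_FRACTION = 0.05


def darcy_velocity(
    pressure_difference_pa: float,
    gel: GelSpec,
    path_length_m: float,
    conditions: PhysicalConditions | None = None,
) -> float:
    """Superficial (plug-flow) velocity through the gel, m/s, signed like dP."""
    if path_length_m <= 0:
        raise InvalidInputError(f"path length must be > 0 m, got {path_length_m}")
    cond = conditions or PhysicalConditions()
    return gel.permeability_m2 * pressure_difference_pa / (cond.viscosity_pa_s * path_length_m)


@dataclass(frozen=True)
class FlowState:
    """Snapshot of the drainage at one time point."""

    time_s: float
    pressure_difference_pa: float
    darcy_velocity_m_s: float  # + means flow from channel #1 toward #3
    reservoir_volumes_ul: tuple[float, float]  # (outer #1, communication #3)


class FlowHistory:
    """Time series of the draining head with analytic evaluation helpers."""

    def __init__(
        self,
        times_s: np.ndarray,
        pressure_pa: np.ndarray,
        velocity_m_s: np.ndarray,
        volumes_outer_ul: np.ndarray,
        volumes_inner_ul: np.ndarray,
        tau_s: float,
        initial_pressure_pa: float,
        initial_velocity_m_s: float,
    ):
        self.times_s = times_s
        self.pressure_pa = pressure_pa
        self.velocity_m_s = velocity_m_s
        self.volumes_outer_ul = volumes_outer_ul
        self.volumes_inner_ul = volumes_inner_ul
        self.tau_s = tau_s
        self.initial_pressure_pa = initial_pressure_pa
        self.initial_velocity_m_s = initial_velocity_m_s

    def velocity_at(self, t_s: float) -> float:
        """Analytic velocity at an arbitrary time (exponential relaxation)."""
        if self.initial_velocity_m_s == 0.0 or self.tau_s <= 0:
            return 0.0
        if t_s < 0:
            return self.initial_velocity_m_s
        return self.initial_velocity_m_s * float(np.exp(-t_s / self.tau_s))

    @property
    def equilibrium_time_s(self) -> float | None:
        """First recorded time with dP below 5% of the initial head."""
        if self.initial_pressure_pa == 0.0:
            return 0.0
        below = np.nonzero(self.pressure_pa < EQUILIBRIUM_FRACTION * self.initial_pressure_pa)[0]
        return float(self.times_s[below[0]]) if below.size else None

    def at(self, t_s: float) -> FlowState:
        i = int(np.searchsorted(self.times_s, t_s))
        i = min(i, self.times_s.size - 1)
        return FlowState(
            time_s=float(self.times_s[i]),
            pressure_difference_pa=float(self.pressure_pa[i]),
            darcy_velocity_m_s=float(self.velocity_m_s[i]),
            reservoir_volumes_ul=(
                float(self.volumes_outer_ul[i]),
                float(self.volumes_inner_ul[i]),
            ),
        )

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "pressure_pa": self.pressure_pa,
                "velocity_m_s": self.velocity_m_s,
                "reservoir_outer_ul": self.volumes_outer_ul,
                "reservoir_inner_ul": self.volumes_inner_ul,
            }
        )


def drain_head(
    initial_volume_difference_ul: float = 60.0,
    hydraulic_time_constant_s: float = DEFAULT_TAU_S,
    duration_s: float = 1800.0,
    dt_s: float = 1.0,
    *,
    gel: GelSpec | None = None,
    conditions: PhysicalConditions | None = None,
    path_length_m: float = 1.0e-3,
    reservoir_area_m2: float = DEFAULT_RESERVOIR_AREA_M2,
    gel_cross_section_m2: float = 1.2e-6,
    reservoir_volumes_ul: tuple[float, float] = (120.0, 60.0),
) -> FlowHistory:
    """Simulate the exponential relaxation of the reservoir head.

    Parameters are the initial liquid-volume difference between the paired
    reservoirs, the lumped time constant, and the sampling grid.  A zero
    initial head yields an identically zero flow history (flow disabled).

    Returns a :class:`FlowHistory`; its ``equilibrium_time_s`` reports when
    the pressure difference first drops below 5% of its initial value.
    """
    if initial_volume_difference_ul < 0:
        raise InvalidInputError("initial volume difference must be >= 0")
    if duration_s <= 0 or dt_s <= 0:
        raise InvalidInputError("duration and dt must be > 0")
    if dt_s >= duration_s:
        raise InvalidInputError(f"dt ({dt_s} s) must be smaller than duration ({duration_s} s)")
    if hydraulic_time_constant_s <= 0 and initial_volume_difference_ul > 0:
        raise InvalidInputError("time constant must be > 0 for a non-zero head")

    gel = gel or GelSpec()
    cond = conditions or PhysicalConditions()

    times = np.arange(0.0, duration_s + 0.5 * dt_s, dt_s)
    if initial_volume_difference_ul == 0.0:
        zeros = np.zeros_like(times)
        v1 = np.full_like(times, reservoir_volumes_ul[0])
        v3 = np.full_like(times, reservoir_volumes_ul[1])
        return FlowHistory(times, zeros, zeros, v1, v3, hydraulic_time_constant_s, 0.0, 0.0)

    dp0 = (
        WATER_DENSITY_KG_M3
        * GRAVITY_M_S2
        * initial_volume_difference_ul
        * 1e-9
        / reservoir_area_m2
    )
    decay = np.exp(-times / hydraulic_time_constant_s)
    pressure = dp0 * decay
    u0 = darcy_velocity(dp0, gel, path_length_m, cond)
    velocity = u0 * decay

    # Liquid bookkeeping: the outer reservoir loses exactly the volume the
    # Darcy flux carries through the gel; the inner reservoir gains it.
    drained_m3 = u0 * gel_cross_section_m2 * hydraulic_time_constant_s * (1.0 - decay)
    drained_ul = drained_m3 * 1e9
    v1 = reservoir_volumes_ul[0] - drained_ul
    v3 = reservoir_volumes_ul[1] + drained_ul
    return FlowHistory(times, pressure, velocity, v1, v3, hydraulic_time_constant_s, dp0, u0)
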