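"""1-D finite-volume convection-diffusion-source solver for the chip cross-section.

The dominant concentration gradients in the device run *across* the channels
(solutes released in one channel and consumed/measured a few channels over),
so the domain is a 1-D chain of compartments in series: each channel is a
segment with its own diffusivity (free in medium, Ogston-hindered in gel).
The same machinery discretizes the vertical Transwell column.

Scheme
------
Explicit conservative finite volumes on (per-segment uniform) cells:

* diffusion: central differences with harmonic-mean interface diffusivity,
* advection: first-order upwind on the faces that lie on the interstitial
  flow path (outer channel -> astrocyte gel -> communication channel); the
  face where the flow path meets a stagnant compartment carries no advective
  flux, so solute swept along the path piles up against that interface and
  enters the stagnant gel by diffusion,
* cell sources: secretion rates spread uniformly over their compartment,
* reservoirs: each medium channel may carry a finite well-mixed reservoir
  exchanging with the channel through a lumped diffusive conductance
  (representing diffusion along the channel length to the ports).

The explicit step obeys ``dt <= 0.4 * min(dx^2 / (2 D), dx / |u|)``, which
also makes the update a convex combination of non-negative values, hence
positivity preserving.  Total amount (cells + reservoirs) is conserved to
round-off in a closed domain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, InvalidInputError, StabilityError

#: Safety factor applied to the explicit stability limit.
CFL_SAFETY = 0.4
#: Default grid resolution across the channels, um.
DEFAULT_DX_UM = 5.0


@dataclass(frozen=True)
class Segment:
    """A homogeneous stretch of the 1-D domain (one channel or column zone)."""

    label: str
    width_m: float
    diffusivity_m2_s: float

    def __post_init__(self) -> None:
        if self.width_m <= 0:
            raise InvalidInputError(f"segment {self.label!r} has non-positive width")
        if self.diffusivity_m2_s < 0:
            raise InvalidInputError(f"segment {self.label!r} has negative diffusivity")


@dataclass(frozen=True)
class SourceTerm:
    """Cells in one compartment secreting a solute at a per-cell rate.

    The rate is an amount per cell per day in whatever (possibly relative)
    unit the solute uses; the solver only requires linearity.
    """

    compartment: str
    cell_count: float
    rate_per_cell_per_day: float
    solute: str = ""

    def __post_init__(self) -> None:
        if self.rate_per_cell_per_day < 0:
            raise InvalidInputError("secretion rate must be >= 0")
        if self.cell_count < 0:
            raise InvalidInputError("cell count must be >= 0")

    @property
    def total_rate_per_s(self) -> float:
        return self.cell_count * self.rate_per_cell_per_day / 86400.0


@dataclass
class Reservoir:
    """Finite well-mixed liquid reservoir coupled to one medium compartment."""

    compartment: str
    volume_ul: float
    conductance_m3_s: float
    concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_ul <= 0:
            raise InvalidInputError("reservoir volume must be > 0")
        if self.conductance_m3_s < 0:
            raise InvalidInputError("reservoir conductance must be >= 0")


class Grid1D:
    """Cell-centered 1-D grid over a sequence of segments.

    Cells are uniform within a segment; a segment narrower than ``dx`` gets a
    single cell.  The transverse cross-section ``area_m2`` is uniform.
    """

    def __init__(self, segments: Sequence[Segment], area_m2: float, dx_m: float = DEFAULT_DX_UM * 1e-6):
        if area_m2 <= 0:
            raise InvalidInputError("grid cross-section area must be > 0")
        if dx_m <= 0:
            raise InvalidInputError("dx must be > 0")
        if not segments:
            raise ConfigError("grid needs at least one segment")
        labels = [s.label for s in segments]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"duplicate segment labels: {labels}")

        dx_list: list[np.ndarray] = []
        d_list: list[np.ndarray] = []
        self.slices: dict[str, slice] = {}
        start = 0
        for seg in segments:
            n = max(1, round(seg.width_m / dx_m))
            dx_list.append(np.full(n, seg.width_m / n))
            d_list.append(np.full(n, seg.diffusivity_m2_s))
            self.slices[seg.label] = slice(start, start + n)
            start += n

        self.segments = tuple(segments)
        self.area_m2 = float(area_m2)
        self.dx = np.concatenate(dx_list)
        self.diffusivity = np.concatenate(d_list)
        self.n = self.dx.size
        self.x = np.cumsum(self.dx) - 0.5 * self.dx
        self.cell_volumes_m3 = self.area_m2 * self.dx

    def segment_volume_m3(self, label: str) -> float:
        return float(self.cell_volumes_m3[self.slices[label]].sum())

    def labels(self) -> list[str]:
        return [s.label for s in self.segments]


@dataclass
class ConcentrationField:
    """Solute concentrations on the grid at one instant, plus reservoir state."""

    grid: Grid1D
    values: np.ndarray
    time_s: float = 0.0
    reservoirs: dict[str, Reservoir] = dataclass_field(default_factory=dict)

    @classmethod
    def uniform(cls, grid: Grid1D, value: float = 0.0) -> "ConcentrationField":
        return cls(grid, np.full(grid.n, float(value)))

    def set_segment(self, label: str, value: float) -> None:
        self.values[self.grid.slices[label]] = value

    def total_amount(self) -> float:
        """Total solute amount in the domain plus reservoirs (amount units)."""
        total = float(self.values @ self.grid.cell_volumes_m3)
        for res in self.reservoirs.values():
            total += res.concentration * res.volume_ul * 1e-9
        return total


def channel_mean(field: ConcentrationField, compartment: str) -> float:
    """Volume-weighted mean concentration over one compartment."""
    sl = field.grid.slices.get(compartment)
    if sl is None:
        raise ConfigError(f"unknown compartment {compartment!r}")
    v = field.grid.cell_volumes_m3[sl]
    return float((field.values[sl] @ v) / v.sum())


@dataclass
class SimulationRecord:
    """Sampled channel means (tidy on request) and the final field."""

    times_s: np.ndarray
    means: dict[str, np.ndarray]
    reservoir_concs: dict[str, np.ndarray]
    field: ConcentrationField
    solute: str = ""

    def mean_series(self, compartment: str) -> np.ndarray:
        return self.means[compartment]

    def as_dataframe(self) -> pd.DataFrame:
        frames = []
        for label, series in self.means.items():
            frames.append(
                pd.DataFrame(
                    {
                        "time_s": self.times_s,
                        "compartment": label,
                        "solute": self.solute,
                        "mean_conc": series,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


class TransportSolver:
    """Explicit FV integrator bound to one grid, one solute and one flow field.

    Parameters
    ----------
    grid : Grid1D
    velocity : callable ``t -> u`` or None
        Superficial velocity on the flow path, m/s (+ points toward higher x).
    flow_path : labels of the segments the flow traverses, in order.  Faces
        interior to and between these segments advect; all other faces are
        purely diffusive.
    sources : per-compartment secretion terms.
    reservoirs : finite well-mixed reservoirs coupled to compartments.
    fixed : mapping label -> concentration held constant (Dirichlet segments,
        used for analytic benchmarks; a fixed segment breaks closure).
    """

    def __init__(
        self,
        grid: Grid1D,
        *,
        velocity: Callable[[float], float] | None = None,
        flow_path: Sequence[str] = (),
        sources: Iterable[SourceTerm] = (),
        reservoirs: Iterable[Reservoir] = (),
        fixed: dict[str, float] | None = None,
        initial: ConcentrationField | None = None,
    ):
        self.grid = grid
        self.velocity = velocity
        self.field = initial if initial is not None else ConcentrationField.uniform(grid)
        if self.field.grid is not grid:
            raise ConfigError("initial field built on a different grid")

        n = grid.n
        # Interface conductances K_j = D_face / s_face (m/s), harmonic mean.
        dx, D = grid.dx, grid.diffusivity
        self._K = np.zeros(n + 1)
        with np.errstate(divide="ignore"):
            resist = 0.5 * dx[:-1] / np.where(D[:-1] > 0, D[:-1], np.inf) + 0.5 * dx[1:] / np.where(
                D[1:] > 0, D[1:], np.inf
            )
            self._K[1:-1] = np.where(
                np.isfinite(resist) & (resist > 0), 1.0 / resist, 0.0
            )

        # Faces carrying advection: interior to / between flow-path segments.
        path = list(flow_path)
        for label in path:
            if label not in grid.slices:
                raise ConfigError(f"flow path segment {label!r} not on the grid")
        in_path = np.zeros(n, dtype=bool)
        for label in path:
            in_path[grid.slices[label]] = True
        self._adv_face = np.zeros(n + 1)
        self._adv_face[1:-1] = (in_path[:-1] & in_path[1:]).astype(float)
        self._has_flow = velocity is not None and bool(self._adv_face.any())

        # Volumetric source density, amount / m^3 / s.
        self._q = np.zeros(n)
        for src in sources:
            if src.compartment not in grid.slices:
                raise ConfigError(f"source targets unknown compartment {src.compartment!r}")
            sl = grid.slices[src.compartment]
            self._q[sl] += src.total_rate_per_s / grid.segment_volume_m3(src.compartment)

        self._reservoirs: list[tuple[slice, float, Reservoir]] = []
        for res in reservoirs:
            if res.compartment not in grid.slices:
                raise ConfigError(f"reservoir attached to unknown compartment {res.compartment!r}")
            sl = grid.slices[res.compartment]
            self._reservoirs.append((sl, grid.segment_volume_m3(res.compartment), res))
            self.field.reservoirs[res.compartment] = res

        self._fixed_mask = np.zeros(n, dtype=bool)
        self._fixed_values = np.zeros(n)
        for label, value in (fixed or {}).items():
            sl = grid.slices[label]
            self._fixed_mask[sl] = True
            self._fixed_values[sl] = value
        self.field.values[self._fixed_mask] = self._fixed_values[self._fixed_mask]
        self._is_closed = not (fixed and len(fixed) > 0)

        self._dt_diff = CFL_SAFETY * float(np.min(dx**2 / (2.0 * np.maximum(D, 1e-300))))
        self._dx_min_path = float(dx[in_path].min()) if in_path.any() else float(dx.min())

    # -- stability ---------------------------------------------------------
    def suggested_dt(self, at_time: float | None = None) -> float:
        """Largest admissible explicit step at the given (default current) time."""
        dt = self._dt_diff
        if self._has_flow:
            u = abs(self.velocity(self.field.time_s if at_time is None else at_time))
            if u > 0:
                dt = min(dt, CFL_SAFETY * self._dx_min_path / u)
        return dt

    def _check_dt(self, dt: float) -> None:
        limit = self.suggested_dt()
        if dt > limit * (1.0 + 1e-9):
            raise StabilityError(
                f"dt = {dt:.3e} s violates the explicit stability contract; "
                f"use dt <= {limit:.3e} s",
                suggested_dt=limit,
            )

    # -- stepping ----------------------------------------------------------
    def step(self, dt: float) -> ConcentrationField:
        """Advance the field by one explicit step of size ``dt``."""
        self._check_dt(dt)
        self._advance(1, dt)
        return self.field

    def _advance(self, n_steps: int, dt: float) -> None:
        c = self.field.values
        n = self.grid.n
        Ki = self._K[1:-1]
        adv = self._adv_face[1:-1]
        has_flow = self._has_flow
        velocity = self.velocity
        fixed = bool(self._fixed_mask.any())
        q_dt = dt * self._q
        has_q = bool(self._q.any())
        inv_dx_dt = dt / self.grid.dx
        t = self.field.time_s
        # preallocated work buffers: interior face fluxes and the divergence
        fint = np.empty(n - 1)
        tmp = np.empty(n - 1)
        delta = np.empty(n)
        for _ in range(n_steps):
            if n > 1:
                # diffusive face flux (amount / m^2 / s), + means toward higher x
                np.subtract(c[:-1], c[1:], out=fint)
                fint *= Ki
                if has_flow:
                    u = velocity(t)
                    if u != 0.0:
                        np.multiply(adv, c[:-1] if u > 0 else c[1:], out=tmp)
                        tmp *= u
                        fint += tmp
                delta[0] = -fint[0]
                delta[-1] = fint[-1]
                np.subtract(fint[:-1], fint[1:], out=delta[1:-1])
                delta *= inv_dx_dt
                c += delta
            if has_q:
                c += q_dt
            for sl, v_seg, res in self._reservoirs:
                if res.conductance_m3_s > 0.0:
                    xfer = res.conductance_m3_s * (res.concentration - c[sl].mean())
                    c[sl] += dt * xfer / v_seg
                    res.concentration -= dt * xfer / (res.volume_ul * 1e-9)
            if fixed:
                c[self._fixed_mask] = self._fixed_values[self._fixed_mask]
            t += dt
        self.field.time_s = t

    # -- high-level driver -------------------------------------------------
    def run(
        self,
        duration_s: float,
        *,
        dt: float | None = None,
        sample_interval_s: float | None = None,
        record: Sequence[str] | None = None,
        stop_when: Callable[[float, dict[str, float]], bool] | None = None,
        solute: str = "",
    ) -> SimulationRecord:
        """Integrate for ``duration_s``, sampling compartment means.

        ``stop_when(time, means)`` is evaluated at each sample; returning True
        ends the run early (the triggering sample is kept).
        """
        if duration_s <= 0:
            raise InvalidInputError("duration must be > 0")
        if dt is None:
            dt = self.suggested_dt()
        else:
            self._check_dt(dt)
        labels = list(record) if record is not None else self.grid.labels()
        interval = sample_interval_s if sample_interval_s else duration_s
        steps_per_sample = max(1, int(math.ceil(interval / dt)))
        t_end = self.field.time_s + duration_s

        times: list[float] = []
        means: dict[str, list[float]] = {lab: [] for lab in labels}
        res_concs: dict[str, list[float]] = {r.compartment: [] for _, _, r in self._reservoirs}

        def take_sample() -> dict[str, float]:
            times.append(self.field.time_s)
            sample = {}
            for lab in labels:
                sample[lab] = channel_mean(self.field, lab)
                means[lab].append(sample[lab])
            for _, _, res in self._reservoirs:
                res_concs[res.compartment].append(res.concentration)
            return sample

        sample = take_sample()
        if not (stop_when and stop_when(self.field.time_s, sample)):
            while self.field.time_s < t_end - 1e-9:
                remaining = t_end - self.field.time_s
                n_steps = min(steps_per_sample, int(math.ceil(remaining / dt - 1e-9)))
                self._advance(n_steps, dt)
                sample = take_sample()
                if stop_when and stop_when(self.field.time_s, sample):
                    break

        return SimulationRecord(
            times_s=np.asarray(times),
            means={lab: np.asarray(v) for lab, v in means.items()},
            reservoir_concs={lab: np.asarray(v) for lab, v in res_concs.items()},
            field=self.field,
            solute=solute,
        )


def step(
    field: ConcentrationField,
    dt: float,
    *,
    velocity: Callable[[float], float] | None = None,
    flow_path: Sequence[str] = (),
    sources: Iterable[SourceTerm] = (),
) -> ConcentrationField:
    """One-shot functional step for small experiments.

    Builds a transient solver around ``field`` and advances it once; for long
    runs construct a :class:`TransportSolver` and reuse it.
    """
    solver = TransportSolver(
        field.grid,
        velocity=velocity,
        flow_path=flow_path,
        sources=sources,
        reservoirs=field.reservoirs.values(),
        initial=field,
    )
    return solver.step(dt)


def simulate(
    grid: Grid1D,
    duration_s: float,
    *,
    initial: ConcentrationField | None = None,
    velocity: Callable[[float], float] | None = None,
    flow_path: Sequence[str] = (),
    sources: Iterable[SourceTerm] = (),
    reservoirs: Iterable[Reservoir] = (),
    fixed: dict[str, float] | None = None,
    dt: float | None = None,
    sample_interval_s: float | None = None,
    stop_when: Callable[[float, dict[str, float]], bool] | None = None,
    solute: str = "",
) -> SimulationRecord:
    """Convenience wrapper: build a solver and run it for ``duration_s``."""
    solver = TransportSolver(
        grid,
        velocity=velocity,
        flow_path=flow_path,
        sources=sources,
        reservoirs=reservoirs,
        fixed=fixed,
        initial=initial,
    )
    return solver.run(
        duration_s,
        dt=dt,
        sample_interval_s=sample_interval_s,
        stop_when=stop_when,
        solute=solute,
    )
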