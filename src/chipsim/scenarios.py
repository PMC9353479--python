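"""Turn-key reproductions of the chip's two transport experiments.

* :func:`run_collagenase_extraction` — selective gel dissolution: collagenase
  loaded in the communication channels while a transient hydrostatic flow
  from the outer channels protects the astrocyte gel (#2); reports when the
  enzyme reaches #2, how long the tumor gel (#4) sits inside the activating
  concentration window, and the head equilibrium time.

* :func:`run_cytokine_enrichment` — 24 h of paracrine secretion from the
  bTME compartments, run in both the chip cross-section and the
  volume/cell-matched Transwell column; reports the tumor-side concentration
  in each geometry and their ratio (the microscale enrichment factor).

Cytokine secretion rates are *relative* source strengths, so all ratio-type
outputs are independent of the unknown absolute scale; absolute cytokine
concentrations are reported in the same arbitrary unit per solute.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import transport
from .chip_model import (
    ChipLayout,
    TranswellLayout,
    build_chip,
    build_transwell,
    cell_counts,
)
from .config import RunConfig
from .errors import ConfigError, InvalidInputError
from .flow import drain_head
from .hydrodynamics import GelSpec, PhysicalConditions, ProteinSpec
from .transport import ConcentrationField, Grid1D, Reservoir, Segment, SourceTerm, TransportSolver

logger = logging.getLogger(__name__)

#: Reference convective velocity above which collagenase cannot diffuse
#: upstream through the gel (stored constant, compared against, never
#: re-derived), mm/s.
PROTECTIVE_VELOCITY_MM_S = 3.95e-2

#: Solute registry.  Secretion rates are per-cell-per-day relative strengths
#: (endothelial and astrocyte values drive the bTME sources; the tumor value
#: is the adenocarcinoma line and is unused by the delivery scenarios).
PROTEINS: dict[str, ProteinSpec] = {
    "collagenase": ProteinSpec("collagenase", 100_000.0),
    "serpin E1": ProteinSpec(
        "serpin E1", 44_000.0, {"bEC": 1.92, "astrocyte": 0.975, "tumor": 0.673}
    ),
    "IL-8": ProteinSpec("IL-8", 8_000.0, {"bEC": 64.0, "astrocyte": 93.12, "tumor": 221.0}),
    "SPP-1": ProteinSpec("SPP-1", 32_900.0),
}


@dataclass
class ProtectionResult:
    protected: bool
    peclet: float


@dataclass
class ScenarioResult:
    """Metrics + full time series + the exact config snapshot that made them."""

    scenario: str
    metrics: dict
    timeseries: pd.DataFrame
    config: dict

    def to_dir(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "metrics.json").write_text(
            json.dumps(self.metrics, indent=2, sort_keys=True) + "\n"
        )
        self.timeseries.to_csv(out / "timeseries.csv", index=False)
        (out / "config.json").write_text(json.dumps(self.config, indent=2, sort_keys=True) + "\n")
        return out


# --------------------------------------------------------------------------
# shared plumbing
# --------------------------------------------------------------------------

def _layout_from_config(cfg: RunConfig) -> ChipLayout:
    return build_chip(
        {
            "medium_channel_width_um": cfg.geometry.medium_channel_width_um,
            "gel_channel_width_um": cfg.geometry.gel_channel_width_um,
            "height_um": cfg.geometry.height_um,
            "length_mm": cfg.geometry.length_mm,
            "reservoir_volume_ul": cfg.geometry.reservoir_volume_ul,
            "gel": GelSpec(**cfg.gel.model_dump()),
            "gel_cell_density_per_ml": cfg.geometry.gel_cell_density_per_ml,
            "bec_suspension_per_ml": cfg.geometry.bec_suspension_per_ml,
            "bec_seed_volume_ul": cfg.geometry.bec_seed_volume_ul,
        }
    )


def _half_chip_grid(
    layout: ChipLayout, d_medium: float, d_gel: float, dx_um: float
) -> Grid1D:
    """Half cross-section (#1..#3 plus half of #4) with a symmetry boundary."""
    ch = [layout.compartment(i) for i in (1, 2, 3, 4)]
    segments = [
        Segment("1", ch[0].width_m, d_medium),
        Segment("2", ch[1].width_m, d_gel),
        Segment("3", ch[2].width_m, d_medium),
        Segment("4", 0.5 * ch[3].width_m, d_gel),
    ]
    return Grid1D(segments, area_m2=ch[0].cross_section_m2, dx_m=dx_um * 1e-6)


def _port_conductance(layout: ChipLayout, channel: int, d_medium: float) -> float:
    """Lumped channel<->reservoir diffusive conductance, m^3/s.

    Exchange runs lengthwise from the channel midsection to the ports, so the
    conductance is D times the channel cross-section over half the culture
    length.  It is small: the reservoirs are nearly decoupled on the hour
    scale, which is exactly the microscale-confinement effect.
    """
    ch = layout.compartment(channel)
    lengthwise_area = ch.width_um * 1e-6 * ch.height_um * 1e-6
    return d_medium * lengthwise_area / (0.5 * ch.length_mm * 1e-3)


def _first_crossing(
    times: np.ndarray, series: np.ndarray, threshold: float
) -> float | None:
    above = np.nonzero(series > threshold)[0]
    return float(times[above[0]]) if above.size else None


# --------------------------------------------------------------------------
# scenario A: selective collagenase extraction
# --------------------------------------------------------------------------

def run_collagenase_extraction(
    config: RunConfig | None = None, *, flow_enabled: bool = True
) -> ScenarioResult:
    """Simulate the protected enzyme-extraction protocol.

    Collagenase (at the configured load) fills channel #3 and its reservoir;
    cold PBS in the outer reservoir drives the protective interstitial flow
    #1 -> #3 across the astrocyte gel while the head drains.  Concentrations
    are tracked in mg/mL.  ``flow_enabled=False`` reruns the identical setup
    with a zero head (the unprotected control).
    """
    cfg = config or RunConfig()
    sc = cfg.collagenase
    layout = _layout_from_config(cfg)
    conditions = PhysicalConditions(**cfg.conditions.model_dump())
    gel = GelSpec(**cfg.gel.model_dump())

    gel_ch = layout.compartment(2)
    history = drain_head(
        cfg.flow.initial_head_ul if flow_enabled else 0.0,
        cfg.flow.tau_s,
        duration_s=sc.duration_s,
        dt_s=1.0,
        gel=gel,
        conditions=conditions,
        path_length_m=gel_ch.width_m,
        reservoir_area_m2=cfg.flow.reservoir_area_m2,
        gel_cross_section_m2=gel_ch.cross_section_m2,
        reservoir_volumes_ul=(sc.pbs_reservoir_ul, sc.collagenase_reservoir_ul),
    )

    grid = _half_chip_grid(layout, sc.d_medium_m2_s, sc.d_gel_m2_s, cfg.geometry.dx_um)
    field = ConcentrationField.uniform(grid, 0.0)
    field.set_segment("3", sc.load_mg_ml)
    reservoirs = [
        Reservoir("1", sc.pbs_reservoir_ul, _port_conductance(layout, 1, sc.d_medium_m2_s), 0.0),
        Reservoir(
            "3",
            sc.collagenase_reservoir_ul,
            _port_conductance(layout, 3, sc.d_medium_m2_s),
            sc.load_mg_ml,
        ),
    ]
    solver = TransportSolver(
        grid,
        velocity=history.velocity_at,
        flow_path=("1", "2", "3"),
        reservoirs=reservoirs,
        initial=field,
    )
    record = solver.run(
        sc.duration_s, sample_interval_s=sc.sample_interval_s, solute="collagenase"
    )

    times = record.times_s
    c2 = record.mean_series("2")
    c4 = record.mean_series("4")
    c0 = sc.load_mg_ml

    metrics: dict = {
        "initial_load_mg_ml": c0,
        "flow_enabled": flow_enabled,
        "equilibrium_time_s": history.equilibrium_time_s,
        "initial_velocity_mm_s": history.initial_velocity_m_s * 1e3,
        "duration_s": sc.duration_s,
    }

    if c0 <= 0.0:
        logger.warning("collagenase load is zero: reach/window metrics are undefined")
        metrics.update(
            {
                "channel2_arrival_s": None,
                "channel2_crossed": False,
                "window_entry_s": None,
                "window_duration_s": 0.0,
                "peak_channel4_mg_ml": 0.0,
                "channel2_exposure_mg_s_ml": 0.0,
            }
        )
    else:
        # Sensitivity of the "reach" call to the threshold convention.
        for frac in (0.005, sc.reach_threshold_fraction, 0.05):
            arrival = _first_crossing(times, c2, frac * c0)
            logger.info(
                "channel #2 arrival at %.1f%% threshold: %s s",
                100 * frac,
                "none within run" if arrival is None else f"{arrival:.0f}",
            )
        arrival = _first_crossing(times, c2, sc.reach_threshold_fraction * c0)
        in_window = (c4 >= sc.activation_min_mg_ml) & (c4 <= sc.activation_max_mg_ml)
        window_duration = float(in_window.sum()) * sc.sample_interval_s
        entry_idx = np.nonzero(in_window)[0]
        if window_duration == 0.0:
            logger.warning("channel #4 never entered the activating window")
        metrics.update(
            {
                # no crossing within the run => the run length is a lower bound
                "channel2_arrival_s": sc.duration_s if arrival is None else arrival,
                "channel2_crossed": arrival is not None,
                "window_entry_s": None if not entry_idx.size else float(times[entry_idx[0]]),
                "window_duration_s": window_duration,
                "peak_channel4_mg_ml": float(c4.max()),
                "channel2_exposure_mg_s_ml": float(np.trapezoid(c2, times)),
            }
        )

    ts = record.as_dataframe()
    return ScenarioResult(
        scenario="collagenase_extraction",
        metrics=metrics,
        timeseries=ts,
        config=cfg.snapshot() | {"flow_enabled": flow_enabled},
    )


# --------------------------------------------------------------------------
# scenario B: cytokine secretion, chip vs Transwell
# --------------------------------------------------------------------------

def _chip_secretion_run(
    cfg: RunConfig,
    layout: ChipLayout,
    protein: ProteinSpec,
    conditions: PhysicalConditions,
    gel: GelSpec,
    duration_s: float,
) -> transport.SimulationRecord:
    d_water = protein.diffusivity_water(conditions)
    d_gel = protein.diffusivity_gel(gel, conditions)
    grid = _half_chip_grid(layout, d_water, d_gel, cfg.geometry.dx_um)

    def pop_count(channel: int, cell_type: str) -> float:
        return sum(
            p.count for p in layout.compartment(channel).populations if p.cell_type == cell_type
        )

    sources = [
        SourceTerm("1", pop_count(1, "bEC"), protein.secretion_rates["bEC"], protein.name),
        SourceTerm(
            "2", pop_count(2, "astrocyte"), protein.secretion_rates["astrocyte"], protein.name
        ),
    ]
    reservoirs = [
        Reservoir("1", cfg.geometry.reservoir_volume_ul, _port_conductance(layout, 1, d_water)),
        Reservoir("3", cfg.geometry.reservoir_volume_ul, _port_conductance(layout, 3, d_water)),
    ]
    return transport.simulate(
        grid,
        duration_s,
        sources=sources,
        reservoirs=reservoirs,
        sample_interval_s=cfg.cytokine.sample_interval_s,
        solute=protein.name,
    )


def _transwell_secretion_run(
    cfg: RunConfig,
    transwell: TranswellLayout,
    protein: ProteinSpec,
    conditions: PhysicalConditions,
    duration_s: float,
) -> transport.SimulationRecord:
    d_water = protein.diffusivity_water(conditions)
    area = transwell.well_area_cm2 * 1e-4
    tumor_zone_m = cfg.cytokine.tumor_zone_um * 1e-6
    sep_m = transwell.separation_mm * 1e-3
    insert_height_m = transwell.insert_volume_ul * 1e-9 / area
    floor_m = min(50e-6, 0.5 * insert_height_m)
    segments = [
        Segment("tumor_zone", tumor_zone_m, d_water),
        Segment("well", sep_m - tumor_zone_m, d_water),
        Segment("insert_floor", floor_m, d_water),
        Segment("insert_bulk", insert_height_m - floor_m, d_water),
    ]
    grid = Grid1D(segments, area_m2=area, dx_m=cfg.geometry.dx_um * 1e-6)
    sources = [
        SourceTerm(
            "insert_floor",
            transwell.insert_cells.get("bEC", 0.0),
            protein.secretion_rates["bEC"],
            protein.name,
        ),
        SourceTerm(
            "insert_floor",
            transwell.insert_cells.get("astrocyte", 0.0),
            protein.secretion_rates["astrocyte"],
            protein.name,
        ),
    ]
    return transport.simulate(
        grid,
        duration_s,
        sources=sources,
        sample_interval_s=cfg.cytokine.sample_interval_s,
        solute=protein.name,
    )


def run_cytokine_enrichment(
    config: RunConfig | None = None,
    *,
    transwell: TranswellLayout | None = None,
) -> ScenarioResult:
    """24 h bTME secretion in the chip and the matched Transwell.

    For every configured solute, reports the tumor-compartment concentration
    in both geometries, the chip/Transwell enrichment ratio, and the time at
    which the solute first reaches the tumor gel (channel #4 mean exceeding
    the configured fraction of the concurrent astrocyte-channel mean).
    """
    cfg = config or RunConfig()
    layout = _layout_from_config(cfg)
    conditions = PhysicalConditions(**cfg.conditions.model_dump())
    gel = GelSpec(**cfg.gel.model_dump())
    if transwell is None:
        transwell = build_transwell(
            layout, cfg.cytokine.separation_mm, cfg.cytokine.well_area_cm2
        )
    chip_counts = cell_counts(layout)
    if transwell.cell_counts() != chip_counts:
        raise ConfigError(
            f"cell counts differ between geometries: chip {chip_counts}, "
            f"Transwell {transwell.cell_counts()}"
        )

    duration_s = cfg.cytokine.duration_h * 3600.0
    metrics: dict = {
        "duration_h": cfg.cytokine.duration_h,
        "transwell_total_volume_ul": transwell.total_volume_ul,
        "chip_medium_volume_ul": layout.medium_volume_ul,
        "solutes": {},
    }
    frames = []
    for name in cfg.cytokine.solutes:
        if name not in PROTEINS:
            raise ConfigError(f"unknown solute {name!r}; known: {sorted(PROTEINS)}")
        protein = PROTEINS[name]
        if not protein.secretion_rates:
            raise ConfigError(f"solute {name!r} has no secretion rates")

        chip_rec = _chip_secretion_run(cfg, layout, protein, conditions, gel, duration_s)
        tw_rec = _transwell_secretion_run(cfg, transwell, protein, conditions, duration_s)

        c4 = chip_rec.mean_series("4")
        c2 = chip_rec.mean_series("2")
        thr = cfg.cytokine.arrival_threshold_fraction
        reached = np.nonzero((c2 > 0) & (c4 > thr * c2))[0]
        arrival_h = float(chip_rec.times_s[reached[0]]) / 3600.0 if reached.size else None

        chip_conc = float(c4[-1])
        tw_conc = float(tw_rec.mean_series("tumor_zone")[-1])
        metrics["solutes"][name] = {
            "molecular_weight_da": protein.molecular_weight_da,
            "chip_tumor_conc": chip_conc,
            "transwell_tumor_conc": tw_conc,
            "enrichment_ratio": chip_conc / tw_conc if tw_conc > 0 else None,
            "tumor_arrival_h": arrival_h,
        }
        for rec, geom in ((chip_rec, "chip"), (tw_rec, "transwell")):
            df = rec.as_dataframe()
            df["geometry"] = geom
            frames.append(df)

    return ScenarioResult(
        scenario="cytokine_enrichment",
        metrics=metrics,
        timeseries=pd.concat(frames, ignore_index=True),
        config=cfg.snapshot(),
    )


# --------------------------------------------------------------------------
# protection criterion
# --------------------------------------------------------------------------

def protection_criterion(
    flow_velocity_m_s: float,
    gel: GelSpec,
    solute: ProteinSpec,
    path_length_m: float,
    conditions: PhysicalConditions | None = None,
) -> ProtectionResult:
    """Is a gel slab protected from upstream solute diffusion by this flow?

    Protection is judged against the stored reference velocity threshold
    (3.95e-2 mm/s); the Peclet number ``u L / D_gel`` is reported alongside
    for transparency.
    """
    if path_length_m <= 0:
        raise InvalidInputError("path length must be > 0")
    d_gel = solute.diffusivity_gel(gel, conditions)
    peclet = flow_velocity_m_s * path_length_m / d_gel
    return ProtectionResult(
        protected=flow_velocity_m_s >= PROTECTIVE_VELOCITY_MM_S * 1e-3,
        peclet=peclet,
    )
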