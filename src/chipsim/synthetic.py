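"""Seed-deterministic synthetic inputs with known ground truth.

Every table the assay estimators consume can be generated here with its true
parameters stored alongside, so each stage of the pipeline is testable
end-to-end without any external data:

* live/dead ROI count tables (Poisson cells per ROI, Binomial live calls),
* Luminex-style endpoint concentration tables produced by the forward
  well-mixed accumulation model plus multiplicative lognormal noise and the
  twofold assay-dilution bookkeeping,
* Hill-curve dose-response viability tables with additive Gaussian noise,
* device QC outcome lists (Bernoulli successes).

Noise models are stated conventions of the generator, chosen as the standard
choices for count, concentration and viability data respectively.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import LUMINEX_BASELINES_PG_ML, hill_curve
from .errors import InvalidInputError

#: Default dose ladder: 6 log-spaced segments spanning 0.04-10 uM.
DEFAULT_DOSES_UM = tuple(np.geomspace(0.04, 10.0, 6).round(4))


@dataclass(frozen=True)
class GroundTruth:
    """True generating parameters stored as a sidecar next to each dataset."""

    seed: int
    viability: dict[str, float] = field(default_factory=dict)
    secretion_rates_pg_cell_day: dict[str, float] = field(default_factory=dict)
    dose_response: dict[str, dict[str, float]] = field(default_factory=dict)
    success_probability: float | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def gen_live_dead(
    n_roi: int,
    true_viability: float,
    mean_cells_per_roi: float = 200.0,
    seed: int = 0,
    condition: str = "bTME+",
) -> tuple[pd.DataFrame, GroundTruth]:
    """ROI live/dead counts: total ~ Poisson(mean), live ~ Binomial(total, v)."""
    if not 0.0 <= true_viability <= 1.0:
        raise InvalidInputError(f"viability must be in [0, 1], got {true_viability}")
    if n_roi <= 0 or mean_cells_per_roi <= 0:
        raise InvalidInputError("n_roi and mean_cells_per_roi must be > 0")
    rng = np.random.default_rng(seed)
    totals = rng.poisson(mean_cells_per_roi, size=n_roi)
    totals = np.maximum(totals, 1)  # an ROI with zero cells is not a valid record
    live = rng.binomial(totals, true_viability)
    table = pd.DataFrame(
        {
            "roi_id": [f"roi{i:03d}" for i in range(n_roi)],
            "condition": condition,
            "live": live,
            "dead": totals - live,
        }
    )
    truth = GroundTruth(seed=seed, viability={condition: true_viability})
    return table, truth


def gen_endpoint_concentrations(
    true_rates_pg_cell_day: dict[str, float],
    noise_cv: float = 0.05,
    n_chips: int = 3,
    seed: int = 0,
    *,
    cells: float = 2.0e4,
    volume_ul: float = 120.0,
    duration_days: float = 1.0,
    dilution_factor: float = 2.0,
    baselines_pg_ml: dict[str, float] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Forward well-mixed endpoint concentrations with lognormal noise.

    The supernatant concentration after ``duration_days`` of secretion into a
    well-mixed volume is ``baseline + rate * cells * duration / V``; the
    reported value is that endpoint after the assay's twofold dilution, with
    a unit-mean multiplicative lognormal error of the given CV.
    """
    if noise_cv < 0:
        raise InvalidInputError("noise CV must be >= 0")
    if n_chips <= 0:
        raise InvalidInputError("need at least one chip")
    baselines = dict(LUMINEX_BASELINES_PG_ML if baselines_pg_ml is None else baselines_pg_ml)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    rows = []
    for solute, rate in true_rates_pg_cell_day.items():
        baseline = baselines.get(solute, 0.0)
        endpoint = baseline + rate * cells * duration_days / (volume_ul * 1e-3)
        for chip in range(n_chips):
            noise = float(np.exp(rng.normal(-0.5 * sigma**2, sigma))) if noise_cv > 0 else 1.0
            rows.append(
                {
                    "chip_id": f"chip{chip + 1}",
                    "solute": solute,
                    "measured_pg_ml": endpoint * noise / dilution_factor,
                    "dilution_factor": dilution_factor,
                    "baseline_pg_ml": baseline,
                    "volume_ul": volume_ul,
                    "cells": cells,
                    "duration_days": duration_days,
                }
            )
    truth = GroundTruth(seed=seed, secretion_rates_pg_cell_day=dict(true_rates_pg_cell_day))
    return pd.DataFrame(rows), truth


def gen_dose_response(
    floor: float = 0.1,
    ceiling: float = 0.95,
    ic50_um: float = 1.0,
    slope: float = 1.5,
    doses_um: tuple[float, ...] = DEFAULT_DOSES_UM,
    replicates: int = 8,
    noise_sd: float = 0.05,
    seed: int = 0,
    drug: str = "drugA",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Hill-curve viability table with Gaussian noise, plus DMSO controls.

    Viability is ``floor + (ceiling - floor) / (1 + (dose/IC50)^slope)`` plus
    N(0, noise_sd), truncated to [0, 1]; controls are draws around the
    ceiling (no drug).
    """
    if not (0 <= floor < ceiling <= 1.0 + 1e-9):
        raise InvalidInputError("need 0 <= floor < ceiling <= 1")
    if ic50_um <= 0 or slope <= 0:
        raise InvalidInputError("IC50 and slope must be > 0")
    if replicates < 1:
        raise InvalidInputError("need at least one replicate")
    doses = np.asarray(doses_um, dtype=float)
    if not np.all(np.diff(doses) > 0):
        raise InvalidInputError("doses must be strictly increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        v_ctrl = np.clip(ceiling + rng.normal(0.0, noise_sd), 0.0, 1.0)
        rows.append(
            {"drug": drug, "dose_um": np.nan, "replicate": rep, "viability": v_ctrl,
             "is_control": True}
        )
        for dose in doses:
            v = hill_curve(dose, floor, ceiling, ic50_um, slope) + rng.normal(0.0, noise_sd)
            rows.append(
                {"drug": drug, "dose_um": dose, "replicate": rep,
                 "viability": float(np.clip(v, 0.0, 1.0)), "is_control": False}
            )
    truth = GroundTruth(
        seed=seed,
        dose_response={
            drug: {"floor": floor, "ceiling": ceiling, "ic50_um": ic50_um, "slope": slope}
        },
    )
    return pd.DataFrame(rows), truth


def gen_device_outcomes(
    n_devices: int = 31, success_probability: float = 0.8, seed: int = 0
) -> tuple[pd.DataFrame, GroundTruth]:
    """Bernoulli success/failure outcome list for extraction QC."""
    if n_devices <= 0:
        raise InvalidInputError("need at least one device")
    if not 0.0 <= success_probability <= 1.0:
        raise InvalidInputError("success probability must be in [0, 1]")
    rng = np.random.default_rng(seed)
    outcomes = rng.random(n_devices) < success_probability
    table = pd.DataFrame(
        {"device_id": [f"dev{i:02d}" for i in range(n_devices)], "success": outcomes}
    )
    truth = GroundTruth(seed=seed, success_probability=success_probability)
    return table, truth
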