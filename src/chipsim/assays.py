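"""Quantification arithmetic for the chip's wet-lab readouts.

Four small estimators, each fed by a documented CSV schema:

viability
    live / (live + dead) per imaging region of interest (ROI), aggregated as
    the mean of per-ROI viabilities +/- SEM (not pooled counts).
    CSV columns: ``roi_id, condition, live, dead``.

extraction QC
    device success percentage with a Wilson binomial interval.

dose-response
    per-replicate viabilities normalized to the mean of the vehicle (DMSO)
    control, summarized per dose as mean +/- SEM.  A 4-parameter logistic
    (Hill) fit is available for recovery experiments on synthetic tables.
    CSV columns: ``drug, dose_um, replicate, viability, is_control``
    (control rows have ``is_control = True`` and no dose).

secretion-rate estimation
    back-calculation of a per-cell secretion rate from an endpoint
    supernatant concentration in the well-mixed single-compartment
    approximation: ``rate = (endpoint - baseline) * V / (cells * duration)``.
    Rates below zero are flagged as net consumption (observed for SPP-1),
    never silently clipped.
    CSV columns: ``chip_id, solute, measured_pg_ml, dilution_factor,
    baseline_pg_ml, volume_ul, cells, duration_days``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .errors import InvalidInputError

VIABILITY_COLUMNS = ["roi_id", "condition", "live", "dead"]
DOSE_COLUMNS = ["drug", "dose_um", "replicate", "viability", "is_control"]
LUMINEX_COLUMNS = [
    "chip_id", "solute", "measured_pg_ml", "dilution_factor",
    "baseline_pg_ml", "volume_ul", "cells", "duration_days",
]

#: Neurobasal-medium normalization baselines, pg/mL.
LUMINEX_BASELINES_PG_ML = {"serpin E1": 2.21, "IL-8": 3.6, "SPP-1": 5244.72}


@dataclass(frozen=True)
class ViabilityRecord:
    roi_id: str
    live: int
    dead: int
    condition: str = ""

    def __post_init__(self) -> None:
        if self.live < 0 or self.dead < 0:
            raise InvalidInputError("cell counts must be >= 0")
        if self.live + self.dead == 0:
            raise InvalidInputError(f"ROI {self.roi_id!r} has no cells")

    @property
    def viability(self) -> float:
        return viability(self.live, self.dead)


def viability(live: float, dead: float) -> float:
    """Fraction of live cells among all stained cells, in [0, 1]."""
    if live < 0 or dead < 0:
        raise InvalidInputError("cell counts must be >= 0")
    total = live + dead
    if total <= 0:
        raise InvalidInputError("live + dead must be > 0 for a valid record")
    return live / total


def summarize_viability(table: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SEM of per-ROI viabilities, grouped by condition."""
    missing = set(VIABILITY_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidInputError(f"viability table missing columns: {sorted(missing)}")
    per_roi = table.assign(
        viability=[viability(lv, dd) for lv, dd in zip(table["live"], table["dead"])]
    )
    grouped = per_roi.groupby("condition")["viability"]
    out = grouped.agg(
        mean_viability="mean",
        sem_viability=lambda v: stats.sem(v) if len(v) > 1 else 0.0,
        n_roi="count",
    )
    return out.reset_index()


@dataclass(frozen=True)
class ExtractionQC:
    """Device-level success statistics for the selective extraction protocol."""

    successes: int
    devices: int
    rate_percent: float
    wilson_low_percent: float
    wilson_high_percent: float


def extraction_success_rate(successes: int, devices: int, alpha: float = 0.05) -> ExtractionQC:
    """Success percentage with a Wilson score interval."""
    if devices <= 0:
        raise InvalidInputError("device count must be > 0")
    if not 0 <= successes <= devices:
        raise InvalidInputError(f"successes ({successes}) must be in [0, {devices}]")
    low, high = proportion_confint(successes, devices, alpha=alpha, method="wilson")
    return ExtractionQC(
        successes=successes,
        devices=devices,
        rate_percent=100.0 * successes / devices,
        wilson_low_percent=100.0 * float(low),
        wilson_high_percent=100.0 * float(high),
    )


def normalize_dose_response(table: pd.DataFrame) -> pd.DataFrame:
    """Divide every replicate by the DMSO-control mean; summarize per dose.

    Returns a frame with ``drug, dose_um, mean_viability, sem_viability, n``
    where viabilities are fractions of the vehicle control.
    """
    missing = set(DOSE_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidInputError(f"dose-response table missing columns: {sorted(missing)}")
    results = []
    for drug, sub in table.groupby("drug", sort=True):
        controls = sub.loc[sub["is_control"].astype(bool), "viability"]
        if controls.empty:
            raise InvalidInputError(f"no DMSO control rows for drug {drug!r}")
        control_mean = float(controls.mean())
        if control_mean <= 0:
            raise InvalidInputError(f"DMSO control viability for {drug!r} is not positive")
        treated = sub.loc[~sub["is_control"].astype(bool)].copy()
        doses = np.sort(treated["dose_um"].unique())
        if not np.all(np.diff(doses) > 0):
            raise InvalidInputError(f"doses for {drug!r} are not strictly increasing")
        treated["normalized"] = treated["viability"] / control_mean
        grouped = treated.groupby("dose_um")["normalized"]
        summary = grouped.agg(
            mean_viability="mean",
            sem_viability=lambda v: stats.sem(v) if len(v) > 1 else 0.0,
            n="count",
        ).reset_index()
        summary.insert(0, "drug", drug)
        results.append(summary)
    return pd.concat(results, ignore_index=True)


def hill_curve(dose: np.ndarray, floor: float, ceiling: float, ic50: float, slope: float):
    """Descending 4-parameter logistic: viability vs dose."""
    return floor + (ceiling - floor) / (1.0 + (np.asarray(dose) / ic50) ** slope)


def fit_hill(doses_um: np.ndarray, viabilities: np.ndarray) -> dict[str, float]:
    """Least-squares 4PL fit; returns floor, ceiling, ic50, slope.

    Provided for synthetic-recovery experiments; the study's own summary is
    the per-dose mean +/- SEM, not a curve fit.
    """
    doses = np.asarray(doses_um, dtype=float)
    v = np.asarray(viabilities, dtype=float)
    if doses.size != v.size or doses.size < 4:
        raise InvalidInputError("need matched dose/viability arrays with >= 4 points")
    p0 = (max(v.min(), 1e-3), min(v.max(), 1.5), float(np.median(doses)), 1.0)
    bounds = ([0.0, 0.0, doses.min() / 100, 0.1], [1.5, 2.0, doses.max() * 100, 10.0])
    popt, _ = optimize.curve_fit(hill_curve, doses, v, p0=p0, bounds=bounds, maxfev=20000)
    return {"floor": popt[0], "ceiling": popt[1], "ic50": popt[2], "slope": popt[3]}


@dataclass(frozen=True)
class SecretionEstimate:
    """Per-cell secretion rate recovered from an endpoint concentration."""

    solute: str
    rate_pg_per_cell_per_day: float
    net_consumption: bool
    endpoint_pg_ml: float
    baseline_pg_ml: float
    volume_ul: float
    cells: float
    duration_days: float


def estimate_secretion_rate(
    endpoint_pg_ml: float,
    baseline_pg_ml: float,
    volume_ul: float,
    cells: float,
    duration_days: float,
    solute: str = "",
) -> SecretionEstimate:
    """Well-mixed back-calculation of the per-cell secretion rate.

    ``rate = (endpoint - baseline) * V / (cells * duration)`` in
    pg / cell / day; a negative rate is returned flagged as net consumption.
    """
    if cells <= 0:
        raise InvalidInputError("cell count must be > 0")
    if duration_days <= 0:
        raise InvalidInputError("duration must be > 0")
    if volume_ul <= 0:
        raise InvalidInputError("volume must be > 0")
    rate = (endpoint_pg_ml - baseline_pg_ml) * (volume_ul * 1e-3) / (cells * duration_days)
    return SecretionEstimate(
        solute=solute,
        rate_pg_per_cell_per_day=rate,
        net_consumption=rate < 0,
        endpoint_pg_ml=endpoint_pg_ml,
        baseline_pg_ml=baseline_pg_ml,
        volume_ul=volume_ul,
        cells=cells,
        duration_days=duration_days,
    )


def estimate_secretion_from_table(table: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`estimate_secretion_rate` chip-wise, then average per solute.

    The measured concentration is first undone for the assay dilution
    (``measured * dilution_factor``).
    """
    missing = set(LUMINEX_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidInputError(f"endpoint table missing columns: {sorted(missing)}")
    rows = []
    for _, r in table.iterrows():
        est = estimate_secretion_rate(
            endpoint_pg_ml=r["measured_pg_ml"] * r["dilution_factor"],
            baseline_pg_ml=r["baseline_pg_ml"],
            volume_ul=r["volume_ul"],
            cells=r["cells"],
            duration_days=r["duration_days"],
            solute=r["solute"],
        )
        rows.append(
            {"solute": r["solute"], "chip_id": r["chip_id"],
             "rate_pg_per_cell_per_day": est.rate_pg_per_cell_per_day}
        )
    per_chip = pd.DataFrame(rows)
    out = (
        per_chip.groupby("solute")["rate_pg_per_cell_per_day"]
        .agg(rate_pg_per_cell_per_day="mean", sem=lambda v: stats.sem(v) if len(v) > 1 else 0.0,
             n_chips="count")
        .reset_index()
    )
    out["net_consumption"] = out["rate_pg_per_cell_per_day"] < 0
    return out


# --- CSV IO ---------------------------------------------------------------

def read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(columns) - set(df.columns)
    if missing:
        raise InvalidInputError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_viability_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, VIABILITY_COLUMNS)


def read_dose_response_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, DOSE_COLUMNS)


def read_luminex_table(path: str | Path) -> pd.DataFrame:
    return read_table(path, LUMINEX_COLUMNS)
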