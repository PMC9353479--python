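"""Assay arithmetic against brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import brentq
from scipy.stats import norm

from chipsim import (
    ConcentrationField,
    Grid1D,
    InvalidInputError,
    Segment,
    SourceTerm,
    estimate_secretion_rate,
    extraction_success_rate,
    normalize_dose_response,
    simulate,
    summarize_viability,
    viability,
)
from chipsim.assays import estimate_secretion_from_table
from chipsim.synthetic import gen_endpoint_concentrations, gen_live_dead


@pytest.mark.parametrize(
    ("live", "dead", "expected"),
    [(80, 20, 0.80), (0, 50, 0.0), (7, 0, 1.0)],
)
def test_viability_examples(live, dead, expected):
    assert viability(live, dead) == pytest.approx(expected)


def test_viability_invalid_records():
    with pytest.raises(InvalidInputError):
        viability(0, 0)
    with pytest.raises(InvalidInputError):
        viability(-1, 5)


@given(st.integers(1, 10_000), st.integers(0, 10_000), st.integers(1, 50))
def test_viability_scale_invariant(live, dead, k):
    assert viability(k * live, k * dead) == pytest.approx(viability(live, dead), rel=1e-12)


def test_summarize_viability_matches_brute_force():
    table, _ = gen_live_dead(40, 0.65, seed=11, condition="bTME+")
    summary = summarize_viability(table).iloc[0]
    # oracle: per-ROI fractions averaged by hand
    fractions = table["live"].to_numpy() / (table["live"] + table["dead"]).to_numpy()
    assert summary["mean_viability"] == pytest.approx(fractions.mean(), rel=1e-12)
    sem = fractions.std(ddof=1) / np.sqrt(len(fractions))
    assert summary["sem_viability"] == pytest.approx(sem, rel=1e-9)
    assert summary["n_roi"] == 40


def test_extraction_success_rate_study_numbers():
    qc = extraction_success_rate(25, 31)
    assert qc.rate_percent == pytest.approx(100 * 25 / 31, rel=1e-12)  # ~80.6%
    assert round(qc.rate_percent, -1) == 80.0
    assert qc.wilson_low_percent < qc.rate_percent < qc.wilson_high_percent


def test_extraction_success_rate_edge_and_errors():
    assert extraction_success_rate(0, 17).rate_percent == 0.0
    with pytest.raises(InvalidInputError):
        extraction_success_rate(5, 4)
    with pytest.raises(InvalidInputError):
        extraction_success_rate(1, 0)


def test_wilson_interval_matches_score_inversion_oracle():
    """Endpoints solve |phat - p| = z * sqrt(p(1-p)/n) (score-test inversion)."""
    s, n = 25, 31
    phat = s / n
    z = norm.ppf(0.975)

    def score(p):
        return (phat - p) ** 2 - z**2 * p * (1 - p) / n

    low = brentq(score, 1e-9, phat)
    high = brentq(score, phat, 1 - 1e-9)
    qc = extraction_success_rate(s, n)
    assert qc.wilson_low_percent == pytest.approx(100 * low, abs=1e-4)
    assert qc.wilson_high_percent == pytest.approx(100 * high, abs=1e-4)


def make_dose_table(viabilities, control=0.8, drug="d"):
    rows = [
        {"drug": drug, "dose_um": np.nan, "replicate": 0, "viability": control,
         "is_control": True}
    ]
    for i, v in enumerate(viabilities):
        rows.append(
            {"drug": drug, "dose_um": float(i + 1), "replicate": 0, "viability": v,
             "is_control": False}
        )
    return pd.DataFrame(rows)


def test_normalize_dose_response_example():
    out = normalize_dose_response(make_dose_table([0.8, 0.6, 0.4], control=0.8))
    assert list(out["mean_viability"]) == pytest.approx([1.0, 0.75, 0.5])


def test_normalize_flat_table_is_unity():
    out = normalize_dose_response(make_dose_table([0.7] * 4, control=0.7))
    assert np.allclose(out["mean_viability"], 1.0)


def test_normalize_idempotent_after_control_reinsertion():
    """Re-normalizing an already-normalized table (control = 1) changes nothing."""
    from chipsim.synthetic import gen_dose_response

    table, _ = gen_dose_response(seed=3)
    first = normalize_dose_response(table)
    cm = table.loc[table.is_control, "viability"].mean()
    renorm = table.assign(viability=table.viability / cm)
    second = normalize_dose_response(renorm)
    pd.testing.assert_frame_equal(first, second)


def test_normalize_requires_positive_control():
    with pytest.raises(InvalidInputError):
        normalize_dose_response(make_dose_table([0.5], control=0.0))
    bad = make_dose_table([0.5]).loc[lambda d: ~d.is_control]
    with pytest.raises(InvalidInputError):
        normalize_dose_response(bad)


def test_per_dose_sem_matches_oracle():
    from chipsim.synthetic import gen_dose_response

    table, _ = gen_dose_response(replicates=8, seed=5)
    out = normalize_dose_response(table)
    cm = table.loc[table.is_control, "viability"].mean()
    for _, row in out.iterrows():
        reps = table.loc[
            (~table.is_control) & (table.dose_um == row.dose_um), "viability"
        ].to_numpy() / cm
        assert row["sem_viability"] == pytest.approx(
            reps.std(ddof=1) / np.sqrt(len(reps)), rel=1e-9
        )


def test_estimate_secretion_rate_arithmetic():
    est = estimate_secretion_rate(
        endpoint_pg_ml=100.0 + 3.6, baseline_pg_ml=3.6, volume_ul=60.0,
        cells=2.0e4, duration_days=1.0,
    )
    assert est.rate_pg_per_cell_per_day == pytest.approx(3.0e-4, rel=1e-12)
    assert not est.net_consumption


def test_estimate_secretion_zero_and_consumption():
    zero = estimate_secretion_rate(5.0, 5.0, 60.0, 1e4, 1.0)
    assert zero.rate_pg_per_cell_per_day == 0.0
    eaten = estimate_secretion_rate(1000.0, 5244.72, 60.0, 1e4, 1.0, solute="SPP-1")
    assert eaten.net_consumption
    assert eaten.rate_pg_per_cell_per_day < 0
    with pytest.raises(InvalidInputError):
        estimate_secretion_rate(1.0, 0.0, 60.0, 0, 1.0)
    with pytest.raises(InvalidInputError):
        estimate_secretion_rate(1.0, 0.0, 60.0, 10, 0.0)


def test_secretion_round_trip_through_transport_well_mixed_limit():
    """Forward PDE accumulation in a well-mixed compartment inverts to the true rate."""
    cells, rate, volume_ul, days = 5.0e4, 2.5e-3, 120.0, 1.0
    width = 1e-3
    area = volume_ul * 1e-9 / width
    grid = Grid1D([Segment("well", width, 5e-10)], area_m2=area, dx_m=5e-5)
    rec = simulate(
        grid,
        days * 86400.0,
        sources=[SourceTerm("well", cells, rate)],
        sample_interval_s=86400.0,
    )
    endpoint_per_ml = rec.field.values.mean() * 1e-6  # amount/m^3 -> amount/mL
    est = estimate_secretion_rate(endpoint_per_ml, 0.0, volume_ul, cells, days)
    assert est.rate_pg_per_cell_per_day == pytest.approx(rate, rel=0.01)


def test_secretion_table_round_trip_noiseless():
    rates = {"serpin E1": 5.0e-3, "IL-8": 2.0e-3, "SPP-1": -1.0e-2}
    table, _ = gen_endpoint_concentrations(rates, noise_cv=0.0, n_chips=3, seed=0)
    out = estimate_secretion_from_table(table).set_index("solute")
    for solute, rate in rates.items():
        assert out.loc[solute, "rate_pg_per_cell_per_day"] == pytest.approx(rate, rel=1e-9)
    assert bool(out.loc["SPP-1", "net_consumption"])
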