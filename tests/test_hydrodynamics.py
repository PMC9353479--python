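"""Radius, diffusivity and unit-conversion relations."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from chipsim import (
    GelSpec,
    PhysicalConditions,
    ProteinSpec,
    InvalidInputError,
    effective_radius,
    free_diffusivity,
    hindrance_factor,
    mass_to_molar,
    molar_to_mass,
)


@pytest.mark.parametrize(
    ("mw_da", "expected_a", "rtol"),
    [
        (8_000, 13.2, 1e-9),       # IL-8
        (1, 0.66, 1e-12),          # unit input
        (100_000, 30.6345, 1e-4),  # default collagenase
    ],
)
def test_effective_radius_examples(mw_da, expected_a, rtol):
    assert effective_radius(mw_da) == pytest.approx(expected_a, rel=rtol)


@pytest.mark.parametrize(
    ("radius_a", "expected_m2_s"),
    [
        (30.64, 8.33e-11),  # ~100 kDa protein at 37 C
        (13.2, 1.93e-10),   # IL-8
    ],
)
def test_free_diffusivity_examples(radius_a, expected_m2_s):
    cond = PhysicalConditions(temperature_k=310.15, viscosity_pa_s=8.9e-4)
    assert free_diffusivity(radius_a, cond) == pytest.approx(expected_m2_s, rel=2e-3)


def test_free_diffusivity_viscosity_scaling():
    cond = PhysicalConditions()
    doubled = PhysicalConditions(viscosity_pa_s=2 * cond.viscosity_pa_s)
    assert free_diffusivity(20.0, doubled) == pytest.approx(
        free_diffusivity(20.0, cond) / 2, rel=1e-12
    )


def test_hindrance_factor_example():
    # 3.064 nm protein in phi=0.125, r_f=200 nm collagen
    assert hindrance_factor(30.64, GelSpec()) == pytest.approx(0.99460, abs=1e-5)


def test_hindrance_factor_small_radius_limit():
    assert hindrance_factor(1e-9, GelSpec()) == pytest.approx(1.0, abs=1e-12)


def test_gel_diffusivity_from_printed_free_value():
    """Applying the obstruction factor to the in-medium 8.4e-11 value."""
    factor = hindrance_factor(effective_radius(100_000), GelSpec())
    assert 8.4e-11 * factor == pytest.approx(8.35e-11, rel=1e-3)


@pytest.mark.parametrize(
    ("mg_ml", "mw", "expected"),
    [
        (0.5, 71_430, 7.0e-3),      # gel-dissolving enzyme working solution
        (1.0, 100_000, 1.0e-2),
    ],
)
def test_mass_to_molar_examples(mg_ml, mw, expected):
    assert mass_to_molar(mg_ml, mw) == pytest.approx(expected, rel=1e-3)


@pytest.mark.parametrize("bad", [0.0, -1.0])
def test_non_positive_inputs_rejected(bad):
    with pytest.raises(InvalidInputError):
        effective_radius(bad)
    with pytest.raises(InvalidInputError):
        free_diffusivity(bad)
    with pytest.raises(InvalidInputError):
        mass_to_molar(bad, 1000.0)
    with pytest.raises(InvalidInputError):
        mass_to_molar(1.0, bad)


def test_invalid_specs_rejected():
    with pytest.raises(InvalidInputError):
        GelSpec(volume_fraction=1.2)
    with pytest.raises(InvalidInputError):
        PhysicalConditions(temperature_k=-1)
    with pytest.raises(InvalidInputError):
        ProteinSpec("x", -5.0)
    with pytest.raises(InvalidInputError):
        ProteinSpec("x", 1000.0, {"tumor": -1.0})


@given(st.floats(min_value=1.0, max_value=1e7), st.floats(min_value=1e-6, max_value=1e3))
def test_mass_molar_round_trip(mw, mg_ml):
    assert molar_to_mass(mass_to_molar(mg_ml, mw), mw) == pytest.approx(mg_ml, rel=1e-12)


@given(
    st.floats(min_value=0.1, max_value=500.0),
    st.floats(min_value=0.1, max_value=500.0),
)
def test_hindrance_decreasing_in_radius(r1, r2):
    gel = GelSpec()
    lo, hi = sorted((r1, r2))
    assert hindrance_factor(hi, gel) <= hindrance_factor(lo, gel) <= 1.0


@given(
    st.floats(min_value=0.01, max_value=0.9),
    st.floats(min_value=0.01, max_value=0.9),
)
def test_hindrance_decreasing_in_volume_fraction(phi1, phi2):
    lo, hi = sorted((phi1, phi2))
    r = 30.0
    assert hindrance_factor(r, GelSpec(volume_fraction=hi)) <= hindrance_factor(
        r, GelSpec(volume_fraction=lo)
    )


@given(st.floats(min_value=100.0, max_value=1e6), st.floats(min_value=100.0, max_value=1e6))
def test_free_diffusivity_decreasing_in_molecular_weight(m1, m2):
    lo, hi = sorted((m1, m2))
    d_lo = free_diffusivity(effective_radius(lo))
    d_hi = free_diffusivity(effective_radius(hi))
    assert d_hi <= d_lo


def test_collagenase_range_hindrance_band():
    """Across the 63-130 kDa enzyme range the gel barely hinders diffusion."""
    gel = GelSpec()
    ratios = np.array(
        [hindrance_factor(effective_radius(m), gel) for m in np.linspace(63e3, 130e3, 200)]
    )
    assert ratios.min() >= 0.993
    assert ratios.max() <= 0.996


def test_protein_spec_radius_consistency():
    p = ProteinSpec("serpin E1", 44_000.0)
    assert p.effective_radius_a == pytest.approx(
        0.66 * 44_000.0 ** (1 / 3), rel=1e-9
    )
    gel = GelSpec()
    assert p.diffusivity_gel(gel) == pytest.approx(
        p.diffusivity_water() * math.exp(-math.sqrt(0.125) * p.effective_radius_a * 0.1 / 200.0),
        rel=1e-12,
    )
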