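"""Finite-volume solver: conservation, analytic oracles, stability, positivity."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.special import erfc

from chipsim import (
    ConcentrationField,
    Grid1D,
    Reservoir,
    Segment,
    SourceTerm,
    StabilityError,
    TransportSolver,
    channel_mean,
    simulate,
    step,
)

D_GEL = 8.35e-11
D_MED = 8.4e-11


def make_grid(width_mm=2.0, d=D_MED, dx_um=5.0, label="slab", area=1.2e-6):
    return Grid1D([Segment(label, width_mm * 1e-3, d)], area_m2=area, dx_m=dx_um * 1e-6)


def test_zero_coefficients_leave_field_unchanged():
    grid = make_grid(d=0.0)
    field = ConcentrationField(grid, np.linspace(0.0, 1.0, grid.n).copy())
    before = field.values.copy()
    step(field, 1.0)
    assert np.array_equal(field.values, before)


def test_closed_domain_conserves_mass():
    """1,000 explicit steps in a closed domain drift by less than 1e-8 relative."""
    grid = Grid1D(
        [Segment("a", 1e-3, D_MED), Segment("b", 1e-3, D_GEL)], area_m2=1.2e-6
    )
    rng = np.random.default_rng(7)
    field = ConcentrationField(grid, rng.random(grid.n))
    res = Reservoir("a", volume_ul=60.0, conductance_m3_s=1e-12, concentration=2.0)
    solver = TransportSolver(grid, reservoirs=[res], initial=field)
    total0 = field.total_amount()
    dt = solver.suggested_dt()
    solver._advance(1000, dt)
    assert field.total_amount() == pytest.approx(total0, rel=1e-8)
    assert field.values.min() >= 0.0


def test_pure_diffusion_matches_erf_solution():
    """Step initial condition vs the infinite-slab erfc profile, L-inf < 1%."""
    grid = make_grid(width_mm=2.0, d=D_MED, dx_um=5.0)
    c0 = 1.0
    field = ConcentrationField(grid, np.where(grid.x < 1e-3, c0, 0.0).astype(float))
    solver = TransportSolver(grid, initial=field)
    t_end = 600.0
    dt = solver.suggested_dt()
    solver._advance(int(np.ceil(t_end / dt)), t_end / np.ceil(t_end / dt))
    analytic = 0.5 * c0 * erfc((grid.x - 1e-3) / (2.0 * np.sqrt(D_MED * t_end)))
    assert np.max(np.abs(field.values - analytic)) < 0.01 * c0


def test_advected_slab_matches_exp_peclet_attenuation():
    """Steady upstream profile against the flow matches c0*exp(-u*d/D) within 2%.

    The source end is held at c0, the upstream boundary is closed, and the
    flow points toward the source; at steady state the net flux is zero and
    the concentration decays as exp(-Pe * d / L) with upstream distance d.
    """
    d = D_GEL
    slab_l = 0.25e-3
    peclet = 3.0
    u = peclet * d / slab_l
    grid = Grid1D(
        [Segment("slab", slab_l, d), Segment("source", 0.025e-3, d)],
        area_m2=1.2e-6,
        dx_m=2.5e-6,
    )
    rec = simulate(
        grid,
        6000.0,
        velocity=lambda t: u,
        flow_path=("slab", "source"),
        fixed={"source": 1.0},
    )
    sl = grid.slices["slab"]
    x = grid.x[sl]
    x_ref = grid.x[grid.slices["source"]][0]  # first held cell center
    analytic = np.exp(-u * (x_ref - x) / d)
    numeric = rec.field.values[sl]
    # mean attenuation across the slab vs the closed form
    assert numeric.mean() == pytest.approx(analytic.mean(), rel=0.02)
    # pointwise agreement in absolute terms
    assert np.max(np.abs(numeric - analytic)) < 0.02


def test_upstream_compartment_shielded_at_high_peclet():
    """With Pe >> 1 the compartment upstream of the source stays near zero."""
    d = D_GEL
    grid = Grid1D(
        [Segment("up", 1e-3, d), Segment("src", 0.2e-3, d)],
        area_m2=1.2e-6,
        dx_m=5e-6,
    )
    peclet = 200.0
    u = peclet * d / 1e-3
    rec = simulate(
        grid,
        2000.0,
        velocity=lambda t: u,
        flow_path=("up", "src"),
        fixed={"src": 1.0},
    )
    mean_up = channel_mean(rec.field, "up")
    assert mean_up < 0.01
    # steady mean of the exponential boundary layer is ~1/Pe
    assert mean_up == pytest.approx(1.0 / peclet, rel=0.2)


def test_linearity_in_sources():
    grid = Grid1D([Segment("a", 0.5e-3, D_MED), Segment("b", 0.5e-3, D_MED)], area_m2=1.2e-6)
    kwargs = dict(sample_interval_s=100.0)
    rec1 = simulate(
        grid, 400.0, sources=[SourceTerm("a", 1000, 2.0)], **kwargs
    )
    grid2 = Grid1D([Segment("a", 0.5e-3, D_MED), Segment("b", 0.5e-3, D_MED)], area_m2=1.2e-6)
    rec2 = simulate(
        grid2, 400.0, sources=[SourceTerm("a", 1000, 4.0)], **kwargs
    )
    assert np.allclose(rec2.field.values, 2.0 * rec1.field.values, rtol=1e-12)


def test_grid_refinement_convergence():
    """Halving dx changes end-of-run channel means by < 2%."""
    means = {}
    for dx in (10.0, 5.0):
        grid = Grid1D(
            [Segment("m", 1e-3, D_MED), Segment("g", 1e-3, D_GEL)],
            area_m2=1.2e-6,
            dx_m=dx * 1e-6,
        )
        field = ConcentrationField.uniform(grid)
        field.set_segment("m", 1.0)
        rec = simulate(grid, 300.0, initial=field)
        means[dx] = channel_mean(rec.field, "g")
    assert means[5.0] == pytest.approx(means[10.0], rel=0.02)


def test_channel_mean_uniform_and_linear():
    grid = make_grid(width_mm=1.0)
    field = ConcentrationField.uniform(grid, 3.25)
    assert channel_mean(field, "slab") == pytest.approx(3.25, rel=1e-15)

    a, b = 0.4, 1.7e3
    field = ConcentrationField(grid, a + b * grid.x)
    # midpoint value of a linear profile == trapezoid-integral mean
    trapezoid_mean = np.trapezoid(field.values, grid.x) / (grid.x[-1] - grid.x[0])
    assert channel_mean(field, "slab") == pytest.approx(trapezoid_mean, rel=1e-12)
    assert channel_mean(field, "slab") == pytest.approx(a + b * 0.5e-3, rel=1e-12)


def test_oversized_dt_refused_with_diagnostic():
    grid = make_grid()
    solver = TransportSolver(grid)
    limit = solver.suggested_dt()
    with pytest.raises(StabilityError) as err:
        solver.step(limit * 3)
    assert err.value.suggested_dt == pytest.approx(limit)
    solver.step(limit)  # the suggested step is accepted


@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_positivity_preserved(seed):
    """No negative concentrations from any non-negative initial state."""
    rng = np.random.default_rng(seed)
    grid = Grid1D(
        [Segment("m", 0.2e-3, D_MED), Segment("g", 0.2e-3, D_GEL)],
        area_m2=1.2e-6,
        dx_m=10e-6,
    )
    field = ConcentrationField(grid, rng.random(grid.n) * 10.0)
    solver = TransportSolver(
        grid, velocity=lambda t: 4e-5, flow_path=("m", "g"), initial=field
    )
    solver._advance(200, solver.suggested_dt())
    assert field.values.min() >= 0.0


def test_reservoir_exchange_equilibrates_and_conserves():
    grid = make_grid(width_mm=0.5, label="ch")
    field = ConcentrationField.uniform(grid, 0.0)
    res = Reservoir("ch", volume_ul=10.0, conductance_m3_s=5e-11, concentration=1.0)
    solver = TransportSolver(grid, reservoirs=[res], initial=field)
    total0 = field.total_amount()
    solver._advance(20000, solver.suggested_dt())
    assert field.total_amount() == pytest.approx(total0, rel=1e-9)
    # both sides drift toward a common concentration
    assert channel_mean(field, "ch") > 0.1
    assert res.concentration < 1.0


def test_unknown_compartment_rejected():
    grid = make_grid()
    from chipsim import ConfigError

    with pytest.raises(ConfigError):
        simulate(grid, 10.0, sources=[SourceTerm("nope", 1, 1.0)])
    with pytest.raises(ConfigError):
        channel_mean(ConcentrationField.uniform(grid), "nope")
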