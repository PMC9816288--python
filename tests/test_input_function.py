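"""Feng model evaluation, integration and fitting."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pbifkit import (
    FengParams,
    FitError,
    SampledCurve,
    feng_auc,
    feng_eval,
    feng_fit,
    sampled_auc,
)
from .conftest import feng_curve

SIMPLE = FengParams(tau=0.0, A1=1.0, A2=0.0, A3=0.0, lam1=1.0, lam2=0.5, lam3=0.1)


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(lam1=0.1, lam2=0.5), "ordering"),
        (dict(lam3=-0.01), "ordering"),
        (dict(A1=0.0), "A1"),
        (dict(A2=-1.0), "nonnegative"),
        (dict(tau=-0.5), "tau"),
    ],
)
def test_invalid_params_name_the_violated_constraint(printed_params, kwargs, match):
    with pytest.raises(ValueError, match=match):
        dataclasses.replace(printed_params, **kwargs)


def test_value_is_zero_at_and_before_onset(printed_params):
    assert feng_eval(printed_params, printed_params.tau) == 0.0
    assert feng_eval(printed_params, 0.0) == 0.0
    t = np.linspace(0, printed_params.tau, 7)
    assert np.all(feng_eval(printed_params, t) == 0.0)


def test_gamma_variate_peak_value():
    # pure gamma variate: maximum e^-1 at t = 1/lam1
    assert feng_eval(SIMPLE, 1.0) == pytest.approx(np.exp(-1), rel=1e-12)


def test_peak_location_matches_closed_form(printed_params):
    # numerically located peak vs the closed form of the dominant term
    # (A1 t - A2 - A3) e^(-lam1 t): stationary at t' = 1/lam1 + (A2+A3)/A1
    grid = np.linspace(printed_params.tau, printed_params.tau + 0.5, 200001)
    values = feng_eval(printed_params, grid)
    t_peak = grid[np.argmax(values)] - printed_params.tau
    expected = 1.0 / printed_params.lam1 + (
        printed_params.A2 + printed_params.A3
    ) / printed_params.A1
    assert t_peak == pytest.approx(expected, rel=0.01)


def test_gamma_variate_total_area_is_A1_over_lam1_squared():
    assert feng_auc(SIMPLE, 0.0, 60.0) == pytest.approx(1.0, rel=1e-9)


def test_feng_auc_rejects_degenerate_window(printed_params):
    with pytest.raises(ValueError):
        feng_auc(printed_params, 5.0, 5.0)
    with pytest.raises(ValueError):
        feng_auc(printed_params, 10.0, 5.0)


def test_feng_auc_matches_fine_trapezoid(printed_params):
    grid = np.linspace(0.0, 65.0, 65001)  # 0.001-min steps
    oracle = np.trapezoid(feng_eval(printed_params, grid), grid)
    assert feng_auc(printed_params, 0.0, 65.0) == pytest.approx(oracle, rel=1e-3)


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    tau=st.floats(0.0, 2.0),
    a1=st.floats(1.0, 30.0),
    a23=st.floats(0.0, 0.1),
    lam1=st.floats(5.0, 40.0),
    lam2=st.floats(0.05, 1.0),
    lam3=st.floats(0.001, 0.04),
)
def test_model_continuity_and_auc_monotonicity(tau, a1, a23, lam1, lam2, lam3):
    params = FengParams(tau, a1, a23, a23, lam1, lam2, lam3)
    eps = 1e-9
    assert abs(feng_eval(params, tau + eps)) < 1e-6 * a1
    aucs = [feng_auc(params, 0.0, T) for T in (5.0, 20.0, 65.0, 200.0, 20000.0)]
    assert np.all(np.diff(aucs) >= 0)
    # convergence as T grows: closed-form limit of each term
    limit = (
        params.A1 / params.lam1**2
        - (params.A2 + params.A3) / params.lam1
        + params.A2 / params.lam2
        + params.A3 / params.lam3
    )
    assert aucs[-1] == pytest.approx(limit, rel=1e-4)


def make_constant_curve(value=1.0, n=10, t_end=10.0):
    edges = np.linspace(0.0, t_end, n + 1)
    return SampledCurve(edges[:-1], edges[1:], np.full(n, value))


def test_sampled_auc_constant_curve():
    assert sampled_auc(make_constant_curve(), 0.0, 10.0) == pytest.approx(10.0, rel=1e-12)


def test_sampled_auc_linear_ramp_is_triangle_area():
    edges = np.linspace(0.0, 10.0, 11)
    mids = 0.5 * (edges[:-1] + edges[1:])
    curve = SampledCurve(edges[:-1], edges[1:], mids)  # value(t) = t
    assert sampled_auc(curve, 0.0, 10.0) == pytest.approx(50.0, rel=1e-12)


def test_sampled_auc_tail_window_matches_analytic(printed_curve, printed_params):
    sa = sampled_auc(printed_curve, 55.0, 65.0)
    fa = feng_auc(printed_params, 55.0, 65.0)
    assert sa == pytest.approx(fa, rel=5e-3)


def test_sampled_auc_refinement_converges(printed_params):
    # halving frame widths must shrink the quadrature error
    errors = []
    for n in (65, 130, 260, 520):
        edges = np.linspace(0.0, 65.0, n + 1)
        mids = 0.5 * (edges[:-1] + edges[1:])
        curve = SampledCurve(edges[:-1], edges[1:], feng_eval(printed_params, mids))
        errors.append(abs(sampled_auc(curve, 5.0, 60.0) - feng_auc(printed_params, 5.0, 60.0)))
    assert np.all(np.diff(errors) < 0)


def test_sampled_auc_rejects_disjoint_window(printed_curve):
    with pytest.raises(ValueError, match="disjoint"):
        sampled_auc(printed_curve, 100.0, 110.0)


def test_fit_recovers_known_parameters(schedule62):
    truth = FengParams(tau=0.7, A1=15.0, A2=0.02, A3=0.02, lam1=18.0, lam2=0.2, lam3=0.01)
    fit = feng_fit(feng_curve(truth, schedule62), seed=0)
    for name in ("tau", "A1", "A2", "A3", "lam1", "lam2", "lam3"):
        assert getattr(fit.params, name) == pytest.approx(getattr(truth, name), rel=0.01)
    assert fit.residual_norm < 1e-8


def test_fit_recovers_printed_population_parameters(printed_curve, printed_params):
    fit = feng_fit(printed_curve, seed=0)
    assert fit.params.A1 == pytest.approx(printed_params.A1, rel=0.01)
    assert fit.params.lam1 == pytest.approx(printed_params.lam1, rel=0.01)


def test_fit_rejects_flat_curve(schedule62):
    curve = SampledCurve(schedule62.start_min, schedule62.end_min,
                         np.zeros(schedule62.n_frames))
    with pytest.raises((FitError, ValueError)):
        feng_fit(curve, seed=0)


def test_fit_requires_enough_frames():
    curve = make_constant_curve(n=5)
    with pytest.raises(ValueError, match="10 frames"):
        feng_fit(curve, seed=0)


@pytest.mark.parametrize("draw", range(4))
def test_fit_recovery_across_population_box(schedule62, printed_params, draw):
    """Parameter recovery holds across the population variability box."""
    rng = np.random.default_rng(100 + draw)
    f = rng.lognormal(mean=0.0, sigma=0.1, size=6)
    truth = FengParams(
        tau=float(rng.uniform(0.4, 1.0)),
        A1=550 * printed_params.A1 * f[0],
        A2=550 * printed_params.A2 * f[1],
        A3=550 * printed_params.A3 * f[2],
        lam1=printed_params.lam1 * f[3],
        lam2=printed_params.lam2 * f[4],
        lam3=printed_params.lam3 * f[5],
    )
    fit = feng_fit(feng_curve(truth, schedule62), seed=draw)
    for name in ("tau", "A1", "A2", "A3", "lam1", "lam2", "lam3"):
        assert getattr(fit.params, name) == pytest.approx(getattr(truth, name), rel=0.01)


@pytest.mark.parametrize(
    "kwargs, match",
    [
        (dict(frame_start=[0, 1], frame_end=[1, 2], value=[1, np.inf]), "finite"),
        (dict(frame_start=[1, 0], frame_end=[2, 1], value=[1, 1]), "increasing"),
        (dict(frame_start=[0, 0.5], frame_end=[1, 1.5], value=[1, 1]), "overlap"),
        (dict(frame_start=[0, 1], frame_end=[0, 2], value=[1, 1]), "exceed"),
    ],
)
def test_curve_validation(kwargs, match):
    with pytest.raises(ValueError, match=match):
        SampledCurve(**kwargs)
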