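"""Marginal-likelihood objective, fitting engine and covariate selection."""

import math

import numpy as np
import pytest

import carnimax as cm
from carnimax.estimation import FitSettings, evaluate
from carnimax.structural import EmaxParams


def closed_form_ofv(params, series_list):
    """Independent weighted-likelihood closed form for omega = 0."""
    total = 0.0
    for s in series_list:
        pred = params.emax_pct * s.times_weeks / (params.et50_weeks + s.times_weeks)
        var = params.sigma**2 / (s.n_treatment / 100.0)
        r = s.effect_net_pct - pred
        total += np.sum(np.log(2 * np.pi * var) + r**2 / var)
    return float(total)


def test_objective_single_zero_residual_obs(make_series):
    p = EmaxParams(emax_pct=-2.0, et50_weeks=4.0, sigma=1.0)
    s = make_series("s", [4.0], [-1.0], [100])  # prediction is exactly -1.0
    assert cm.objective(p, [s]) == pytest.approx(math.log(2 * math.pi), abs=1e-12)


def test_objective_matches_weighted_closed_form(make_series):
    p = EmaxParams(emax_pct=-3.0, et50_weeks=2.5, sigma=0.4)
    data = [
        make_series("s1", [4.0, 12.0], [-2.2, -2.9], [50, 50]),
        make_series("s2", [4.0, 12.0], [-1.7, -2.4], [200, 200]),
    ]
    assert cm.objective(p, data) == pytest.approx(closed_form_ofv(p, data), rel=1e-12)


@pytest.mark.parametrize("omega", [0.02, 0.05])
@pytest.mark.parametrize("n_studies", [1, 3])
def test_laplace_agrees_with_gauss_hermite(make_series, omega, n_studies):
    """Laplace OFV within 1e-3 of 41-node adaptive Gauss-Hermite."""
    data = [
        make_series("s1", [4.0, 12.0], [-2.0, -3.1], [30, 30]),
        make_series("s2", [4.0, 12.0], [-1.5, -2.6], [40, 40]),
        make_series("s3", [2.0, 8.0], [-1.1, -2.9], [25, 25]),
    ][:n_studies]
    p = EmaxParams(-3.5, 3.0, omega_emax=omega, omega_et50=omega, sigma=0.5)
    assert cm.objective(p, data) == pytest.approx(cm.objective_agq(p, data), abs=1e-3)


def test_objective_permutation_invariant(default_series, truth):
    forward = cm.objective(truth, default_series)
    backward = cm.objective(truth, list(reversed(default_series)))
    assert forward == pytest.approx(backward, rel=1e-12)


def test_objective_split_invariant_without_random_effects(make_series):
    """With omega = 0 the likelihood factorises over observations, so
    splitting a study's observation list cannot change the OFV."""
    p = EmaxParams(emax_pct=-3.0, et50_weeks=2.5, sigma=0.4)
    whole = [make_series("s1", [2.0, 6.0, 12.0], [-1.5, -2.2, -2.8], [30, 30, 30])]
    split = [
        make_series("s1a", [2.0], [-1.5], [30]),
        make_series("s1b", [6.0, 12.0], [-2.2, -2.8], [30, 30]),
    ]
    assert cm.objective(p, whole) == pytest.approx(cm.objective(p, split), rel=1e-12)


def test_fit_zero_noise_recovery(noise_free_series):
    init = EmaxParams(
        emax_pct=-4.0, et50_weeks=4.0, omega_emax=0.0, omega_et50=0.0, sigma=0.5
    )
    settings = FitSettings(fix_omega_emax=True, fix_omega_et50=True)
    res = cm.fit(noise_free_series, init=init, settings=settings)
    assert res.converged
    assert res.params.emax_pct == pytest.approx(-3.92, rel=1e-4)
    assert res.params.et50_weeks == pytest.approx(3.6, rel=1e-4)


def test_fit_requires_two_studies(make_series):
    with pytest.raises(ValueError, match="2 studies"):
        cm.fit([make_series("s", [4.0, 12.0], [-2.0, -3.0], [30, 30])])


def test_fit_reports_start_grid(fitted_default):
    res, _ = fitted_default
    assert len(res.start_ofvs) == 9  # deterministic 3 x 3 multi-start grid
    assert res.converged
    assert res.ofv == pytest.approx(min(s["ofv"] for s in res.start_ofvs))


def test_relaxing_omega_bound_never_raises_ofv(default_series):
    """The omega-free model nests the omega-fixed one."""
    init0 = EmaxParams(
        emax_pct=-4.0, et50_weeks=4.0, omega_emax=0.0, omega_et50=0.0, sigma=0.5
    )
    fixed = cm.fit(
        default_series,
        init=init0,
        settings=FitSettings(fix_omega_emax=True, fix_omega_et50=True),
    )
    free = cm.fit(default_series)
    assert free.ofv <= fixed.ofv + 1e-6


def test_evaluate_wraps_objective(default_series, truth):
    res = evaluate(truth, default_series)
    assert res.converged
    assert res.ofv == pytest.approx(cm.objective(truth, default_series))
    assert set(res.eta_modes) == {s.study_id for s in default_series}


@pytest.mark.parametrize(
    "alpha, df, expected", [(0.05, 1, 3.84), (0.01, 1, 6.63), (0.05, 2, 5.99)]
)
def test_lrt_threshold_values(alpha, df, expected):
    assert cm.lrt_threshold(alpha, df) == expected


@pytest.mark.parametrize("alpha, df", [(0.0, 1), (1.0, 1), (0.05, 0), (0.05, 1.5)])
def test_lrt_threshold_domain(alpha, df):
    with pytest.raises(ValueError):
        cm.lrt_threshold(alpha, df)


def _dose_effect_data(make_series, theta=0.004):
    """Low-noise data whose Emax depends linearly on the daily dose."""
    rng = np.random.default_rng(5)
    doses = (250.0, 500.0, 750.0, 1000.0)
    ages = (27.9, 23.9, 30.2, 26.1)  # deliberately unrelated to dose
    times = np.array([4.0, 8.0, 12.0])
    data = []
    for k, dose in enumerate(doses):
        emax = -3.92 + (dose - 625.0) * theta
        y = emax * times / (3.6 + times) + rng.normal(0, 0.05, times.size)
        data.append(
            make_series(
                f"s{k}",
                times,
                y,
                [30, 30, 30],
                covariates={"dose": dose, "age": ages[k]},
            )
        )
    return data


def test_covariate_step_retains_strong_dose_effect(make_series):
    data = _dose_effect_data(make_series)
    base = cm.fit(data)
    candidates = [
        ("dose", "emax", "additive_centered"),
        ("age", "emax", "additive_centered"),
    ]
    res = cm.covariate_step(data, base, candidates)
    assert "dose" in res.params.theta_cor
    assert res.params.theta_cor["dose"].parameter == "emax"
    included = [e for e in res.selection_trace if e["decision"] == "included"]
    assert any(e["covariate"] == "dose" for e in included)
    retained = [e for e in res.selection_trace if e["step"] == "backward"]
    assert all(e["decision"] == "retained" for e in retained if e["covariate"] == "dose")
    # sign and rough size of the recovered coefficient
    assert res.params.theta_cor["dose"].coefficient == pytest.approx(0.004, rel=0.5)


def test_covariate_step_tie_break_is_deterministic(make_series):
    data = _dose_effect_data(make_series)
    base = cm.fit(data)
    dup = [("dose", "emax", "additive_centered"), ("dose", "emax", "additive_centered")]
    res = cm.covariate_step(data, base, dup)
    tested = [e for e in res.selection_trace if e["decision"] == "tested"]
    assert len(tested) == 2
    assert tested[0]["delta_ofv"] == pytest.approx(tested[1]["delta_ofv"], abs=1e-6)
    # only one copy enters the model
    assert sum(1 for e in res.selection_trace if e["decision"] == "included") == 1


def test_covariate_step_missing_covariate_fails_before_fitting(default_series):
    base = evaluate(
        EmaxParams(-3.92, 3.6, omega_emax=0.1, omega_et50=0.1, sigma=0.2),
        default_series,
    )
    with pytest.raises(KeyError, match="not_a_covariate"):
        cm.covariate_step(default_series, base, [("not_a_covariate", "emax", "additive_centered")])
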