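"""Goodness-of-fit tables, CWRES, bootstrap and prediction-corrected VPC."""

import numpy as np
import pytest
from scipy import stats

import carnimax as cm
from carnimax.diagnostics import relative_bias
from carnimax.estimation import FitSettings, evaluate
from carnimax.structural import EmaxParams


def test_predictions_no_iiv_individual_equals_population(make_series):
    p = EmaxParams(emax_pct=-3.0, et50_weeks=2.5, sigma=0.4)
    data = [
        make_series("s1", [4.0, 12.0], [-2.2, -2.9], [50, 50]),
        make_series("s2", [4.0, 12.0], [-1.7, -2.4], [200, 200]),
    ]
    table = cm.predictions(evaluate(p, data), data)
    np.testing.assert_allclose(table["individual_pred"], table["population_pred"])


def test_predictions_match_noise_free_observations(noise_free_series):
    p = EmaxParams(emax_pct=-3.92, et50_weeks=3.6, sigma=0.1)
    table = cm.predictions(evaluate(p, noise_free_series), noise_free_series)
    np.testing.assert_allclose(
        table["observation"], table["individual_pred"], atol=1e-6
    )


def test_predictions_require_convergence(default_series, truth):
    res = evaluate(truth, default_series)
    bad = cm.FitResult(
        params=res.params, ofv=res.ofv, converged=False, n_obs=res.n_obs,
        n_studies=res.n_studies,
    )
    with pytest.raises(ValueError):
        cm.predictions(bad, default_series)


def test_cwres_closed_form_without_iiv(make_series):
    """With omega = 0, CWRES = (obs - pred) * sqrt(N/100) / sigma:
    a 0.5% residual in a 400-subject arm at sigma = 1 gives exactly 1."""
    p = EmaxParams(emax_pct=-2.0, et50_weeks=4.0, sigma=1.0)
    pred = -2.0 * 4.0 / (4.0 + 4.0)
    s = make_series("s", [4.0], [pred + 0.5], [400])
    s2 = make_series("s2", [4.0], [pred - 0.5], [400])
    res = evaluate(p, [s, s2])
    np.testing.assert_allclose(cm.cwres(res, [s, s2]), [1.0, -1.0], atol=1e-12)


def test_cwres_standard_normal_under_correct_model(truth):
    """Self-simulated data should give CWRES with mean ~0, SD ~1 and an
    unremarkable normality statistic."""
    series = cm.build_effect_series(cm.generate(cm.default_config(seed=11, truth=truth)))
    res = evaluate(truth, series)
    r = cm.cwres(res, series)
    assert len(r) == 12
    assert abs(np.mean(r)) < 0.6  # SE ~ 0.29 at n = 12
    assert abs(np.std(r, ddof=1) - 1.0) < 0.5
    # QQ slope close to 1
    osm, osr = stats.probplot(r, dist="norm")[0]
    slope = np.polyfit(osm, osr, 1)[0]
    assert 0.5 < slope < 1.6


def test_cwres_normality_across_replicates(truth):
    """Shapiro-Wilk should not reject a correctly specified model in most
    replicates."""
    ok = 0
    n_rep = 20
    for seed in range(300, 300 + n_rep):
        series = cm.build_effect_series(
            cm.generate(cm.default_config(seed=seed, truth=truth))
        )
        r = cm.cwres(evaluate(truth, series), series)
        if stats.shapiro(r).pvalue > 0.01:
            ok += 1
    assert ok >= 0.9 * n_rep


@pytest.mark.parametrize(
    "median, estimate, expected",
    [(0.376, 0.867, -0.566), (0.098, 0.106, -0.075)],
)
def test_relative_bias_formula(median, estimate, expected):
    assert relative_bias(median, estimate) == pytest.approx(expected, abs=5e-4)


def test_bootstrap_degenerate_resampling(make_series):
    """If every study is an identical copy, every resample is the original
    dataset, so the replicate median equals the estimate and bias is 0."""
    p = EmaxParams(emax_pct=-3.0, et50_weeks=2.5, sigma=0.4)
    base = make_series("s0", [4.0, 12.0], [-2.2, -2.9], [50, 50])
    data = [
        make_series(f"s{k}", [4.0, 12.0], [-2.2, -2.9], [50, 50]) for k in range(3)
    ]
    fit = cm.fit(data, init=p, settings=FitSettings(single_start=True))
    summary = cm.bootstrap(data, fit, n_replicates=6, seed=4)
    assert summary.n_failed == 0
    for name, ps in summary.parameters.items():
        assert ps.median == pytest.approx(ps.estimate, rel=1e-5, abs=1e-7)
        if ps.estimate != 0:
            assert ps.bias == pytest.approx(0.0, abs=1e-4)
    assert base.study_id == "s0"  # fixture sanity


def test_bootstrap_reproducible_under_seed(fitted_default):
    res, series = fitted_default
    a = cm.bootstrap(series, res, n_replicates=8, seed=99)
    b = cm.bootstrap(series, res, n_replicates=8, seed=99)
    assert a == b
    for ps in a.parameters.values():
        assert ps.ci_low <= ps.median <= ps.ci_high


def test_pcvpc_correction_identity_and_nesting(fitted_default):
    """Without covariates all studies share one population prediction per
    bin, so the multiplicative correction is the identity."""
    res, series = fitted_default
    vpc = cm.pcvpc(res, series, n_sim=200, seed=3)
    raw = np.concatenate([s.effect_net_pct for s in series])
    corrected = np.concatenate(vpc.observed)
    np.testing.assert_allclose(np.sort(corrected), np.sort(raw), rtol=1e-12)
    assert np.all(vpc.sim_p2_5 <= vpc.sim_p50)
    assert np.all(vpc.sim_p50 <= vpc.sim_p97_5)


def test_pcvpc_single_replicate_collapses(make_series):
    p = EmaxParams(emax_pct=-3.0, et50_weeks=2.5, sigma=0.3)
    # one observation per bin: bands must collapse onto the lone replicate
    data = [
        make_series("s1", [2.0, 6.0], [-1.4, -2.1], [30, 30]),
        make_series("s2", [4.0, 8.0], [-1.8, -2.3], [30, 30]),
    ]
    vpc = cm.pcvpc(evaluate(p, data), data, n_sim=1, seed=1)
    np.testing.assert_allclose(vpc.sim_p2_5, vpc.sim_p97_5)
    np.testing.assert_allclose(vpc.sim_p2_5, vpc.sim_p50)


def test_pcvpc_coverage_on_self_simulated_data(truth):
    """Pooled over several self-simulated datasets, ~95% of observations
    should fall inside the simulated 95% band (12 observations per dataset
    are too few for a stable single-dataset coverage estimate)."""
    inside = total = 0
    for seed in range(21, 26):
        series = cm.build_effect_series(
            cm.generate(cm.default_config(seed=seed, truth=truth))
        )
        vpc = cm.pcvpc(evaluate(truth, series), series, n_sim=300, seed=5)
        total += sum(len(o) for o in vpc.observed)
        inside += round(vpc.coverage * sum(len(o) for o in vpc.observed))
    assert inside / total >= 0.85
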