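"""Model evaluation: goodness-of-fit tables, conditional weighted
residuals, nonparametric bootstrap and prediction-corrected VPC.

Residuals are decorrelated with the model-implied covariance
``G Omega G^T + diag(sigma^2/(N/100))`` evaluated at the empirical-Bayes
eta modes (first-order-conditional linearisation), so under a correct
model they are approximately standard normal.  The bootstrap resamples
studies with replacement — the study is the model's exchangeable unit —
and summarises replicate medians, 2.5/97.5 percentiles and the relative
bias (median - estimate)/estimate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .aggregate_data import EffectSeries
from .estimation import (
    FitResult,
    FitSettings,
    _active_dims,
    _curve,
    _typical,
    fit as _fit,
)
from .structural import EmaxParams

__all__ = [
    "ParamSummary",
    "BootstrapSummary",
    "VpcResult",
    "predictions",
    "cwres",
    "bootstrap",
    "pcvpc",
    "relative_bias",
    "draw_etas",
]

logger = logging.getLogger(__name__)


def relative_bias(median: float, estimate: float) -> float:
    """Bootstrap bias on the relative scale: (median - estimate)/estimate."""
    if estimate == 0:
        return math.nan
    return (median - estimate) / estimate


@dataclass(frozen=True)
class ParamSummary:
    estimate: float
    median: float
    ci_low: float
    ci_high: float
    bias: float


@dataclass(frozen=True)
class BootstrapSummary:
    parameters: dict
    n_replicates: int
    n_failed: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": name,
                "estimate": p.estimate,
                "median": p.median,
                "ci_2.5": p.ci_low,
                "ci_97.5": p.ci_high,
                "bias": p.bias,
            }
            for name, p in self.parameters.items()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class VpcResult:
    bins: np.ndarray
    sim_p2_5: np.ndarray
    sim_p50: np.ndarray
    sim_p97_5: np.ndarray
    observed: list  # corrected observations per bin
    coverage: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_weeks": self.bins,
                "sim_p2.5": self.sim_p2_5,
                "sim_p50": self.sim_p50,
                "sim_p97.5": self.sim_p97_5,
                "n_observed": [len(o) for o in self.observed],
            }
        )


def _study_curves(params: EmaxParams, series: EffectSeries, eta_full):
    """(population f, individual f, Jacobian at eta) for one study."""
    t = np.asarray(series.times_weeks, float)
    emax_tv, et50_tv = _typical(params, series.covariates)
    dims, _ = _active_dims(params)
    eta = np.array([eta_full[d] for d in dims])
    f_pop, _ = _curve(
        emax_tv, et50_tv, params.eta_form_emax, params.eta_form_et50, dims,
        np.zeros(len(dims)), t,
    )
    f_ind, J = _curve(
        emax_tv, et50_tv, params.eta_form_emax, params.eta_form_et50, dims, eta, t
    )
    return f_pop, f_ind, J, eta, dims


def predictions(fit: FitResult, data) -> pd.DataFrame:
    """Observation vs population (eta = 0) and individual (eta mode) predictions."""
    if not fit.converged:
        raise ValueError("predictions require a converged fit")
    rows = []
    for s in data:
        eta_full = fit.eta_modes.get(s.study_id, (0.0, 0.0))
        f_pop, f_ind, _, _, _ = _study_curves(fit.params, s, eta_full)
        for k in range(len(s)):
            rows.append(
                {
                    "study_id": s.study_id,
                    "time_weeks": float(s.times_weeks[k]),
                    "observation": float(s.effect_net_pct[k]),
                    "population_pred": float(f_pop[k]),
                    "individual_pred": float(f_ind[k]),
                    "n": int(s.n_treatment[k]),
                }
            )
    return pd.DataFrame(rows)


def cwres(fit: FitResult, data) -> np.ndarray:
    """Conditional weighted residuals (FOCE-style linearisation).

    Per study the linearised marginal distribution of y is
    ``N(f(eta_hat) - G eta_hat, G Omega G^T + diag(v))``; residuals are
    decorrelated with the Cholesky factor of that covariance.  With all
    omegas zero this reduces to (obs - pred) * sqrt(N/100) / sigma.
    """
    if not fit.converged:
        raise ValueError("cwres requires a converged fit")
    params = fit.params
    _, w2 = _active_dims(params)
    out = []
    for s in data:
        y = np.asarray(s.effect_net_pct, float)
        n = np.asarray(s.n_treatment, float)
        v = params.sigma**2 / (n / 100.0)
        eta_full = fit.eta_modes.get(s.study_id, (0.0, 0.0))
        _, f_ind, G, eta, dims = _study_curves(params, s, eta_full)
        if dims:
            cov = G @ np.diag(w2) @ G.T + np.diag(v)
            mean = f_ind - G @ eta
        else:
            cov = np.diag(v)
            mean = f_ind
        try:
            L = linalg.cholesky(cov, lower=True)
        except linalg.LinAlgError as exc:
            raise linalg.LinAlgError(
                f"singular model covariance in study {s.study_id!r}"
            ) from exc
        out.append(linalg.solve_triangular(L, y - mean, lower=True))
    return np.concatenate(out)


def _relabel(series: EffectSeries, new_id: str) -> EffectSeries:
    return EffectSeries(
        study_id=new_id,
        times_weeks=series.times_weeks,
        effect_sum_pct=series.effect_sum_pct,
        effect_control_pct=series.effect_control_pct,
        effect_net_pct=series.effect_net_pct,
        n_treatment=series.n_treatment,
        covariates=series.covariates,
    )


_BOOT_PARAMS = ("emax_pct", "et50_weeks", "omega_emax", "omega_et50", "sigma")


def bootstrap(
    data,
    fit: FitResult,
    n_replicates: int = 1000,
    seed: int = 20220810,
    settings: FitSettings | None = None,
) -> BootstrapSummary:
    """Nonparametric bootstrap with the study as the resampling unit.

    Each replicate resamples studies with replacement, refits the model
    (warm-started at the original estimates, single start, unless other
    ``settings`` are supplied) and records the parameter estimates;
    replicates that fail to converge are counted and excluded from the
    percentiles.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    data = list(data)
    n = len(data)
    rng = np.random.default_rng(seed)
    if settings is None:
        settings = FitSettings(single_start=True)
    estimates = {nm: getattr(fit.params, nm) for nm in _BOOT_PARAMS}
    draws: dict[str, list] = {nm: [] for nm in _BOOT_PARAMS}
    n_failed = 0
    for _ in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        resampled = [_relabel(data[j], f"{data[j].study_id}#{k}") for k, j in enumerate(idx)]
        try:
            fr = _fit(resampled, init=fit.params, settings=settings)
        except (ValueError, FloatingPointError, np.linalg.LinAlgError):
            n_failed += 1
            continue
        if not fr.converged:
            n_failed += 1
            continue
        for nm in _BOOT_PARAMS:
            draws[nm].append(getattr(fr.params, nm))
    n_ok = n_replicates - n_failed
    if n_ok == 0:
        raise RuntimeError("all bootstrap replicates failed to converge")
    if n_failed > 0.2 * n_replicates:
        logger.warning(
            "bootstrap: %d of %d replicates failed to converge", n_failed, n_replicates
        )
    parameters = {}
    for nm in _BOOT_PARAMS:
        arr = np.asarray(draws[nm])
        med = float(np.median(arr))
        lo, hi = np.percentile(arr, [2.5, 97.5])
        parameters[nm] = ParamSummary(
            estimate=float(estimates[nm]),
            median=med,
            ci_low=float(lo),
            ci_high=float(hi),
            bias=relative_bias(med, float(estimates[nm])),
        )
    return BootstrapSummary(parameters=parameters, n_replicates=n_replicates, n_failed=n_failed)


def draw_etas(params: EmaxParams, rng: np.random.Generator, max_tries: int = 1000):
    """One (eta_emax, eta_et50) draw honouring the eta forms and omegas.

    Additive draws that would push ET50 non-positive are rejected and
    redrawn.
    """
    for _ in range(max_tries):
        e1 = rng.normal(0.0, params.omega_emax) if params.omega_emax > 0 else 0.0
        e2 = rng.normal(0.0, params.omega_et50) if params.omega_et50 > 0 else 0.0
        if params.eta_form_et50 == "additive" and params.et50_weeks + e2 <= 0:
            continue
        return e1, e2
    raise RuntimeError("could not draw a valid eta (additive ET50 persistently <= 0)")


def pcvpc(fit: FitResult, data, n_sim: int = 1000, seed: int = 20220810) -> VpcResult:
    """Prediction-corrected visual predictive check.

    Simulates ``n_sim`` replicate datasets from the fitted model (fresh
    etas per study, fresh residuals per observation), prediction-corrects
    observed and simulated values multiplicatively by the ratio of the
    bin-median population prediction to each observation's population
    prediction (bins = unique observation times), and returns 2.5/50/97.5
    percentile bands with observed coverage of the 95% band.  A bin whose
    population predictions include zero switches to additive correction.
    """
    if not fit.converged:
        raise ValueError("pcvpc requires a converged fit")
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    data = list(data)
    params = fit.params
    rng = np.random.default_rng(seed)

    times = np.concatenate([np.asarray(s.times_weeks, float) for s in data])
    obs = np.concatenate([np.asarray(s.effect_net_pct, float) for s in data])
    pop = np.concatenate(
        [_study_curves(params, s, (0.0, 0.0))[0] for s in data]
    )
    bins = np.unique(times)
    bin_idx = np.searchsorted(bins, times)
    bin_median = np.array([np.median(pop[bin_idx == b]) for b in range(len(bins))])
    additive_bin = np.array(
        [np.any(pop[bin_idx == b] == 0.0) for b in range(len(bins))]
    )
    if additive_bin.any():
        logger.warning(
            "pcvpc: zero population prediction in bin(s) %s; using additive correction",
            bins[additive_bin],
        )

    def correct(values: np.ndarray) -> np.ndarray:
        out = np.empty_like(values)
        for b in range(len(bins)):
            m = bin_idx == b
            if additive_bin[b]:
                out[m] = values[m] - pop[m] + bin_median[b]
            else:
                out[m] = values[m] * bin_median[b] / pop[m]
        return out

    obs_corr = correct(obs)

    dims, _ = _active_dims(params)
    sim_corr = np.empty((n_sim, len(obs)))
    for r in range(n_sim):
        sim = np.empty(len(obs))
        pos = 0
        for s in data:
            t = np.asarray(s.times_weeks, float)
            nn = np.asarray(s.n_treatment, float)
            v = params.sigma**2 / (nn / 100.0)
            e1, e2 = draw_etas(params, rng)
            emax_tv, et50_tv = _typical(params, s.covariates)
            eta = np.array([(e1, e2)[d] for d in dims])
            f, _ = _curve(
                emax_tv, et50_tv, params.eta_form_emax, params.eta_form_et50, dims, eta, t
            )
            sim[pos : pos + len(t)] = f + rng.normal(0.0, np.sqrt(v))
            pos += len(t)
        sim_corr[r] = correct(sim)

    p2_5 = np.empty(len(bins))
    p50 = np.empty(len(bins))
    p97_5 = np.empty(len(bins))
    observed = []
    inside = 0
    for b in range(len(bins)):
        m = bin_idx == b
        pooled = sim_corr[:, m].ravel()
        lo, mid, hi = np.percentile(pooled, [2.5, 50.0, 97.5])
        p2_5[b], p50[b], p97_5[b] = lo, mid, hi
        observed.append(obs_corr[m])
        inside += int(np.sum((obs_corr[m] >= lo) & (obs_corr[m] <= hi)))
    coverage = inside / len(obs)
    return VpcResult(
        bins=bins,
        sim_p2_5=p2_5,
        sim_p50=p50,
        sim_p97_5=p97_5,
        observed=observed,
        coverage=float(coverage),
    )
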