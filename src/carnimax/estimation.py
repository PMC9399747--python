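"""Marginal maximum-likelihood estimation of the Emax mixed-effects model.

Observations are study-level net effects y_ij (percent change, control
corrected) with residual variance sigma^2 / (N_ij / 100), so that an arm
of 100 subjects has residual SD exactly sigma.  Study-level random
effects eta on Emax and ET50 are integrated out per study by a Laplace
approximation (damped Newton inner optimisation over <= 2 etas with the
exact analytic Hessian of the joint negative log-density); an adaptive
Gauss-Hermite quadrature routine is provided as an independent numerical
cross-check.

The objective function value (OFV) is -2 x the marginal log-likelihood;
differences between nested models are compared with chi-square quantiles
(likelihood-ratio test) during stepwise covariate selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats

from .aggregate_data import EffectSeries
from .structural import CovariateEffect, EmaxParams, apply_covariate

__all__ = [
    "FitResult",
    "FitSettings",
    "objective",
    "objective_agq",
    "evaluate",
    "fit",
    "lrt_threshold",
    "covariate_step",
    "FORWARD_THRESHOLD",
    "BACKWARD_THRESHOLD",
]

LOG2PI = math.log(2.0 * math.pi)
_OMEGA_ACTIVE = 1e-10  # below this an omega is treated as exactly zero
FORWARD_THRESHOLD = 3.84
BACKWARD_THRESHOLD = 6.63


@dataclass
class FitSettings:
    """Optimiser configuration for :func:`fit`.

    The default multi-start grid is deterministic; ``single_start`` fits
    from the supplied initial values only (used for warm-started refits in
    covariate selection and bootstrap).
    """

    starts_emax: tuple = (-10.0, -4.0, -1.0)
    starts_et50: tuple = (1.0, 4.0, 10.0)
    single_start: bool = False
    fix_omega_emax: bool = False
    fix_omega_et50: bool = False
    maxiter: int = 500
    ftol: float = 1e-8  # relative OFV tolerance
    xtol: float = 1e-6  # parameter tolerance (pgtol proxy)


@dataclass
class FitResult:
    """Outcome of a model fit: estimates, OFV and diagnostics."""

    params: EmaxParams
    ofv: float
    converged: bool
    n_obs: int
    n_studies: int
    eta_modes: dict = field(default_factory=dict)
    selection_trace: list = field(default_factory=list)
    message: str = ""
    start_ofvs: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "ofv": self.ofv,
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_studies": self.n_studies,
            "eta_modes": {k: list(v) for k, v in self.eta_modes.items()},
            "selection_trace": self.selection_trace,
            "message": self.message,
            "start_ofvs": self.start_ofvs,
        }


# ---------------------------------------------------------------------------
# per-study machinery


def _typical(params: EmaxParams, covariates) -> tuple[float, float]:
    adj = apply_covariate(params, covariates) if params.theta_cor else params
    return adj.emax_pct, adj.et50_weeks


def _active_dims(params: EmaxParams) -> tuple[list[int], np.ndarray]:
    """Random-effect dimensions in play: 0 = Emax, 1 = ET50."""
    dims, w2 = [], []
    if params.omega_emax > _OMEGA_ACTIVE and params.eta_form_emax != "none":
        dims.append(0)
        w2.append(params.omega_emax**2)
    if params.omega_et50 > _OMEGA_ACTIVE and params.eta_form_et50 != "none":
        dims.append(1)
        w2.append(params.omega_et50**2)
    return dims, np.asarray(w2)


def _curve(emax_tv, et50_tv, form_emax, form_et50, dims, eta, t):
    """Study-level curve f(t) and its Jacobian w.r.t. the active etas.

    Returns (f, J) or (None, None) when an additive eta pushes ET50 <= 0.
    """
    e1 = e2 = 0.0
    for k, d in enumerate(dims):
        if d == 0:
            e1 = eta[k]
        else:
            e2 = eta[k]
    if form_emax == "exponential":
        a = emax_tv * math.exp(e1)
        da = a
    elif form_emax == "additive":
        a = emax_tv + e1
        da = 1.0
    else:
        a, da = emax_tv, 0.0
    if form_et50 == "exponential":
        b = et50_tv * math.exp(e2)
        db = b
    elif form_et50 == "additive":
        b = et50_tv + e2
        db = 1.0
    else:
        b, db = et50_tv, 0.0
    if b <= 0:
        return None, None
    denom = b + t
    f = a * t / denom
    cols = []
    for d in dims:
        if d == 0:
            cols.append(da * t / denom)
        else:
            cols.append(-f / denom * db)
    J = np.stack(cols, axis=1) if cols else np.empty((len(t), 0))
    return f, J


def _penalised_ssq(emax_tv, et50_tv, params, dims, w2, eta, t, y, v):
    f, _ = _curve(emax_tv, et50_tv, params.eta_form_emax, params.eta_form_et50, dims, eta, t)
    if f is None:
        return math.inf
    r = y - f
    q = float(np.sum(r * r / v))
    if len(dims):
        q += float(np.sum(eta * eta / w2))
    return q


def _half_grad(emax_tv, et50_tv, params, dims, w2, eta, t, y, v):
    """Gradient of g/2 where g = -2 log[p(y|eta) p(eta)] (constants drop)."""
    f, J = _curve(emax_tv, et50_tv, params.eta_form_emax, params.eta_form_et50, dims, eta, t)
    if f is None:
        raise FloatingPointError("curve undefined at eta")
    r = y - f
    return -(J.T @ (r / v)) + eta / w2


def _eta_mode(emax_tv, et50_tv, params, dims, w2, t, y, v, eta0=None):
    """Newton (Gauss-Newton Hessian, backtracking) mode of the joint density."""
    d = len(dims)
    eta = np.zeros(d) if eta0 is None else np.array(eta0, float)
    q = _penalised_ssq(emax_tv, et50_tv, params, dims, w2, eta, t, y, v)
    if not math.isfinite(q):
        eta = np.zeros(d)
        q = _penalised_ssq(emax_tv, et50_tv, params, dims, w2, eta, t, y, v)
    for _ in range(80):
        f, J = _curve(
            emax_tv, et50_tv, params.eta_form_emax, params.eta_form_et50, dims, eta, t
        )
        r = y - f
        grad = -2.0 * (J.T @ (r / v)) + 2.0 * eta / w2
        if np.max(np.abs(grad)) < 1e-10 * (1.0 + abs(q)):
            break
        H = 2.0 * (J.T @ (J / v[:, None])) + 2.0 * np.diag(1.0 / w2)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = grad / np.diag(H)
        alpha, accepted = 1.0, False
        for _ in range(40):
            cand = eta - alpha * step
            qc = _penalised_ssq(emax_tv, et50_tv, params, dims, w2, cand, t, y, v)
            if qc < q:
                eta, q, accepted = cand, qc, True
                break
            alpha *= 0.5
        if not accepted:
            break
    return eta, q


def _half_hessian(emax_tv, et50_tv, params, dims, w2, eta, t, y, v):
    """Central finite-difference Hessian of g/2 from the analytic gradient."""
    d = len(dims)
    H = np.empty((d, d))
    for k in range(d):
        h = 1e-5 * (1.0 + abs(eta[k]))
        ep = eta.copy()
        ep[k] += h
        em = eta.copy()
        em[k] -= h
        gp = _half_grad(emax_tv, et50_tv, params, dims, w2, ep, t, y, v)
        gm = _half_grad(emax_tv, et50_tv, params, dims, w2, em, t, y, v)
        H[:, k] = (gp - gm) / (2.0 * h)
    return 0.5 * (H + H.T)


def _gauss_newton_half_hessian(emax_tv, et50_tv, params, dims, w2, eta, t, y, v):
    f, J = _curve(
        emax_tv, et50_tv, params.eta_form_emax, params.eta_form_et50, dims, eta, t
    )
    return J.T @ (J / v[:, None]) + np.diag(1.0 / w2)


class _StudyEval:
    """Pre-extracted arrays for fast repeated likelihood evaluation."""

    __slots__ = ("sid", "t", "y", "n100", "cov", "eta_cache")

    def __init__(self, series: EffectSeries):
        self.sid = series.study_id
        self.t = np.asarray(series.times_weeks, float)
        self.y = np.asarray(series.effect_net_pct, float)
        self.n100 = np.asarray(series.n_treatment, float) / 100.0
        self.cov = series.covariates
        self.eta_cache = None


def _ab(a_tv, b_tv, fa, fb, e1, e2):
    """Study-level (Emax_i, ET50_i) and their eta derivatives; None if invalid."""
    if abs(e1) > 200.0 or abs(e2) > 200.0:  # keeps exp() and its powers finite
        return None
    if fa == "exponential":
        a = a_tv * math.exp(e1)
        da = a
    elif fa == "additive":
        a = a_tv + e1
        da = 1.0
    else:
        a, da = a_tv, 0.0
    if fb == "exponential":
        b = b_tv * math.exp(e2)
        db = b
    elif fb == "additive":
        b = b_tv + e2
        db = 1.0
    else:
        b, db = b_tv, 0.0
    if b <= 0 or not (math.isfinite(a) and math.isfinite(b)):
        return None
    return a, da, b, db


def _deriv_factors(value, form):
    """(level, d/deta, d2/deta2) of the eta-shifted parameter."""
    if form == "exponential":
        return value, value, value
    if form == "additive":
        return value, 1.0, 0.0
    return value, 0.0, 0.0


def _mode_fast(a_tv, b_tv, fa, fb, dims, w2, t, y, v, eta0):
    """Inner Newton on <= 2 etas with the exact analytic Hessian.

    Returns (eta, q) with q the penalised weighted sum of squares at the
    mode, or q = inf when no valid point exists.  Falls back to the
    Gauss-Newton Hessian whenever the exact one is not positive definite.
    """
    d = len(dims)
    ia = dims.index(0) if 0 in dims else None
    ib = dims.index(1) if 1 in dims else None
    eta = np.zeros(d) if eta0 is None else np.array(eta0, float)

    def qval(eta_):
        e1 = eta_[ia] if ia is not None else 0.0
        e2 = eta_[ib] if ib is not None else 0.0
        ab = _ab(a_tv, b_tv, fa, fb, e1, e2)
        if ab is None:
            return math.inf
        a, _, b, _ = ab
        r = y - a * t / (b + t)
        return float(np.dot(r / v, r)) + float(np.dot(eta_ * eta_, 1.0 / w2))

    q = qval(eta)
    if not math.isfinite(q):
        eta = np.zeros(d)
        q = qval(eta)
    for it in range(60):
        e1 = eta[ia] if ia is not None else 0.0
        e2 = eta[ib] if ib is not None else 0.0
        grad, H, Hgn = _grad_hess(a_tv, b_tv, fa, fb, ia, ib, d, w2, e1, e2, t, y, v)
        if np.max(np.abs(grad)) < 1e-10 * (1.0 + abs(q)):
            break
        step = _newton_step(grad, H, d)
        if step is None:
            step = _newton_step(grad, Hgn, d)
            if step is None:
                step = grad / np.abs(np.diag(Hgn))
        alpha, accepted, drop = 1.0, False, 0.0
        for _ in range(25):
            cand = eta - alpha * step
            qc = qval(cand)
            if qc < q:
                drop = q - qc
                eta, q, accepted = cand, qc, True
                break
            alpha *= 0.5
        if not accepted or drop < 1e-15 * (1.0 + abs(q)):
            break
    return eta, q


def _grad_hess(a_tv, b_tv, fa, fb, ia, ib, d, w2, e1, e2, t, y, v):
    """Gradient and exact/Gauss-Newton Hessians of the penalised SSQ.

    Second derivatives of f = A(eta1) * g(B(eta2)) with g = t/(B+t):
    f_11 = A'' g, f_12 = A' g' B', f_22 = A (g'' B'^2 + g' B'').
    """
    a, da, d2a = _deriv_factors(
        a_tv * math.exp(e1) if fa == "exponential" else (a_tv + e1 if fa == "additive" else a_tv),
        fa,
    )
    b, db, d2b = _deriv_factors(
        b_tv * math.exp(e2) if fb == "exponential" else (b_tv + e2 if fb == "additive" else b_tv),
        fb,
    )
    denom = b + t
    g = t / denom
    gp = -t / denom**2
    gpp = 2.0 * t / denom**3
    f = a * g
    r = y - f
    rv = r / v
    grad = np.empty(d)
    H = np.empty((d, d))
    Hgn = np.empty((d, d))
    if ia is not None:
        j1 = da * g
        grad[ia] = -2.0 * float(np.dot(j1, rv)) + 2.0 * e1 / w2[ia]
        Hgn[ia, ia] = 2.0 * float(np.dot(j1, j1 / v)) + 2.0 / w2[ia]
        H[ia, ia] = Hgn[ia, ia] - 2.0 * float(np.dot(rv, d2a * g))
    if ib is not None:
        j2 = a * gp * db
        grad[ib] = -2.0 * float(np.dot(j2, rv)) + 2.0 * e2 / w2[ib]
        Hgn[ib, ib] = 2.0 * float(np.dot(j2, j2 / v)) + 2.0 / w2[ib]
        f22 = a * (gpp * db * db + gp * d2b)
        H[ib, ib] = Hgn[ib, ib] - 2.0 * float(np.dot(rv, f22))
    if ia is not None and ib is not None:
        cross = 2.0 * float(np.dot(j1, j2 / v))
        Hgn[ia, ib] = Hgn[ib, ia] = cross
        f12 = da * gp * db
        H[ia, ib] = H[ib, ia] = cross - 2.0 * float(np.dot(rv, f12))
    return grad, H, Hgn


def _newton_step(grad, H, d):
    if d == 1:
        return grad / H[0, 0] if H[0, 0] > 0 else None
    det = H[0, 0] * H[1, 1] - H[0, 1] * H[1, 0]
    if det <= 0 or H[0, 0] <= 0:
        return None
    return (
        np.array(
            [
                H[1, 1] * grad[0] - H[0, 1] * grad[1],
                H[0, 0] * grad[1] - H[1, 0] * grad[0],
            ]
        )
        / det
    )


def _study_ofv_laplace(params, se, use_cache: bool = False):
    if isinstance(se, EffectSeries):
        se = _StudyEval(se)
    v = params.sigma**2 / se.n100
    emax_tv, et50_tv = _typical(params, se.cov)
    if et50_tv <= 0:
        raise ValueError(f"study {se.sid!r}: typical ET50 <= 0")
    dims, w2 = _active_dims(params)
    fa, fb = params.eta_form_emax, params.eta_form_et50
    const_res = float(np.sum(np.log(2.0 * math.pi * v)))
    if not dims:
        f = emax_tv * se.t / (et50_tv + se.t)
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(f"non-finite prediction in study {se.sid!r}")
        r = se.y - f
        return const_res + float(np.dot(r / v, r)), np.empty(0)
    eta0 = se.eta_cache if use_cache and se.eta_cache is not None and len(se.eta_cache) == len(dims) else None
    eta_hat, q = _mode_fast(emax_tv, et50_tv, fa, fb, dims, w2, se.t, se.y, v, eta0)
    if use_cache:
        se.eta_cache = eta_hat
    if not math.isfinite(q):
        raise FloatingPointError(f"non-finite joint density in study {se.sid!r}")
    g_min = q + const_res + float(np.sum(np.log(2.0 * math.pi * w2)))
    d = len(dims)
    ia = dims.index(0) if 0 in dims else None
    ib = dims.index(1) if 1 in dims else None
    e1 = eta_hat[ia] if ia is not None else 0.0
    e2 = eta_hat[ib] if ib is not None else 0.0
    _, Hq, Hq_gn = _grad_hess(
        emax_tv, et50_tv, fa, fb, ia, ib, d, w2, e1, e2, se.t, se.y, v
    )
    # Hessian of g/2 is half the penalised-SSQ Hessian; use the exact one
    # when positive definite, Gauss-Newton otherwise (flat or saddle mode)
    sign, logdet = np.linalg.slogdet(0.5 * Hq)
    if sign <= 0:
        sign, logdet = np.linalg.slogdet(0.5 * Hq_gn)
    ofv = g_min - d * LOG2PI + logdet
    return ofv, eta_hat


def objective(params: EmaxParams, data) -> float:
    """OFV = -2 x marginal log-likelihood of the data under ``params``.

    With both omegas zero this reduces exactly to the sample-size-weighted
    residual closed form
    ``sum_ij [ log(2 pi sigma^2/(N/100)) + r_ij^2 (N/100) / sigma^2 ]``.
    """
    data = list(data)
    if not data:
        raise ValueError("data must contain at least one effect series")
    return float(sum(_study_ofv_laplace(params, s)[0] for s in data))


def eta_modes(params: EmaxParams, data) -> dict:
    """Empirical-Bayes eta modes per study, padded as (eta_emax, eta_et50)."""
    dims, _ = _active_dims(params)
    out = {}
    for s in data:
        _, eta_hat = _study_ofv_laplace(params, s)
        full = [0.0, 0.0]
        for k, d in enumerate(dims):
            full[d] = float(eta_hat[k])
        out[s.study_id] = tuple(full)
    return out


def evaluate(params: EmaxParams, data) -> FitResult:
    """Wrap fixed parameters as a converged :class:`FitResult`.

    Computes the OFV and empirical-Bayes eta modes without optimising;
    useful for diagnostics under known (e.g. simulated-truth) parameters.
    """
    data = list(data)
    return FitResult(
        params=params,
        ofv=objective(params, data),
        converged=True,
        n_obs=int(sum(len(s) for s in data)),
        n_studies=len(data),
        eta_modes=eta_modes(params, data),
    )


def objective_agq(params: EmaxParams, data, n_nodes: int = 41) -> float:
    """OFV by adaptive Gauss-Hermite quadrature (numerical cross-check).

    Nodes are centred on the per-study mode and scaled by the inverse
    Cholesky factor of the Hessian; tensor-product rule in two dimensions.
    """
    x, w = np.polynomial.hermite.hermgauss(n_nodes)
    logw = np.log(w)
    total = 0.0
    for s in data:
        t = np.asarray(s.times_weeks, float)
        y = np.asarray(s.effect_net_pct, float)
        n = np.asarray(s.n_treatment, float)
        v = params.sigma**2 / (n / 100.0)
        emax_tv, et50_tv = _typical(params, s.covariates)
        dims, w2 = _active_dims(params)
        const_res = float(np.sum(np.log(2.0 * math.pi * v)))
        if not dims:
            f, _ = _curve(emax_tv, et50_tv, params.eta_form_emax, params.eta_form_et50, [], np.empty(0), t)
            r = y - f
            total += const_res + float(np.sum(r * r / v))
            continue
        d = len(dims)
        eta_hat, _ = _eta_mode(emax_tv, et50_tv, params, dims, w2, t, y, v)
        H = _half_hessian(emax_tv, et50_tv, params, dims, w2, eta_hat, t, y, v)
        if np.linalg.slogdet(H)[0] <= 0:
            H = _gauss_newton_half_hessian(emax_tv, et50_tv, params, dims, w2, eta_hat, t, y, v)
        L = np.linalg.cholesky(H)
        # B B^T = H^{-1}; eta = eta_hat + sqrt(2) B xk
        B = np.linalg.inv(L).T
        log_det_B = -float(np.sum(np.log(np.diag(L))))
        if d == 1:
            nodes = x[:, None]
            lw = logw
        else:
            g1, g2 = np.meshgrid(np.arange(n_nodes), np.arange(n_nodes), indexing="ij")
            nodes = np.stack([x[g1.ravel()], x[g2.ravel()]], axis=1)
            lw = logw[g1.ravel()] + logw[g2.ravel()]
        const_eta = float(np.sum(np.log(2.0 * math.pi * w2)))
        vals = np.empty(len(nodes))
        for k, xk in enumerate(nodes):
            eta = eta_hat + math.sqrt(2.0) * (B @ xk)
            q = _penalised_ssq(emax_tv, et50_tv, params, dims, w2, eta, t, y, v)
            if math.isinf(q):
                vals[k] = -np.inf
                continue
            g = q + const_res + const_eta
            vals[k] = lw[k] + float(np.sum(xk * xk)) - 0.5 * g
        m = np.max(vals)
        log_int = (
            0.5 * d * math.log(2.0)
            + log_det_B
            + m
            + math.log(np.sum(np.exp(vals - m)))
        )
        total += -2.0 * log_int
    return float(total)


# ---------------------------------------------------------------------------
# population fitting


_BOUNDS = {
    "emax_pct": (-100.0, 100.0),
    "et50_weeks": (1e-3, 500.0),
    "omega_emax": (0.0, 10.0),
    "omega_et50": (0.0, 10.0),
    "sigma": (1e-4, 100.0),
    "theta": (-50.0, 50.0),
}


def _free_names(init: EmaxParams, settings: FitSettings) -> list[str]:
    names = ["emax_pct", "et50_weeks"]
    if not settings.fix_omega_emax:
        names.append("omega_emax")
    if not settings.fix_omega_et50:
        names.append("omega_et50")
    names.append("sigma")
    names.extend(f"theta:{c}" for c in init.theta_cor)
    return names


def _pack(params: EmaxParams, names) -> np.ndarray:
    vals = []
    for nm in names:
        if nm.startswith("theta:"):
            vals.append(params.theta_cor[nm.split(":", 1)[1]].coefficient)
        else:
            vals.append(getattr(params, nm))
    return np.asarray(vals, float)


def _unpack(x: np.ndarray, template: EmaxParams, names) -> EmaxParams:
    kw = {}
    theta = dict(template.theta_cor)
    for nm, val in zip(names, x):
        if nm.startswith("theta:"):
            cname = nm.split(":", 1)[1]
            theta[cname] = replace(theta[cname], coefficient=float(val))
        else:
            kw[nm] = float(val)
    # clip away from invalid interior values the optimiser may probe
    if "et50_weeks" in kw:
        kw["et50_weeks"] = max(kw["et50_weeks"], 1e-6)
    if "sigma" in kw:
        kw["sigma"] = max(kw["sigma"], 1e-8)
    return template.replace(theta_cor=theta, **kw)


def fit(data, init: EmaxParams | None = None, settings: FitSettings | None = None) -> FitResult:
    """Fit the Emax mixed-effects model by marginal maximum likelihood.

    Minimises :func:`objective` over (Emax, ET50, omegas, sigma) and any
    covariate coefficients carried by ``init.theta_cor``, from a
    deterministic multi-start grid, with a bounded quasi-Newton optimiser
    (L-BFGS-B).  Returns the best converged start.
    """
    data = list(data)
    n_studies = len(data)
    if n_studies < 2:
        raise ValueError(
            "at least 2 studies are required: inter-study variability is not "
            "identifiable from a single study"
        )
    n_obs = int(sum(len(s) for s in data))
    settings = settings or FitSettings()
    if init is None:
        init = EmaxParams(
            emax_pct=-4.0, et50_weeks=4.0, omega_emax=0.1, omega_et50=0.1, sigma=0.5
        )
    names = _free_names(init, settings)
    bounds = [
        _BOUNDS["theta"] if nm.startswith("theta:") else _BOUNDS[nm] for nm in names
    ]

    if settings.single_start:
        starts = [(init.emax_pct, init.et50_weeks)]
    else:
        starts = [(e, t) for e in settings.starts_emax for t in settings.starts_et50]

    evals = [_StudyEval(s) for s in data]

    def wrapped(x):
        try:
            p = _unpack(x, init, names)
            val = float(sum(_study_ofv_laplace(p, se, use_cache=True)[0] for se in evals))
        except (FloatingPointError, np.linalg.LinAlgError, ValueError, OverflowError):
            return 1e12
        if not math.isfinite(val):
            return 1e12
        return val

    best = None
    start_ofvs = []
    for emax0, et500 in starts:
        x0 = _pack(init.replace(emax_pct=emax0, et50_weeks=et500), names)
        res = optimize.minimize(
            wrapped,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": settings.maxiter,
                "ftol": settings.ftol,
                "gtol": settings.xtol,
                # FD step large enough that inner-optimisation noise in the
                # objective does not corrupt the numerical gradient
                "eps": 1e-6,
            },
        )
        start_ofvs.append(
            {"start": (emax0, et500), "ofv": float(res.fun), "converged": bool(res.success)}
        )
        if best is None or _better(res, best):
            best = res
    assert best is not None
    params = _unpack(best.x, init, names)
    converged = bool(best.success) and best.fun < 1e11
    modes = eta_modes(params, data) if converged else {}
    return FitResult(
        params=params,
        ofv=float(best.fun),
        converged=converged,
        n_obs=n_obs,
        n_studies=n_studies,
        eta_modes=modes,
        message=str(best.message),
        start_ofvs=start_ofvs,
    )


def _better(res, best) -> bool:
    if res.success and not best.success:
        return True
    if best.success and not res.success:
        return False
    return res.fun < best.fun


def lrt_threshold(alpha: float, df: int) -> float:
    """Chi-square upper-alpha quantile, rounded to the 2-decimal cutoffs
    conventionally quoted for likelihood-ratio model comparison
    (3.84 at alpha = 0.05, 6.63 at alpha = 0.01, df = 1)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if df < 1 or int(df) != df:
        raise ValueError("df must be a positive integer")
    return round(float(stats.chi2.isf(alpha, df)), 2)


def _candidate_params(base: EmaxParams, data, cov, param, relation) -> EmaxParams:
    median = None
    if relation in ("additive_centered", "power_centered"):
        median = float(np.median([s.covariates[cov] for s in data]))
    theta = dict(base.theta_cor)
    key = cov if cov not in theta else f"{cov}@{param}"
    theta[key] = CovariateEffect(
        0.0, parameter=param, relation=relation, median=median, covariate=cov
    )
    return base.replace(theta_cor=theta), key


def covariate_step(data, base: FitResult, candidates, settings: FitSettings | None = None) -> FitResult:
    """Stepwise covariate selection by OFV change.

    Forward: each (covariate, parameter, relation) candidate is added to
    the current model one at a time; the largest OFV drop wins if it
    exceeds 3.84 (chi-square, alpha = 0.05, df = 1); iterate until no
    candidate qualifies.  Ties are broken by candidate list order.
    Backward: each included covariate is retained only if its removal
    raises the OFV by more than 6.63 (alpha = 0.01, df = 1).
    Every tested delta is recorded in the selection trace.
    """
    data = list(data)
    for cov, param, relation in candidates:
        for s in data:
            if cov not in s.covariates:
                raise KeyError(
                    f"candidate covariate {cov!r} missing from study {s.study_id!r}"
                )
    settings = settings or FitSettings()
    warm = replace(settings, single_start=True)

    trace: list[dict] = []
    current = base
    included: list[tuple] = []  # (key, cov, param, relation)
    remaining = list(candidates)

    while remaining:
        tested = []
        for cand in remaining:
            cov, param, relation = cand
            cand_init, key = _candidate_params(current.params, data, cov, param, relation)
            fr = fit(data, init=cand_init, settings=warm)
            delta = current.ofv - fr.ofv
            tested.append((delta, cand, key, fr))
            trace.append(
                {
                    "step": "forward",
                    "covariate": cov,
                    "parameter": param,
                    "relation": relation,
                    "delta_ofv": float(delta),
                    "decision": "tested",
                }
            )
        best_delta, best_cand, best_key, best_fit = tested[0]
        for delta, cand, key, fr in tested[1:]:
            if delta > best_delta:  # strict: ties keep the earlier candidate
                best_delta, best_cand, best_key, best_fit = delta, cand, key, fr
        if best_delta > FORWARD_THRESHOLD and best_fit.converged:
            trace.append(
                {
                    "step": "forward",
                    "covariate": best_cand[0],
                    "parameter": best_cand[1],
                    "relation": best_cand[2],
                    "delta_ofv": float(best_delta),
                    "decision": "included",
                }
            )
            included.append((best_key, *best_cand))
            current = best_fit
            remaining = [c for c in remaining if c != best_cand]
        else:
            break

    for key, cov, param, relation in list(included):
        reduced_theta = {k: v for k, v in current.params.theta_cor.items() if k != key}
        reduced_init = current.params.replace(theta_cor=reduced_theta)
        fr = fit(data, init=reduced_init, settings=warm)
        delta_rm = fr.ofv - current.ofv
        keep = delta_rm > BACKWARD_THRESHOLD
        trace.append(
            {
                "step": "backward",
                "covariate": cov,
                "parameter": param,
                "relation": relation,
                "delta_ofv": float(delta_rm),
                "decision": "retained" if keep else "removed",
            }
        )
        if not keep:
            included = [e for e in included if e[0] != key]
            current = fr

    return FitResult(
        params=current.params,
        ofv=current.ofv,
        converged=current.converged,
        n_obs=current.n_obs,
        n_studies=current.n_studies,
        eta_modes=current.eta_modes,
        selection_trace=trace,
        message=current.message,
        start_ofvs=current.start_ofvs,
    )
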