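"""Saturating (Emax) time-course model with study-level random effects.

The structural model for the net treatment effect (percent change from
baseline, control-corrected) at treatment duration ``t`` weeks is

    E(t) = Emax * t / (ET50 + t)

where ``Emax`` is the asymptotic maximal effect (negative for weight loss,
on the x100 percent scale: -3.92 means -3.92%) and ``ET50`` is the
treatment duration at which half of Emax is reached.

Between-study variability enters through normally distributed random
effects eta on Emax and/or ET50, either exponentially
(``P_i = P * exp(eta)``) or additively (``P_i = P + eta``).  Covariates
adjust the typical parameter values through additive (categorical),
centred-additive or centred-power relations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "EmaxParams",
    "CovariateEffect",
    "MilestoneTable",
    "emax_effect",
    "apply_eta",
    "apply_covariate",
    "time_to_fraction",
    "milestone_table",
]

ETA_FORMS = ("exponential", "additive", "none")
COVARIATE_RELATIONS = ("additive_categorical", "additive_centered", "power_centered")


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relation with its correction coefficient.

    ``parameter`` is ``"emax"`` or ``"et50"``; ``median`` is the population
    median of the covariate, required by the centred relations.
    """

    coefficient: float
    parameter: str
    relation: str
    median: float | None = None
    covariate: str | None = None  # defaults to the theta_cor key

    def __post_init__(self) -> None:
        if self.parameter not in ("emax", "et50"):
            raise ValueError(f"unknown target parameter {self.parameter!r}")
        if self.relation not in COVARIATE_RELATIONS:
            raise ValueError(f"unknown covariate relation {self.relation!r}")


@dataclass(frozen=True)
class EmaxParams:
    """Population parameters of the Emax time-course model.

    ``omega_emax``/``omega_et50`` are the standard deviations of the
    study-level random effects; ``sigma`` is the residual standard
    deviation on the percent scale for an arm of 100 subjects (the
    residual variance of an arm of N subjects is ``sigma**2 / (N/100)``).
    """

    emax_pct: float
    et50_weeks: float
    omega_emax: float = 0.0
    omega_et50: float = 0.0
    sigma: float = 0.1
    eta_form_emax: str = "exponential"
    eta_form_et50: str = "exponential"
    theta_cor: Mapping[str, CovariateEffect] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.et50_weeks <= 0:
            raise ValueError("et50_weeks must be positive")
        if self.omega_emax < 0 or self.omega_et50 < 0:
            raise ValueError("omega values must be non-negative")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.eta_form_emax not in ETA_FORMS or self.eta_form_et50 not in ETA_FORMS:
            raise ValueError(f"eta forms must be one of {ETA_FORMS}")

    def replace(self, **kwargs) -> "EmaxParams":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = {
            "emax_pct": self.emax_pct,
            "et50_weeks": self.et50_weeks,
            "omega_emax": self.omega_emax,
            "omega_et50": self.omega_et50,
            "sigma": self.sigma,
            "eta_form_emax": self.eta_form_emax,
            "eta_form_et50": self.eta_form_et50,
        }
        if self.theta_cor:
            d["theta_cor"] = {
                name: {
                    "coefficient": eff.coefficient,
                    "parameter": eff.parameter,
                    "relation": eff.relation,
                    "median": eff.median,
                    "covariate": eff.covariate,
                }
                for name, eff in self.theta_cor.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "EmaxParams":
        theta = {
            name: CovariateEffect(**spec) for name, spec in d.get("theta_cor", {}).items()
        }
        return cls(
            emax_pct=float(d["emax_pct"]),
            et50_weeks=float(d["et50_weeks"]),
            omega_emax=float(d.get("omega_emax", 0.0)),
            omega_et50=float(d.get("omega_et50", 0.0)),
            sigma=float(d.get("sigma", 0.1)),
            eta_form_emax=d.get("eta_form_emax", "exponential"),
            eta_form_et50=d.get("eta_form_et50", "exponential"),
            theta_cor=theta,
        )


@dataclass(frozen=True)
class MilestoneTable:
    """Treatment durations needed to reach given fractions of Emax."""

    fractions: tuple
    times_weeks: tuple

    def __post_init__(self) -> None:
        if len(self.fractions) != len(self.times_weeks):
            raise ValueError("fractions and times must have equal length")
        t = np.asarray(self.times_weeks)
        if np.any(np.diff(t) <= 0) and len(t) > 1:
            raise ValueError("milestone times must be strictly increasing")


def emax_effect(params: EmaxParams, time_weeks) -> np.ndarray | float:
    """Structural effect Emax * t / (ET50 + t) at time(s) ``time_weeks``.

    Returns 0 at t = 0 and tends to ``emax_pct`` as t grows; accepts a
    scalar or an array of non-negative times.
    """
    t = np.asarray(time_weeks, dtype=float)
    if np.any(t < 0):
        raise ValueError("time_weeks must be non-negative")
    out = params.emax_pct * t / (params.et50_weeks + t)
    if np.isscalar(time_weeks):
        return float(out)
    return out


def _shift(value: float, eta: float, form: str) -> float:
    if form == "exponential":
        return value * math.exp(eta)
    if form == "additive":
        return value + eta
    return value  # "none"


def apply_eta(params: EmaxParams, eta_emax: float, eta_et50: float) -> EmaxParams:
    """Study-level parameters from population values and random effects.

    Exponential form multiplies by exp(eta); additive form adds eta.  An
    additive eta that drives ET50 non-positive is rejected with
    ``ValueError`` (the caller decides whether to resample or abort).
    """
    emax_i = _shift(params.emax_pct, eta_emax, params.eta_form_emax)
    et50_i = _shift(params.et50_weeks, eta_et50, params.eta_form_et50)
    if et50_i <= 0:
        raise ValueError(
            f"eta {eta_et50:g} drives ET50 to {et50_i:g} <= 0 under additive form"
        )
    return params.replace(emax_pct=emax_i, et50_weeks=et50_i)


def apply_covariate(params: EmaxParams, covariates: Mapping[str, float]) -> EmaxParams:
    """Adjust typical parameter values for a study's covariates.

    Relations: additive_categorical  P = Pv + COV * theta
               additive_centered     P = Pv + (COV - COVmed) * theta
               power_centered        P = Pv * (COV / COVmed) ** theta
    """
    emax = params.emax_pct
    et50 = params.et50_weeks
    for name, eff in params.theta_cor.items():
        cov_name = eff.covariate or name
        if cov_name not in covariates:
            raise KeyError(f"covariate {cov_name!r} missing from study covariates")
        value = float(covariates[cov_name])
        base = emax if eff.parameter == "emax" else et50
        if eff.relation == "additive_categorical":
            new = base + value * eff.coefficient
        elif eff.relation == "additive_centered":
            if eff.median is None:
                raise ValueError(f"covariate {name!r}: centred relation needs a median")
            new = base + (value - eff.median) * eff.coefficient
        else:  # power_centered
            if eff.median is None or eff.median <= 0:
                raise ValueError(
                    f"covariate {name!r}: power relation needs a positive median"
                )
            new = base * (value / eff.median) ** eff.coefficient
        if eff.parameter == "emax":
            emax = new
        else:
            et50 = new
    return params.replace(emax_pct=emax, et50_weeks=et50)


def time_to_fraction(et50_weeks: float, fraction: float) -> float:
    """Treatment duration at which the effect reaches ``fraction`` of Emax.

    Exact inverse of the saturating curve: t = ET50 * f / (1 - f).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    if et50_weeks <= 0:
        raise ValueError("et50_weeks must be positive")
    return et50_weeks * fraction / (1.0 - fraction)


def milestone_table(
    et50_weeks: float, fractions=(0.25, 0.50, 0.75, 0.80)
) -> MilestoneTable:
    """Milestone durations for a set of Emax fractions (default 25/50/75/80%)."""
    fr = tuple(sorted(float(f) for f in fractions))
    times = tuple(time_to_fraction(et50_weeks, f) for f in fr)
    return MilestoneTable(fractions=fr, times_weeks=times)
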