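"""Synthetic arm-level aggregate datasets for the meta-analysis pipeline.

The generator emulates the structure of a small literature-mined
meta-analysis of carnitine supplementation and body weight: a handful of
randomised studies, each contributing one treatment and one control arm
of mean body weights observed at baseline and a few follow-up visits over
12 weeks.  Mean weights are built from a percent-change decomposition —
a shared background drift in both arms (diet and other non-treatment
effects), a saturating Emax treatment effect with study-level random
effects, and residual noise whose variance scales inversely with arm
size (sigma^2 / (N/100)) — so that recomputing percent changes and
subtracting the control arm recovers the simulated net effect exactly.

The default design mirrors the meta-analytic setting the model targets:
4 studies, 242 patients in total, daily doses 250-1,000 mg, visits at
4/8/12 weeks, mean ages 23.6-30.8 years.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .aggregate_data import ArmRecord, write_table
from .diagnostics import draw_etas
from .structural import EmaxParams, apply_eta, emax_effect

__all__ = ["StudyTemplate", "SimConfig", "default_config", "generate", "write_fixture"]

DOSE_RANGE = (250.0, 1000.0)
AGE_RANGE = (23.6, 30.8)


@dataclass(frozen=True)
class StudyTemplate:
    """Design of one two-arm study: dose, arm sizes, baselines, age."""

    study_id: str
    dose_mg_per_day: float
    n_treatment: int
    n_control: int
    baseline_treatment_kg: float
    baseline_control_kg: float
    age_mean_years: float

    def __post_init__(self) -> None:
        if not DOSE_RANGE[0] <= self.dose_mg_per_day <= DOSE_RANGE[1]:
            raise ValueError(
                f"dose {self.dose_mg_per_day} outside the supported range {DOSE_RANGE}"
            )
        if self.n_treatment < 1 or self.n_control < 1:
            raise ValueError("arm sizes must be at least 1")
        if self.baseline_treatment_kg <= 0 or self.baseline_control_kg <= 0:
            raise ValueError("baseline weights must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Truth parameters plus the study-design template.

    ``control_drift_end_pct`` is the control arm's percent change at the
    final visit; the drift is linear in time.  The default truth is the
    final published-scale model: Emax = -3.92%, ET50 = 3.6 weeks,
    omega_Emax = 0.106, omega_ET50 = 0.867, sigma = 0.1 (residual SD for
    a 100-subject arm; variance 0.01).
    """

    truth: EmaxParams = field(
        default_factory=lambda: EmaxParams(
            emax_pct=-3.92,
            et50_weeks=3.6,
            omega_emax=0.106,
            omega_et50=0.867,
            sigma=0.1,
        )
    )
    studies: tuple = ()
    time_points_weeks: tuple = (0.0, 4.0, 8.0, 12.0)
    control_drift_end_pct: float = -1.0
    seed: int = 20220810

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.time_points_weeks)
        if 0.0 not in times or any(t < 0 for t in times):
            raise ValueError("time points must be non-negative and include 0")
        if len(set(times)) != len(times):
            raise ValueError("time points must be distinct")


_DEFAULT_STUDIES = (
    StudyTemplate("study_a", 250.0, 30, 30, 74.5, 75.2, 26.7),
    StudyTemplate("study_b", 500.0, 36, 35, 80.1, 79.4, 23.6),
    StudyTemplate("study_c", 750.0, 25, 24, 72.3, 71.8, 28.4),
    StudyTemplate("study_d", 1000.0, 31, 31, 77.0, 76.5, 30.8),
)


def default_config(seed: int = 20220810, truth: EmaxParams | None = None) -> SimConfig:
    """The default 4-study, 242-patient design template."""
    kwargs = {"studies": _DEFAULT_STUDIES, "seed": seed}
    if truth is not None:
        kwargs["truth"] = truth
    return SimConfig(**kwargs)


def _drift(config: SimConfig, t: float) -> float:
    horizon = max(config.time_points_weeks)
    if horizon == 0:
        return 0.0
    return config.control_drift_end_pct * t / horizon


def generate(config: SimConfig | None = None, rng: np.random.Generator | None = None) -> list[ArmRecord]:
    """Simulate one arm-level dataset from the configured truth.

    Control-arm mean weights follow ``baseline * (1 + drift(t)/100)``;
    treatment-arm means add the study-level Emax effect and residual
    noise on the percent scale, so the downstream percent-change and
    control-subtraction steps are exact inverses of the construction.
    Deterministic under a fixed config seed.
    """
    config = config or default_config()
    studies = config.studies or _DEFAULT_STUDIES
    rng = np.random.default_rng(config.seed) if rng is None else rng
    truth = config.truth
    times = sorted(config.time_points_weeks)
    records: list[ArmRecord] = []
    for tpl in studies:
        if not AGE_RANGE[0] <= tpl.age_mean_years <= AGE_RANGE[1]:
            raise ValueError(
                f"{tpl.study_id}: age {tpl.age_mean_years} outside {AGE_RANGE}"
            )
        e1, e2 = draw_etas(truth, rng)
        study_params = apply_eta(truth, e1, e2)
        for t in times:
            drift = _drift(config, t)
            records.append(
                ArmRecord(
                    study_id=tpl.study_id,
                    arm="control",
                    dose_mg_per_day=0.0,
                    time_weeks=t,
                    weight_mean_kg=tpl.baseline_control_kg * (1.0 + drift / 100.0),
                    n_subjects=tpl.n_control,
                    age_mean_years=tpl.age_mean_years,
                )
            )
            if t == 0:
                pct = 0.0
            else:
                eps = rng.normal(
                    0.0, truth.sigma / np.sqrt(tpl.n_treatment / 100.0)
                )
                pct = drift + emax_effect(study_params, t) + eps
            records.append(
                ArmRecord(
                    study_id=tpl.study_id,
                    arm="treatment",
                    dose_mg_per_day=tpl.dose_mg_per_day,
                    time_weeks=t,
                    weight_mean_kg=tpl.baseline_treatment_kg * (1.0 + pct / 100.0),
                    n_subjects=tpl.n_treatment,
                    age_mean_years=tpl.age_mean_years,
                )
            )
    return records


def write_fixture(records: Sequence[ArmRecord], path) -> None:
    """Write generated records as the canonical arm-level CSV.

    Output is byte-identical for identical inputs, so fixtures are
    reproducible from (config, seed) alone.
    """
    write_table(records, path)
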