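"""Arm-level aggregate data: loading, validation and effect construction.

Input is a tidy CSV with one row per study arm per visit (study_id, arm,
dose_mg_per_day, time_weeks, weight_mean_kg, n_subjects, age_mean_years).
Each (study, arm) must contain a baseline row at t = 0; percent change
from that baseline is the therapeutic index, and the control arm's change
is subtracted from the treatment arm's at matched times to isolate the
net treatment effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ArmRecord",
    "EffectSeries",
    "ValidationError",
    "REQUIRED_COLUMNS",
    "load_table",
    "write_table",
    "percent_change",
    "build_effect_series",
    "effect_series_to_frame",
    "write_effect_series",
    "read_effect_series",
]

REQUIRED_COLUMNS = (
    "study_id",
    "arm",
    "dose_mg_per_day",
    "time_weeks",
    "weight_mean_kg",
    "n_subjects",
)
OPTIONAL_COLUMNS = ("age_mean_years",)
ARMS = ("treatment", "control")


class ValidationError(ValueError):
    """Structured input-validation failure; message names the offending rows."""


@dataclass(frozen=True)
class ArmRecord:
    """One aggregate observation: a study arm's mean weight at one visit."""

    study_id: str
    arm: str
    dose_mg_per_day: float
    time_weeks: float
    weight_mean_kg: float
    n_subjects: int
    age_mean_years: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if self.time_weeks < 0:
            raise ValidationError("time_weeks must be non-negative")
        if self.weight_mean_kg <= 0:
            raise ValidationError("weight_mean_kg must be positive")
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be at least 1")
        if self.dose_mg_per_day < 0:
            raise ValidationError("dose_mg_per_day must be non-negative")
        if self.arm == "treatment" and self.dose_mg_per_day <= 0:
            raise ValidationError("treatment arm requires a positive dose")


@dataclass(frozen=True)
class EffectSeries:
    """Per-study percent-change effects at post-baseline times.

    ``effect_sum_pct`` is the treatment arm's change from its own baseline
    (treatment + background effect), ``effect_control_pct`` the control
    arm's, and ``effect_net_pct`` their difference — the net treatment
    effect.  ``covariates`` carries study-level covariates (dose, baseline
    weight, age, source label) for covariate modelling.
    """

    study_id: str
    times_weeks: np.ndarray
    effect_sum_pct: np.ndarray
    effect_control_pct: np.ndarray
    effect_net_pct: np.ndarray
    n_treatment: np.ndarray
    covariates: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {
            len(self.times_weeks),
            len(self.effect_sum_pct),
            len(self.effect_control_pct),
            len(self.effect_net_pct),
            len(self.n_treatment),
        }
        if len(lengths) != 1:
            raise ValidationError(f"{self.study_id}: vectors differ in length")
        t = np.asarray(self.times_weeks, float)
        if len(t) and (np.any(t <= 0) or np.any(np.diff(t) <= 0)):
            raise ValidationError(
                f"{self.study_id}: times must be positive and strictly increasing"
            )

    def __len__(self) -> int:
        return len(self.times_weeks)


def percent_change(weight_at_time: float, weight_at_baseline: float) -> float:
    """Percent change from baseline: (E_t - E_0) / E_0 * 100.

    Stored on the x100 scale, so a 4% loss is -4.0.
    """
    if weight_at_baseline <= 0 or weight_at_time <= 0:
        raise ValueError("weights must be positive")
    return (weight_at_time - weight_at_baseline) / weight_at_baseline * 100.0


def _validated_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required column(s): {', '.join(missing)}")
    df = df.copy()
    numeric = ("dose_mg_per_day", "time_weeks", "weight_mean_kg", "n_subjects")
    for col in numeric + tuple(c for c in OPTIONAL_COLUMNS if c in df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header and 0-base
            raise ValidationError(f"non-numeric value in column {col!r} at file row(s) {rows}")
        if col in numeric and coerced.isna().any():
            rows = ", ".join(str(i + 2) for i in df.index[coerced.isna()][:5])
            raise ValidationError(f"empty value in column {col!r} at file row(s) {rows}")
        df[col] = coerced
    dup = df.duplicated(subset=["study_id", "arm", "time_weeks"], keep=False)
    if dup.any():
        rows = ", ".join(str(i + 2) for i in df.index[dup][:6])
        raise ValidationError(
            f"duplicate (study_id, arm, time_weeks) key at file row(s) {rows}"
        )
    for (study, arm), grp in df.groupby(["study_id", "arm"], sort=False):
        if not (grp["time_weeks"] == 0).any():
            raise ValidationError(
                f"study {study!r} arm {arm!r} has no baseline row at time_weeks = 0"
            )
    return df


def load_table(path, dialect: Mapping | None = None) -> list[ArmRecord]:
    """Read and validate an arm-level CSV into ``ArmRecord`` objects.

    ``dialect`` may rename columns: a mapping from the canonical names to
    the names used in the file (e.g. ``{"study_id": "trial"}``).
    """
    df = pd.read_csv(path)
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})
    df = _validated_frame(df)
    for (study, arm), grp in df.groupby(["study_id", "arm"], sort=True):
        logger.info("loaded %s/%s: %d rows", study, arm, len(grp))
    records = []
    for row in df.itertuples(index=False):
        age = getattr(row, "age_mean_years", None)
        if age is not None and pd.isna(age):
            age = None
        records.append(
            ArmRecord(
                study_id=str(row.study_id),
                arm=str(row.arm),
                dose_mg_per_day=float(row.dose_mg_per_day),
                time_weeks=float(row.time_weeks),
                weight_mean_kg=float(row.weight_mean_kg),
                n_subjects=int(row.n_subjects),
                age_mean_years=None if age is None else float(age),
            )
        )
    return records


def write_table(records: Iterable[ArmRecord], path) -> None:
    """Write arm records back to the canonical CSV schema."""
    df = pd.DataFrame(
        [
            {
                "study_id": r.study_id,
                "arm": r.arm,
                "dose_mg_per_day": r.dose_mg_per_day,
                "time_weeks": r.time_weeks,
                "weight_mean_kg": r.weight_mean_kg,
                "n_subjects": r.n_subjects,
                "age_mean_years": r.age_mean_years,
            }
            for r in records
        ]
    )
    df.to_csv(path, index=False)


def build_effect_series(records: Sequence[ArmRecord]) -> list[EffectSeries]:
    """Control-corrected percent-change series, one per study.

    Each study needs exactly one treatment and one control arm observed on
    identical post-baseline time grids; the treatment and control percent
    changes are computed against each arm's own baseline and subtracted at
    matched times.  No interpolation is attempted — mismatched grids are an
    error.
    """
    by_study: dict[str, dict[str, list[ArmRecord]]] = {}
    for r in records:
        by_study.setdefault(r.study_id, {}).setdefault(r.arm, []).append(r)

    study_ids = list(by_study)
    source_code = {sid: i for i, sid in enumerate(sorted(study_ids))}
    out = []
    for sid in study_ids:
        arms = by_study[sid]
        if "control" not in arms:
            raise ValidationError(
                f"study {sid!r} lacks a control arm (inclusion requires a control group)"
            )
        if "treatment" not in arms:
            raise ValidationError(f"study {sid!r} lacks a treatment arm")

        def split(rows: list[ArmRecord]):
            rows = sorted(rows, key=lambda r: r.time_weeks)
            base = [r for r in rows if r.time_weeks == 0]
            post = [r for r in rows if r.time_weeks > 0]
            if len(base) != 1:
                raise ValidationError(f"study {sid!r}: expected exactly one baseline row")
            return base[0], post

        t_base, t_post = split(arms["treatment"])
        c_base, c_post = split(arms["control"])
        t_times = [r.time_weeks for r in t_post]
        c_times = [r.time_weeks for r in c_post]
        if t_times != c_times:
            raise ValidationError(
                f"study {sid!r}: treatment times {t_times} != control times {c_times}; "
                "arms must share the post-baseline grid"
            )
        e_sum = np.array(
            [percent_change(r.weight_mean_kg, t_base.weight_mean_kg) for r in t_post]
        )
        e_ctl = np.array(
            [percent_change(r.weight_mean_kg, c_base.weight_mean_kg) for r in c_post]
        )
        covariates = {
            "dose": t_base.dose_mg_per_day,
            "baseline_weight": t_base.weight_mean_kg,
            "source": float(source_code[sid]),
        }
        if t_base.age_mean_years is not None:
            covariates["age"] = t_base.age_mean_years
        out.append(
            EffectSeries(
                study_id=sid,
                times_weeks=np.array(t_times, float),
                effect_sum_pct=e_sum,
                effect_control_pct=e_ctl,
                effect_net_pct=e_sum - e_ctl,
                n_treatment=np.array([r.n_subjects for r in t_post], int),
                covariates=covariates,
            )
        )
    return out


def effect_series_to_frame(series: Sequence[EffectSeries]) -> pd.DataFrame:
    """Tidy long-format frame of effect series (one row per study x time)."""
    rows = []
    for s in series:
        for k in range(len(s)):
            row = {
                "study_id": s.study_id,
                "time_weeks": s.times_weeks[k],
                "effect_sum_pct": s.effect_sum_pct[k],
                "effect_control_pct": s.effect_control_pct[k],
                "effect_net_pct": s.effect_net_pct[k],
                "n": int(s.n_treatment[k]),
            }
            for name, value in s.covariates.items():
                row[f"cov_{name}"] = value
            rows.append(row)
    return pd.DataFrame(rows)


def write_effect_series(series: Sequence[EffectSeries], path) -> None:
    effect_series_to_frame(series).to_csv(path, index=False)


def read_effect_series(path) -> list[EffectSeries]:
    """Read a tidy effect-series CSV written by :func:`write_effect_series`."""
    df = pd.read_csv(path)
    needed = {"study_id", "time_weeks", "effect_net_pct", "n"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"effect-series file missing column(s): {sorted(missing)}")
    out = []
    for sid, grp in df.groupby("study_id", sort=False):
        grp = grp.sort_values("time_weeks")
        cov = {
            c[len("cov_"):]: float(grp[c].iloc[0])
            for c in grp.columns
            if c.startswith("cov_") and pd.notna(grp[c].iloc[0])
        }
        zeros = np.zeros(len(grp))
        out.append(
            EffectSeries(
                study_id=str(sid),
                times_weeks=grp["time_weeks"].to_numpy(float),
                effect_sum_pct=grp.get("effect_sum_pct", pd.Series(zeros)).to_numpy(float),
                effect_control_pct=grp.get(
                    "effect_control_pct", pd.Series(zeros)
                ).to_numpy(float),
                effect_net_pct=grp["effect_net_pct"].to_numpy(float),
                n_treatment=grp["n"].to_numpy(int),
                covariates=cov,
            )
        )
    return out
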