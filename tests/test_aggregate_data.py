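"""Arm-level table IO, percent-change arithmetic and effect construction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import carnimax as cm
from carnimax.aggregate_data import ValidationError, read_effect_series, write_effect_series


@pytest.mark.parametrize(
    "at_time, at_baseline, expected",
    [
        (96.0, 100.0, -4.0),
        (100.0, 100.0, 0.0),
        (70.47, 72.0, (70.47 - 72.0) / 72.0 * 100.0),  # -2.125
    ],
)
def test_percent_change_examples(at_time, at_baseline, expected):
    assert cm.percent_change(at_time, at_baseline) == pytest.approx(expected)


def test_percent_change_rejects_nonpositive_baseline():
    with pytest.raises(ValueError):
        cm.percent_change(70.0, 0.0)


@settings(max_examples=60, derandomize=True)
@given(
    a=st.floats(1.0, 500.0),
    b=st.floats(1.0, 500.0),
    c=st.floats(0.01, 100.0),
)
def test_percent_change_scale_invariant(a, b, c):
    assert cm.percent_change(c * a, c * b) == pytest.approx(
        cm.percent_change(a, b), rel=1e-9, abs=1e-9
    )


def _fixture_frame():
    rows = []
    for sid, base_t, base_c in (("s1", 80.0, 82.0), ("s2", 70.0, 71.0)):
        for arm, base in (("treatment", base_t), ("control", base_c)):
            for k, t in enumerate((0.0, 6.0, 12.0)):
                rows.append(
                    {
                        "study_id": sid,
                        "arm": arm,
                        "dose_mg_per_day": 500.0 if arm == "treatment" else 0.0,
                        "time_weeks": t,
                        "weight_mean_kg": base * (1 - 0.01 * k),
                        "n_subjects": 30,
                        "age_mean_years": 27.0,
                    }
                )
    return pd.DataFrame(rows)


def test_load_table_counts(tmp_path):
    path = tmp_path / "arms.csv"
    _fixture_frame().to_csv(path, index=False)
    records = cm.load_table(path)
    assert len(records) == 12
    assert len({r.study_id for r in records}) == 2


def test_load_table_missing_baseline_names_arm(tmp_path):
    df = _fixture_frame()
    df = df[~((df.study_id == "s2") & (df.arm == "control") & (df.time_weeks == 0))]
    path = tmp_path / "arms.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="s2.*control"):
        cm.load_table(path)


def test_load_table_duplicate_key_rejected(tmp_path):
    df = _fixture_frame()
    df = pd.concat([df, df.iloc[[3]]])
    path = tmp_path / "arms.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="duplicate"):
        cm.load_table(path)


def test_load_table_non_numeric_cell_names_row(tmp_path):
    df = _fixture_frame().astype({"weight_mean_kg": object})
    df.iloc[2, df.columns.get_loc("weight_mean_kg")] = "heavy"
    path = tmp_path / "arms.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="weight_mean_kg"):
        cm.load_table(path)


def test_load_table_missing_column(tmp_path):
    df = _fixture_frame().drop(columns=["n_subjects"])
    path = tmp_path / "arms.csv"
    df.to_csv(path, index=False)
    with pytest.raises(ValidationError, match="n_subjects"):
        cm.load_table(path)


def test_default_template_totals(default_records):
    """The default design carries 242 subjects over 4 two-arm studies."""
    baselines = [r for r in default_records if r.time_weeks == 0]
    assert sum(r.n_subjects for r in baselines) == 242
    assert len({r.study_id for r in default_records}) == 4


def test_round_trip_write_load(tmp_path, default_records):
    path = tmp_path / "rt.csv"
    cm.write_table(default_records, path)
    back = cm.load_table(path)
    assert back == default_records


def test_build_effect_series_subtraction(make_series, tmp_path):
    df = _fixture_frame()
    path = tmp_path / "arms.csv"
    df.to_csv(path, index=False)
    series = cm.build_effect_series(cm.load_table(path))
    for s in series:
        np.testing.assert_allclose(
            s.effect_net_pct, s.effect_sum_pct - s.effect_control_pct, rtol=0, atol=0
        )
        # identical relative trajectories in both arms cancel exactly
        np.testing.assert_allclose(s.effect_net_pct, 0.0, atol=1e-12)


def test_build_effect_series_requires_control():
    records = [r for r in cm.generate(cm.default_config(seed=1)) if r.arm == "treatment"]
    with pytest.raises(ValidationError, match="control"):
        cm.build_effect_series(records)


def test_build_effect_series_rejects_mismatched_grids(default_records):
    records = [
        r
        for r in default_records
        if not (r.study_id == "study_a" and r.arm == "control" and r.time_weeks == 8.0)
    ]
    with pytest.raises(ValidationError, match="grid"):
        cm.build_effect_series(records)


def test_noise_free_series_matches_structural_curve(noise_free_series):
    """With no noise, no drift and no etas the pipeline recovers
    Emax * t / (ET50 + t) at machine precision."""
    for s in noise_free_series:
        expected = -3.92 * s.times_weeks / (3.6 + s.times_weeks)
        np.testing.assert_allclose(s.effect_net_pct, expected, rtol=1e-7, atol=1e-7)


def test_effect_series_round_trip(tmp_path, default_series):
    path = tmp_path / "effects.csv"
    write_effect_series(default_series, path)
    back = read_effect_series(path)
    assert len(back) == len(default_series)
    for a, b in zip(default_series, back):
        assert a.study_id == b.study_id
        np.testing.assert_allclose(a.effect_net_pct, b.effect_net_pct)
        np.testing.assert_allclose(a.times_weeks, b.times_weeks)
        assert dict(a.covariates) == pytest.approx(dict(b.covariates))
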