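import numpy as np
import pytest

import carnimax as cm
from carnimax.aggregate_data import EffectSeries
from carnimax.structural import EmaxParams

TRUTH = EmaxParams(
    emax_pct=-3.92, et50_weeks=3.6, omega_emax=0.106, omega_et50=0.867, sigma=0.1
)


@pytest.fixture(scope="session")
def truth():
    return TRUTH


@pytest.fixture
def make_series():
    """Factory for hand-built effect series with explicit net effects."""

    def _make(study_id, times, net, n, covariates=None):
        times = np.asarray(times, float)
        net = np.asarray(net, float)
        return EffectSeries(
            study_id=study_id,
            times_weeks=times,
            effect_sum_pct=net,
            effect_control_pct=np.zeros_like(net),
            effect_net_pct=net,
            n_treatment=np.asarray(n, int),
            covariates=covariates or {},
        )

    return _make


@pytest.fixture
def default_records():
    return cm.generate(cm.default_config(seed=1))


@pytest.fixture
def default_series(default_records):
    return cm.build_effect_series(default_records)


@pytest.fixture(scope="session")
def fitted_default():
    """One full multi-start fit of a default-design synthetic dataset."""
    series = cm.build_effect_series(cm.generate(cm.default_config(seed=1)))
    return cm.fit(series), series


@pytest.fixture
def noise_free_series():
    """Deterministic dataset from the structural curve: no etas, no noise."""
    truth = EmaxParams(
        emax_pct=-3.92, et50_weeks=3.6, omega_emax=0.0, omega_et50=0.0, sigma=1e-8
    )
    cfg = cm.SimConfig(
        truth=truth,
        studies=cm.synthetic._DEFAULT_STUDIES,
        control_drift_end_pct=0.0,
        seed=7,
    )
    return cm.build_effect_series(cm.generate(cfg))
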