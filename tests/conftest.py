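import warnings

import pytest
from hypothesis import HealthCheck, settings

import ceflux as cf
from ceflux.metrics import compute_metrics
from ceflux.rates import compute_rates

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return cf.default_registry()


@pytest.fixture(scope="session")
def preset_runs():
    """Noiseless simulation + pipeline metrics for every scenario preset."""
    runs = {}
    for name in cf.scenario_presets():
        ts, truth = cf.build_preset(name, seed=11)
        records = compute_rates(ts, cf.STUDY_FEED)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            metrics = compute_metrics(ts, records, cf.STUDY_FEED)
        runs[name] = (ts, truth, records, metrics)
    return runs
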