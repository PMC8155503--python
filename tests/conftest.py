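import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=25,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fitted_stages():
    """Calibrated post-S1 and pre-S2 models, fitted once per session."""
    from norwoodlpn.io import PipelineConfig
    from norwoodlpn.pipeline import run_pipeline

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            stage: run_pipeline(PipelineConfig(stage=stage), write=False)
            for stage in ("post_s1", "pre_s2")
        }


@pytest.fixture(scope="session")
def benchmark_netlists():
    from norwoodlpn.synth import fixture_netlists

    return fixture_netlists()
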