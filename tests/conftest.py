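import numpy as np
import pytest

from drclaims.simulate import SimConfig, generate_claim_stream


@pytest.fixture(scope="session")
def small_stream():
    """A 600-patient scripted claim stream shared across cohort tests."""
    return generate_claim_stream(SimConfig(n_patients=600, seed=17))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def no_effect_config(**overrides) -> SimConfig:
    """Exponential event times, no covariate effects, no censoring."""
    base = dict(
        n_patients=10_000,
        n_phecode_features=0,
        hazard_shape=1.0,
        hazard_scale_by_arm=(5.0, 5.0),
        log_hazard_coefficients_by_arm=(np.zeros(9), np.zeros(9)),
        ps_coefficients=np.zeros(9),
        censor_rate=0.0,
        seed=123,
    )
    base.update(overrides)
    return SimConfig(**base)
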