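import numpy as np
import pytest

from pneumotox.synth_ehr import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def clean_streams():
    """Moderate cohort with distractors and negated mentions disabled, so
    the cascade should recover ground truth exactly."""
    cfg = GeneratorConfig(
        n_patients=800, seed=11, distractor_rate=0.0, negated_distractors=False
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def noisy_streams():
    """Cohort with the default distractor mix (request-only mentions,
    untreated mimics, negated mentions)."""
    cfg = GeneratorConfig(n_patients=800, seed=12, distractor_rate=0.3)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
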