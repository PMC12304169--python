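import numpy as np
import pytest

from benthoscan import sampling, synthetic


@pytest.fixture(scope="session")
def default_survey():
    """One full synthetic survey (navigation, detections, truth)."""
    config = synthetic.default_config(seed=7)
    records, detections, truth = synthetic.generate_survey(config)
    return config, records, detections, truth


@pytest.fixture(scope="session")
def abundance_matrix(default_survey):
    """The default survey pushed through the standardisation stage."""
    _, records, detections, truth = default_survey
    units, records = sampling.partition_units(records)
    matrix = sampling.pool_and_standardise(
        units, records, detections, region_map=truth.region_of_dive
    )
    return matrix, truth


@pytest.fixture
def rng():
    return np.random.default_rng(123)
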