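import numpy as np
import pytest
from hypothesis import settings

from aquamyo.config import PipelineConfig
from aquamyo.pipeline import long_format, process_cohort
from aquamyo.synthetic import GeneratorConfig, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast, small-scale generator configuration for unit tests."""
    return GeneratorConfig(
        rest_duration_s=5.0,
        contraction_duration_s=12.0,
        reps_options=(2, 3),
        n_sets=2,
        seed=7,
    )


@pytest.fixture(scope="session")
def default_cohort_products():
    """Default 15-subject cohort run once through the full pipeline.

    Returns (wide per-trial feature table, segmentation diagnostics,
    long-format feature table).  Shared across the cohort-scale tests.
    """
    cohort = generate_cohort(15, GeneratorConfig(seed=1))
    wide, diag = process_cohort(cohort, PipelineConfig())
    return wide, diag, long_format(wide)
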