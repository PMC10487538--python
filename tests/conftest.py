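"""Shared fixtures: a desk-scale cohort and one full pipeline run.

The default cohort and pipeline run are session-scoped because several
test modules assert different properties of the same end-to-end analysis.
"""

import warnings

import numpy as np
import pytest

from screlink.pipeline import PipelineConfig, run_pipeline
from screlink.synthetic_data import GeneratorConfig, generate_cohort

ACCEPTANCE_SEED = 1


def small_config(seed=7, **overrides):
    """A miniature cohort for unit tests: same genome logic, fewer cells."""
    defaults = dict(
        rng_seed=seed,
        n_rna_cells_per_sample=150,
        n_atac_cells_per_sample=150,
        chr1_blocks=24,
        chr3_blocks=24,
        n_link_peaks=8,
        n_two_target_lineage=2,
        n_reference_overlap_cancer=1,
    )
    defaults.update(overrides)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config())


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(GeneratorConfig(rng_seed=ACCEPTANCE_SEED))


@pytest.fixture(scope="session")
def pipeline_result(default_cohort):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(default_cohort, PipelineConfig(seed=ACCEPTANCE_SEED))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
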