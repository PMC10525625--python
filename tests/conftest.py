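import numpy as np
import pytest

from posapk.cohort import (CohortSpec, SamplingDesign, generate_covariates,
                           generate_tdm_dataset)
from posapk.pk import DosingRegimen, StructuralParams
from posapk.population import PopulationParameters


@pytest.fixture(scope="session")
def pop_final():
    """The final population model estimates (the package defaults)."""
    return PopulationParameters()


@pytest.fixture()
def typical_56y():
    """Structural parameters of the typical 56-year-old subject."""
    return StructuralParams(ka=0.8, v=386.35, cl=5.316)


@pytest.fixture(scope="session")
def study_cohort():
    """A 32-subject virtual cohort matching the published summaries."""
    rng = np.random.default_rng(20230901)
    return generate_covariates(CohortSpec(), rng)


@pytest.fixture(scope="session")
def sparse_dataset(pop_final):
    """A study-like sparse TDM dataset (32 subjects, ~2.5 samples each)."""
    rng = np.random.default_rng(11)
    cohort = generate_covariates(CohortSpec(), rng)
    design = SamplingDesign()
    ds, truth = generate_tdm_dataset(cohort, design, pop_final,
                                     DosingRegimen(300.0), rng,
                                     return_truth=True)
    return ds, truth


@pytest.fixture(scope="session")
def rich_dataset(pop_final):
    """A 50-subject, 6-samples-per-subject dataset for estimation tests."""
    rng = np.random.default_rng(12)
    cohort = generate_covariates(CohortSpec(n_subjects=50), rng)
    design = SamplingDesign(samples_range=(6, 6), samples_mean=6.0,
                            end_day=30)
    ds, truth = generate_tdm_dataset(cohort, design, pop_final,
                                     DosingRegimen(300.0), rng,
                                     return_truth=True)
    return ds, truth
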