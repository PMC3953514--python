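import numpy as np
import pytest
from hypothesis import settings

from snpset import CohortConfig, make_candidate_panel, simulate_cohort
from snpset.candidates import FLUID_COHORT_SIZES

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def candidate_panel():
    """The 470-SNP candidate panel used by the study-condition tests."""
    return make_candidate_panel(470, seed=11)


@pytest.fixture(scope="session")
def fluid_cohorts(candidate_panel):
    """Five synthetic cohorts at the fluid-ability sample sizes."""
    seeds = np.random.SeedSequence(101).generate_state(len(FLUID_COHORT_SIZES))
    return [
        simulate_cohort(
            CohortConfig(name=name, n_individuals=n, panel=candidate_panel,
                         ld_rho=0.2, seed=int(s % 2**31))
        )
        for (name, n), s in zip(FLUID_COHORT_SIZES.items(), seeds)
    ]


@pytest.fixture(scope="session")
def small_panel():
    """A 60-SNP panel for cheap unit tests."""
    return make_candidate_panel(60, seed=21)


@pytest.fixture(scope="session")
def small_cohort(small_panel):
    return simulate_cohort(
        CohortConfig(name="unit", n_individuals=400, panel=small_panel,
                     ld_rho=0.2, seed=33)
    )
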