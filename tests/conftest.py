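import numpy as np
import pytest
from hypothesis import settings

from stratmix.groups import PopulationTable
from stratmix.matrices import AgeContactMatrix, IntermediateMatrix, reciprocity_correct
from stratmix.expansion import homogeneous_expansion, sample_ensemble
from stratmix.synthetic import (
    GroundTruthConfig,
    make_population,
    make_truth_matrix,
    simulate_survey,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pop() -> PopulationTable:
    return make_population(GroundTruthConfig())


@pytest.fixture(scope="session")
def base_rec(pop) -> AgeContactMatrix:
    return reciprocity_correct(
        AgeContactMatrix(GroundTruthConfig().base_age_matrix), pop
    )


@pytest.fixture(scope="session")
def truth(pop, base_rec):
    return make_truth_matrix(pop, base_rec, 0.3, 0.3)


@pytest.fixture(scope="session")
def bar_exact(pop, truth) -> IntermediateMatrix:
    """Adjusted intermediate matrix implied exactly by the truth matrix."""
    return IntermediateMatrix(
        truth.aggregate_rows_to_age(), adjusted=True, population=pop
    )


@pytest.fixture(scope="session")
def m_rec_exact(pop, bar_exact) -> AgeContactMatrix:
    return AgeContactMatrix(
        bar_exact.aggregate_to_age(pop), corrected=True, population=pop
    )


@pytest.fixture(scope="session")
def hom(pop, m_rec_exact):
    return homogeneous_expansion(m_rec_exact, pop)


@pytest.fixture(scope="session")
def small_ensemble(pop, bar_exact):
    return sample_ensemble(bar_exact, pop, n=100, seed=7)


@pytest.fixture(scope="session")
def synth(pop, truth):
    return simulate_survey(truth, pop, n_per_stratum=500, seed=11)
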