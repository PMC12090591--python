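import numpy as np
import pytest

from symptomnet import (
    MarginalSpec,
    SymptomDataset,
    TrueNetwork,
    generate_dataset,
    study_true_network,
    table2_marginals,
)


@pytest.fixture(scope="session")
def study_truth() -> TrueNetwork:
    return study_true_network()


@pytest.fixture(scope="session")
def study_marginals() -> MarginalSpec:
    return table2_marginals(warn=False)


@pytest.fixture(scope="session")
def study_dataset(study_truth, study_marginals) -> SymptomDataset:
    """A study-scale synthetic dataset: p = 19, n = 367."""
    return generate_dataset(study_truth, study_marginals, 367, seed=11)


def flat_marginals(p: int, prevalence: float = 0.7, mean: float = 2.0) -> MarginalSpec:
    return MarginalSpec(
        np.full(p, prevalence), np.full(p, mean), tuple(f"S{i+1}" for i in range(p))
    )


@pytest.fixture(scope="session")
def small_dataset() -> SymptomDataset:
    """Tiny deterministic dataset for descriptive-statistics checks."""
    scores = np.array(
        [
            [0, 1, 5, 0],
            [1, 2, 6, 0],
            [2, 0, 7, 0],
            [3, 4, 8, 0],
        ]
    )
    return SymptomDataset(scores, ("A", "B", "C", "D"))
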