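import numpy as np
import pytest

from ehrpred.codes import CodeHierarchy
from ehrpred.corpus_io import PatientHistory, SequenceDataset
from ehrpred.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 300-patient synthetic cohort with its hierarchy (seeded)."""
    return generate_cohort(CohortConfig(n_patients=300, seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def toy_dataset():
    """Three short handwritten histories over a tiny alphabet."""
    return SequenceDataset(
        [
            PatientHistory("p1", [(0, "a"), (1, "b"), (2, "a"), (3, "b")]),
            PatientHistory("p2", [(0, "b"), (1, "c"), (2, "c"), (3, "a"), (4, "b")]),
            PatientHistory("p3", [(0, "a"), (1, "a"), (2, "a")]),
        ]
    )


def random_history(rng, length, alphabet_size, pid="p"):
    codes = rng.integers(0, alphabet_size, size=length)
    return PatientHistory(pid, [(i, f"c{c}") for i, c in enumerate(codes)])


def tiny_hierarchy():
    return CodeHierarchy(
        {
            "a": ("t1", "X", "ch1"),
            "b": ("t1", "X", "ch1"),
            "c": ("t2", "X", "ch1"),
            "d": ("t3", "Y", "ch2"),
        }
    )
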