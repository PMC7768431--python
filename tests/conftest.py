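import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from fluencynet.data import equate_groups, preprocess, records_from_frame, split_matrix
from fluencynet.synthetic import simulate_study

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def study():
    """One reference synthetic two-group study."""
    return simulate_study(seed=11)


@pytest.fixture(scope="session")
def equated_matrices(study):
    """The study's equated (low, high) incidence matrices."""
    matrix = preprocess(records_from_frame(study.records), min_producers=2)
    labels = dict(zip(study.scores.index, study.scores.group_true))
    mat_low, mat_high = split_matrix(matrix, labels)
    return equate_groups(mat_low, mat_high)


@pytest.fixture()
def random_incidence():
    """Factory for random binary incidence matrices with non-empty columns."""

    def make(n_participants=29, n_words=20, p=0.25, seed=0):
        rng = np.random.default_rng(seed)
        cells = rng.random((n_participants, n_words)) < p
        mat = pd.DataFrame(
            cells.astype(int),
            index=[f"p{i:02d}" for i in range(n_participants)],
            columns=[f"w{j:02d}" for j in range(n_words)],
        )
        return mat.loc[:, mat.sum() > 0]

    return make
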