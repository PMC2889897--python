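import numpy as np
import pandas as pd
import pytest

from mirblood import generate_cohort, preprocess
from mirblood.config import SimulationConfig


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort (866 x 55), preprocessed."""
    probe, ann, truth = generate_cohort(SimulationConfig(seed=11))
    return preprocess(probe), ann, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Full-size cohort with no planted effects."""
    probe, ann, truth = generate_cohort(SimulationConfig(seed=23, n_planted=0))
    return preprocess(probe), ann, truth


@pytest.fixture
def tiny_matrix():
    """Deterministic 6-feature x 6-sample matrix with annotation."""
    rng = np.random.default_rng(5)
    m = pd.DataFrame(
        rng.uniform(10, 1000, size=(6, 6)),
        index=[f"f{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(6)],
    )
    ann = pd.DataFrame(
        {"sample_id": m.columns, "group": ["C", "C", "C", "M", "M", "N"]}
    )
    return m, ann
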