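import numpy as np
import pandas as pd
import pytest

from extremescan import ExpressionMatrix, SelectionCriteria, SyntheticSpec, generate
from extremescan.select import select_extremes


@pytest.fixture(scope="session")
def small_cohort():
    """100-case, 300-gene cohort with 10 planted signal genes."""
    return generate(SyntheticSpec(n_cases=100, n_genes=300, n_signal_genes=10, seed=42))


@pytest.fixture(scope="session")
def small_groups(small_cohort):
    return select_extremes(small_cohort.cohort, SelectionCriteria())


@pytest.fixture()
def tiny_matrix():
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(7, 1, (6, 8)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(8)],
    )
    return ExpressionMatrix(values)
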