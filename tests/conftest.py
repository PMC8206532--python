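import numpy as np
import pytest

from miosel.data_model import PredictorMatrix, ResponseVector, Timepoint
from miosel.model import BestSubsetSelection
from miosel.subset_select import standardize
from miosel.synthetic_data import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def reduced_cohort():
    """One 200-predictor synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortSpec.reduced(seed=11))


@pytest.fixture(scope="session")
def reduced_fit(reduced_cohort):
    """k-best fit (sizes 1-3, k=20) of the shared cohort."""
    sel = BestSubsetSelection.from_cohort(reduced_cohort)
    return sel.fit(p_max=3, k=20, backend="enumeration")


def make_design(seed, n=50, t=12, support=(2, 5, 9), betas=(1.5, -1.0, 0.7), noise=0.8):
    """Small random regression instance with a planted sparse signal."""
    rng = np.random.default_rng(seed)
    X = PredictorMatrix(
        rng.normal(size=(n, t)),
        list(range(t)),
        [str(i) for i in range(t)],
        [Timepoint.BASELINE] * t,
    )
    beta = np.zeros(t)
    for j, b in zip(support, betas):
        if j < t:
            beta[j] = b
    y = ResponseVector(X.values @ beta + rng.normal(0, noise, n))
    return X, y, standardize(X, y)


@pytest.fixture
def small_design():
    return make_design(0)
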