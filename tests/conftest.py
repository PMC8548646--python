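import numpy as np
import pytest

from jst.simulator import GenotypeModel, make_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_model():
    """A small 8-SNP gene with two LD blocks."""
    return GenotypeModel(m=8, maf=np.linspace(0.1, 0.4, 8), block_sizes=(4, 4), rho=0.6)


@pytest.fixture
def small_cohort(rng, small_model):
    """(X_recipient, X_donor, W, Y_binary) for 120 pairs."""
    X_R, X_D = make_cohort(small_model, 120, rng)
    W = np.column_stack([rng.binomial(1, 0.5, 120), rng.standard_normal(120)])
    lp = -1.0 + 0.5 * W[:, 0] + 0.5 * W[:, 1]
    Y = rng.binomial(1, 1 / (1 + np.exp(-lp))).astype(float)
    return X_R, X_D, W, Y
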