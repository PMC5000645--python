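import numpy as np
import pandas as pd
import pytest

from kocqspr.molgraph import attribute_profile, parse_smiles
from kocqspr.published_models import FORMALDEHYDE_CW
from kocqspr.synthetic_data import SyntheticSpec, gen_planted_linear


@pytest.fixture(scope="session")
def formaldehyde_profile():
    return attribute_profile(parse_smiles("C=O"), molecule_id="formaldehyde")


@pytest.fixture(scope="session")
def formaldehyde_cw():
    return dict(FORMALDEHYDE_CW)


@pytest.fixture()
def planted_pool():
    """Small descriptor pool with a known 2-descriptor linear truth."""
    spec = SyntheticSpec(
        n_train=60, n_test=30, n_descriptors=15,
        true_subset=(3, 7), beta=(1.5, -2.0), sigma=0.01, seed=42,
    )
    matrix, y = gen_planted_linear(spec)
    return matrix, y, spec


@pytest.fixture()
def fixture_93x4():
    """A 93-compound, 4-descriptor regression fixture with realistic noise."""
    rng = np.random.default_rng(7)
    X = rng.standard_normal((93, 4))
    beta = np.array([0.8, -1.2, 0.5, 0.3])
    y = 1.0 + X @ beta + rng.normal(0, 0.4, 93)
    return pd.DataFrame(X, columns=list("abcd")), y
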