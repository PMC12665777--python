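import numpy as np
import pandas as pd
import pytest

from qsarkit import SyntheticSpec, generate, reference_study_fixture, preprocess_pipeline


@pytest.fixture(scope="session")
def study_fixture():
    """Study-shaped dataset (62 compounds, 8 named informative descriptors)
    plus a mixed in/out-of-domain query set."""
    return reference_study_fixture(seed=11)


@pytest.fixture(scope="session")
def prepared(study_fixture):
    """Preprocessed (standardized, filtered, split) study fixture."""
    ds, _, _ = study_fixture
    return preprocess_pipeline(ds.X, ds.y, seed=11)


@pytest.fixture(scope="session")
def small_linear():
    """n=60, p=10, y exactly linear in 3 named columns plus tiny noise."""
    rng = np.random.default_rng(5)
    X = pd.DataFrame(rng.standard_normal((60, 10)),
                     columns=[f"D{i}" for i in range(10)],
                     index=[f"c{i}" for i in range(60)])
    X = (X - X.mean()) / X.std(ddof=1)
    beta = {"D1": 1.0, "D4": -0.8, "D7": 0.6}
    y = sum(b * X[c] for c, b in beta.items()) + 0.01 * rng.standard_normal(60)
    return X, pd.Series(y, index=X.index, name="y"), beta
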