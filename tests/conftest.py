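import numpy as np
import pandas as pd
import pytest

import synaptodyn as sd


@pytest.fixture(scope="session")
def small_config():
    """A scaled-down study: fewer subjects and time points, full region count."""
    return sd.SynthConfig(seed=7, n_subjects=3, n_timepoints=400)


@pytest.fixture(scope="session")
def small_density(small_config):
    density, truth = sd.synthetic.gen_density(small_config)
    return density, truth


@pytest.fixture(scope="session")
def small_stack(small_config, small_density):
    density, _ = small_density
    stack, info = sd.synthetic.gen_timeseries(small_config, density)
    return stack, info


@pytest.fixture(scope="session")
def small_features(small_stack):
    stack, _ = small_stack
    mats = sd.features.compute_feature_matrix(stack)
    norm = [sd.features.normalize_features(m) for m in mats]
    return norm, sd.features.group_average(norm)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_feature_matrix(values: np.ndarray, normalized=False, family="distribution"):
    """Wrap a raw regions x features array in a FeatureMatrix."""
    cols = [f"f{i}" for i in range(values.shape[1])]
    vals = pd.DataFrame(values, index=[f"R{i:03d}" for i in range(values.shape[0])],
                        columns=cols)
    catalog = pd.DataFrame({"family": [family] * len(cols)},
                           index=pd.Index(cols, name="feature"))
    return sd.FeatureMatrix(values=vals, catalog=catalog, normalized=normalized)
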