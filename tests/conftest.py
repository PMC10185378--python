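import numpy as np
import pandas as pd
import pytest

import actionspace as a


@pytest.fixture(scope="session")
def default_sim():
    """One study-scale synthetic rating study (240 actions, 20 characteristics,
    4 oblique factors, 10 raters) shared across read-only tests."""
    cfg = a.default_config(seed=11)
    return a.simulate_study(cfg)


@pytest.fixture(scope="session")
def default_matrix(default_sim):
    return a.aggregate_means(default_sim.study)


@pytest.fixture()
def toy_study_frame():
    """2 raters x 2 actions x 1 characteristic in canonical long format."""
    return pd.DataFrame({
        "participant": ["p1", "p1", "p2", "p2"],
        "characteristic": ["Weak - Powerful"] * 4,
        "action": ["a1", "a2", "a1", "a2"],
        "rating": [3, 5, 5, 7],
    })


def make_cluster_loadings(p=6, k=2, value=0.8):
    """Perfect cluster pattern: items split evenly over factors."""
    lam = np.zeros((p, k))
    for i in range(p):
        lam[i, i % k] = value
    return lam
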