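import numpy as np
import pandas as pd
import pytest

import hetcrt


@pytest.fixture(scope="session")
def tiny_frame():
    """Two clusters x four observations, values printed in full.

    Small enough that dense-matrix oracles are exact and fast.
    """
    return pd.DataFrame({
        "cluster_id": [1, 1, 1, 1, 2, 2, 2, 2],
        "trt":        [1, 1, 1, 1, 0, 0, 0, 0],
        "gr":         [0, 0, 1, 1, 0, 1, 1, 0],
        "y": [0.82, 1.31, 0.45, 1.77, -0.12, 0.63, -0.50, 0.91],
    })


@pytest.fixture(scope="session")
def six_cluster_frame():
    """Six clusters of 12, Gaussian outcomes from a well-separated mixed model."""
    spec = hetcrt.ScenarioSpec(
        scenario_id="custom",
        family_spec=hetcrt.FamilySpec("gaussian", residual_sd=0.8),
        fixed=hetcrt.FixedEffects(0.0, 0.5, (0.3,), (0.0,)),
        ranef=hetcrt.RandomEffectSpec("subgroup_specific",
                                      Sigma=np.array([[0.4, 0.1], [0.1, 0.3]])),
        n_clusters=6, cluster_sizes=12)
    return hetcrt.simulate_trial(spec, 20240803).frame


@pytest.fixture(scope="session")
def poisson_cluster_frame():
    """Two small clusters with printed count outcomes (quadrature fixtures)."""
    return pd.DataFrame({
        "cluster_id": [1, 1, 1, 2, 2, 2, 2],
        "trt":        [1, 1, 1, 0, 0, 0, 0],
        "gr":         [0, 1, 0, 0, 1, 1, 0],
        "y":          [0, 2, 1, 1, 0, 3, 1],
    })


@pytest.fixture(scope="session")
def scenario1_gauss_data():
    spec = hetcrt.make_scenario(1, "gaussian", 50, "fixed")
    return hetcrt.simulate_trial(spec, 91)


@pytest.fixture(scope="session")
def scenario3_count_data():
    spec = hetcrt.make_scenario(3, "poisson", 12, "fixed")
    return hetcrt.simulate_trial(spec, 47)
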