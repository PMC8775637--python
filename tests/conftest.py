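import numpy as np
import pytest

import lanelogit as ll


@pytest.fixture(scope="session")
def scheme():
    return ll.default_scheme()


@pytest.fixture(scope="session")
def small_dataset():
    """n=800 synthetic dataset over four variables with known truth."""
    covs = ll.sample_covariates(ll.default_scheme(), 800, seed=42)
    covs.covariates = covs.covariates[["gender", "bike_type", "workday"]]
    truth = ll.TrueModel(
        mu={
            "intercept": -0.8,
            "gender:male vs female": 0.5,
            "bike_type:e_bike vs c_bike": 1.0,
            "bike_type:e_scooter vs c_bike": 1.5,
            "bike_type:tricycle vs c_bike": 2.0,
            "workday:yes vs no": 0.9,
        },
        seed=42,
    )
    return ll.simulate_outcomes(covs, truth)


@pytest.fixture(scope="session")
def small_design(small_dataset):
    return small_dataset.design


@pytest.fixture()
def toy_design():
    """Three observations, intercept plus one dummy."""
    X = np.array([[1.0, 0.0], [1.0, 1.0], [1.0, 1.0]])
    return ll.DesignMatrix(
        X=X, columns=["intercept", "x:1 vs 0"], column_info={"x:1 vs 0": ("x", "1", "0")}
    )
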