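import numpy as np
import pandas as pd
import pytest

from mirisk import (
    CohortSpec,
    CovariateSpec,
    SimulationTruth,
    generate_cohort,
)


def make_exponential_cohort(
    n=400, hazard=0.2, beta=0.0, censor_hi=6.0, seed=0, extra_noise=True
):
    """Simple exponential survival data with one normal covariate ``x``."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    h = hazard * np.exp(beta * x)
    T = rng.exponential(1.0 / h)
    C = rng.uniform(0.5, censor_hi, n)
    t = np.minimum(T, C)
    e = (T <= C).astype(int)
    df = pd.DataFrame({"time": t, "event": e, "x": x})
    if extra_noise:
        df["noise"] = rng.normal(size=n)
    return df


@pytest.fixture
def exp_cohort():
    return make_exponential_cohort(n=400, beta=0.7, seed=11)


@pytest.fixture
def single_node_truth():
    return SimulationTruth(
        tree={"leaf": "root", "hazard": 0.3},
        admin_censoring=(0.5, 5.5),
        dropout_rate=0.0,
    )


@pytest.fixture
def tiny_spec():
    return CohortSpec(
        n_subjects=200,
        covariates=[
            CovariateSpec("x1", "normal", {"mean": 0.0, "sd": 1.0}),
            CovariateSpec("x2", "binary", {"prevalence": 0.4}),
        ],
    )


@pytest.fixture
def small_cohort(tiny_spec, single_node_truth):
    cohort, _ = generate_cohort(tiny_spec, single_node_truth, seed=5)
    return cohort
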