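import numpy as np
import pandas as pd
import pytest

from spemlab import TaskConfig, simulate_session
from spemlab.simulate import FEATURES, SubjectProfile


@pytest.fixture(scope="session")
def task_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def noiseless_profile():
    # plausible control-like ground truth
    return SubjectProfile(
        true_gain_predictive=0.93,
        true_gain_early=0.79,
        true_accel=80.0,
        true_latency=176.0,
        saccade_threshold=2.0,
        blink_rate=0.0,
        noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_session(task_config, noiseless_profile):
    return simulate_session(task_config, noiseless_profile, seed=42)


def make_gaussian_table(n_per_class: int, separation: float, seed: int) -> pd.DataFrame:
    """Two spherical-Gaussian classes separated by ``separation`` SDs."""
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [
            rng.normal(0.0, 1.0, (n_per_class, 4)),
            rng.normal(separation, 1.0, (n_per_class, 4)),
        ]
    )
    df = pd.DataFrame(X, columns=list(FEATURES))
    df["group"] = ["control"] * n_per_class + ["psychosis"] * n_per_class
    return df


@pytest.fixture(scope="session")
def separable_table():
    return make_gaussian_table(100, 6.0, seed=11)


@pytest.fixture(scope="session")
def noise_table():
    return make_gaussian_table(100, 0.0, seed=12)


QUICK_GRID = dict(
    classifiers=("svm", "gaussian_nb", "logistic"),
    svm_kernels=("linear",),
    svm_C=(0.5, 1.0),
    balancers=("undersample",),
    n_components=(2, 4),
)

TINY_GRID = dict(
    classifiers=("gaussian_nb",),
    balancers=("undersample",),
    n_components=(4,),
)
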