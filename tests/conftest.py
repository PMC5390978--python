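import numpy as np
import pytest

from dispersalkit.diffusion import DiffusionParams, eval_model

RINGS = np.array([40.0, 80.0, 160.0, 320.0, 640.0, 960.0])

#: fitted heterogeneous-model parameters of the study's best model
BEST_PARAMS = dict(A1_prime=3.2, B1=21.6, A2_prime=0.04, B2=1022.0)


@pytest.fixture(scope="session")
def rings():
    return RINGS.copy()


@pytest.fixture(scope="session")
def het_params():
    return DiffusionParams(kind="heterogeneous", **BEST_PARAMS)


def noisy_mixture_dataset(seed, n_replicates=6, noise=0.05):
    """Ring x release percentages from the heterogeneous curve with
    multiplicative Gaussian noise."""
    rng = np.random.default_rng(seed)
    r_all = np.tile(RINGS, n_replicates)
    mu = eval_model(DiffusionParams(kind="heterogeneous", **BEST_PARAMS), r_all)
    y = mu * (1.0 + noise * rng.standard_normal(mu.shape))
    return r_all, np.abs(y)


@pytest.fixture()
def mixture_dataset():
    return noisy_mixture_dataset(seed=42)
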