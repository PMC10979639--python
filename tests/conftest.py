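import numpy as np
import pytest

from scatinception.network import ModelConfig
from scatinception.synthetic_mri import PhenotypeParams, generate_case, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def gbm_case():
    return generate_case(PhenotypeParams.default("GBM", noise_sd=0.0), seed=11)


@pytest.fixture
def met_case():
    return generate_case(PhenotypeParams.default("MET", noise_sd=0.0), seed=12)


@pytest.fixture(scope="session")
def small_cohort():
    """8 cases (4 GBM / 4 MET), noise-free, shared across tests."""
    _, cases = generate_cohort(4, 4, seed=5, noise_sd=0.0)
    return cases


@pytest.fixture
def tiny_model_cfg():
    return ModelConfig(
        input_size=(32, 32), width_multiplier=0.1, stem_channels=8, dropout_rate=0.0, seed=3
    )


def jitter_params(module, rng, scale=0.05):
    """Move parameters off exact-zero ReLU kinks before gradchecking."""
    for p in module.params():
        p.data = p.data.astype(np.float64) + rng.normal(0, scale, p.data.shape)
        p.grad = np.zeros_like(p.data)


def numeric_grad(loss_fn, param, idx, eps=1e-6):
    orig = param.data.flat[idx]
    param.data.flat[idx] = orig + eps
    lp = loss_fn()
    param.data.flat[idx] = orig - eps
    lm = loss_fn()
    param.data.flat[idx] = orig
    return (lp - lm) / (2 * eps)
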