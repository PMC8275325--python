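import numpy as np
import pytest

from pharmadapt import DrugResponseDataset, ModelConfig, MtlScenario, generate_mtl
from pharmadapt.model import init_model


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_dataset(rng):
    """6 samples x 7 genes x 3 drugs with a couple of masked entries."""
    X = rng.standard_normal((6, 7))
    Y = rng.standard_normal((6, 3))
    mask = np.ones((6, 3), dtype=bool)
    mask[0, 1] = mask[4, 2] = False
    return DrugResponseDataset(expression=X, response=Y, mask=mask)


@pytest.fixture
def tiny_model():
    cfg = ModelConfig(n_latent=4, dropout_rate=0.3, seed=7)
    params = init_model(cfg, n_genes=7, n_tasks=3)
    return params, cfg


@pytest.fixture
def noiseless_data():
    scen = MtlScenario(
        n_genes=20, n_latent=4, n_tasks=5,
        samples_per_task=[80] * 5,
        noise_sd_per_task=[0.0] * 5,
        sparsity=0.0,
        seed=11,
    )
    return generate_mtl(scen)
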