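import numpy as np
import pytest

from paravae.phantom import PhantomConfig, generate_dataset
from paravae.vae import LossWeights, VAEConfig, train_single_vae
from paravae.parallel import train_parallel_vae

# small 32x32 configurations keep the unit-level training tests fast;
# acceptance-scale runs live in test_acceptance.py

TINY_SIDE = 32


@pytest.fixture(scope="session")
def tiny_phantom_config():
    return PhantomConfig(image_side=TINY_SIDE, seed=5)


@pytest.fixture(scope="session")
def tiny_records(tiny_phantom_config):
    return generate_dataset(40, tiny_phantom_config)


@pytest.fixture(scope="session")
def tiny_vae_config():
    return VAEConfig(image_side=TINY_SIDE, n_latent=8, epochs=30, batch_size=16)


@pytest.fixture(scope="session")
def tiny_single_model(tiny_records, tiny_vae_config):
    images = [r.image_a for r in tiny_records[:30]] + \
             [r.image_b for r in tiny_records[:30]]
    return train_single_vae(images, LossWeights.single_default(),
                            tiny_vae_config, np.random.default_rng(1))


@pytest.fixture(scope="session")
def tiny_parallel_model(tiny_records, tiny_vae_config):
    return train_parallel_vae(tiny_records[:30], LossWeights.preset("loss2"),
                              tiny_vae_config, np.random.default_rng(1))
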