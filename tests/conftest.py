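import numpy as np
import pytest

import statcell as sc


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_params():
    """Desk-scale phantom geometry used across the suite."""
    return sc.PhantomParams(
        image_shape=(32, 32), cell_semiaxes=(12.0, 9.0), nucleus_semiaxes=(5.5, 4.0)
    )


@pytest.fixture(scope="session")
def small_population(tiny_params):
    return sc.generate_population(
        16, {"envelope": 0.5, "control_dna_dup": 0.5}, tiny_params, seed=3
    )


@pytest.fixture(scope="session")
def tiny_spec():
    return sc.NetworkSpec(
        dimensionality=2,
        input_shape=(32, 32),
        input_channels=2,
        channels=(3, 4),
        latent_dim=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_model(tiny_spec):
    return sc.build_reference_model(tiny_spec)
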