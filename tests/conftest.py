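import numpy as np
import pytest

import alignsim as al


@pytest.fixture(scope="session")
def mirror10():
    """Noiseless 10-concept world: both modalities are isometric images of
    the same latents, so the true mapping aligns perfectly."""
    return al.make_fixture("mirror10")


@pytest.fixture(scope="session")
def noisy30():
    return al.make_fixture("noisy30")


@pytest.fixture(scope="session")
def planted60():
    return al.make_fixture("planted60")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_system(rng, n, dim, modality="visual", prefix="c"):
    return al.EmbeddingSystem(
        modality,
        tuple(f"{prefix}{i}" for i in range(n)),
        rng.standard_normal((n, dim)),
    )


@pytest.fixture()
def make_system():
    return random_system
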