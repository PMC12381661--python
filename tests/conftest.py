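import numpy as np
import pytest

from rootletreg import PhantomSpec, generate_phantom
from rootletreg.pipeline import TemplateBundle


@pytest.fixture(scope="session")
def template_set():
    """Clean (noise-free, straight) template phantom shared across tests."""
    return generate_phantom(PhantomSpec(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def template_bundle(template_set):
    return TemplateBundle(
        image=template_set.image,
        cord=template_set.cord,
        rootlets=template_set.rootlets,
        discs=template_set.discs,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
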