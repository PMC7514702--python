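import numpy as np
import pytest

from ishcdae.synthetic import SyntheticSpec, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """Desk-scale corpus: 64x32 images, 80 genes, 2 categories."""
    spec = SyntheticSpec(image_height=64, image_width=32, n_genes=80,
                         n_categories=2, positives_per_category=(15, 20),
                         pool_stages=4, seed=42)
    return generate_corpus(spec)


@pytest.fixture(scope="session")
def small_stack(small_corpus):
    return np.stack([im.pixels for im in small_corpus.images])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
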