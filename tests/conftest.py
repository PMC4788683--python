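import numpy as np
import pytest

import domlink as dl


@pytest.fixture
def two_domain_definition():
    """Segments whose residue annotation is the canonical worked example."""
    return dl.DomainDefinition(((4, 11), (14, 18)))


@pytest.fixture
def small_dataset():
    """A small synthetic dataset under the default study conditions."""
    return dl.sample_dataset(dl.ArchitectureParams(n_proteins=18, seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_annotation(rng, length, alphabet="DL"):
    letters = rng.choice(list(alphabet), size=length)
    return dl.ResidueAnnotation("".join(letters))
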