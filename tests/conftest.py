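import numpy as np
import pytest

from peakflow import FixtureSpec, make_annotation, make_count_matrix


@pytest.fixture(scope="session")
def default_spec():
    return FixtureSpec(seed=7)


@pytest.fixture(scope="session")
def annotation(default_spec):
    return make_annotation(default_spec)


@pytest.fixture(scope="session")
def blob_matrix():
    """Normalized-scale matrix with 3 planted, well-separated clusters."""
    from peakflow import normalize

    matrix, labels, _ = make_count_matrix(FixtureSpec(seed=11, planted_k=3))
    return normalize(matrix), labels


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
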