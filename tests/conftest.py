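import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from deserthub.core import GenomicInterval
from deserthub.contacts import ContactMatrix
from deserthub.simulate import default_locus_model, simulate_fragment_map


@pytest.fixture(scope="session")
def locus_model():
    """Default study-geometry locus, modest depth for unit tests."""
    return default_locus_model(n_pairs=100_000, seed=0)


@pytest.fixture(scope="session")
def fragmap(locus_model):
    return simulate_fragment_map(locus_model.region, 256, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_balanced(values: np.ndarray, binsize: int = 5_000) -> ContactMatrix:
    """Wrap a symmetric array as a (fabricated) balanced matrix."""
    n = values.shape[0]
    return ContactMatrix(
        region=GenomicInterval("chrT", 0, n * binsize),
        binsize=binsize,
        matrix=values,
        mask=np.ones(n, dtype=bool),
        stage="balanced",
        ignore_diags=0,
    )


def two_block_matrix(
    n: int, junction: int, intra: float, inter: float, noise: float, seed: int
) -> ContactMatrix:
    """Two dense blocks with a contact-depleted junction between them."""
    rng = np.random.default_rng(seed)
    m = np.full((n, n), float(inter))
    m[:junction, :junction] = intra
    m[junction:, junction:] = intra
    m += rng.normal(0, noise, (n, n))
    m = np.triu(m) + np.triu(m, 1).T
    m = np.clip(m, 0.01, None)
    return make_balanced(m)
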