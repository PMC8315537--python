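import numpy as np
import pytest

from dartpop import SimConfig, generate_collection, gower_matrix


@pytest.fixture(scope="session")
def small_collection():
    """A 40-accession dual-platform collection with two planted clone groups."""
    cfg = SimConfig(
        n_accessions=40,
        n_landrace=20,
        n_improved=10,
        n_snp=2000,
        n_silico=2000,
        clone_groups=((4, "landrace"), (2, "landrace")),
        n_replicates=3,
        seed=11,
    )
    snp, sil, truth = generate_collection(cfg)
    return cfg, snp, sil, truth


@pytest.fixture(scope="session")
def small_distances(small_collection):
    _, snp, sil, _ = small_collection
    return gower_matrix(snp), gower_matrix(sil)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
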