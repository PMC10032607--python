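import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from coliaspop.core import GenotypeMatrix, Morph, SampleInfo, SampleSheet


def make_matrix(genotypes, samples=None, chrom="chr1", pos=None):
    """GenotypeMatrix from a nested list of dosages (-1 = missing)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n_sites, n_samples = g.shape
    if samples is None:
        samples = [f"s{i}" for i in range(n_samples)]
    if pos is None:
        pos = np.arange(n_sites)
    return GenotypeMatrix(
        chrom=np.asarray([chrom] * n_sites, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(["A"] * n_sites, dtype=object),
        alt=np.asarray(["T"] * n_sites, dtype=object),
        genotypes=g,
        samples=list(samples),
    )


def random_matrix(rng, n_sites=200, n_samples=8, missing_rate=0.05):
    g = rng.integers(0, 3, size=(n_sites, n_samples)).astype(np.int8)
    g[rng.random(g.shape) < missing_rate] = -1
    return make_matrix(g)


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def quartet_sheet():
    infos = []
    for sp, morph in [
        ("P1", Morph.colored),
        ("P2", Morph.alba),
        ("P3", Morph.alba),
        ("O", Morph.colored),
    ]:
        for k in range(2):
            infos.append(SampleInfo(f"{sp}_{k}", sp, morph=morph))
    return SampleSheet(infos)
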