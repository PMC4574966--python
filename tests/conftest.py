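import numpy as np
import pytest

from raschgwas.genotypes import GenotypeMatrix
from raschgwas.rasch_core import ItemThresholds, simulate_pcm_responses


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def pcm_dataset(rng):
    """PCM responses from known, sum-zero thresholds (6 tri-category items)."""
    taus = [rng.normal(0.0, 0.7, 2) for _ in range(6)]
    shift = np.mean(np.concatenate(taus))
    taus = [t - shift for t in taus]
    thresholds = ItemThresholds(taus)
    data = simulate_pcm_responses(thresholds, rng.normal(0.0, 1.0, 400), rng)
    return thresholds, data


@pytest.fixture
def balanced_trait():
    from raschgwas.association import TraitVector

    y = np.concatenate([np.ones(250), np.zeros(250)])
    return TraitVector(y)


@pytest.fixture
def snp_panel(rng):
    """Null 0/1/2 genotype panel, 500 subjects x 10 SNPs, MAF ~ 0.2-0.5."""
    maf = rng.uniform(0.2, 0.5, 10)
    u = rng.random((500, 10, 2))
    values = (u < maf[None, :, None]).sum(axis=2).astype(np.int16)
    return GenotypeMatrix(values)
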