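import numpy as np
import pytest

from gentag.dataset import (
    GenotypeDataset,
    Locus,
    SampleMetadata,
    allele_frequencies,
)
from gentag import simulate as sim


def make_dataset(genotypes, populations=None, ids=None, loci=None, **meta_kwargs):
    """Small-dataset builder: genotypes is (n, L, 2) array-like."""
    g = np.asarray(genotypes, dtype=np.int32)
    n, L = g.shape[:2]
    if loci is None:
        loci = [Locus(f"L{j + 1}") for j in range(L)]
    if ids is None:
        ids = [f"s{i + 1}" for i in range(n)]
    if populations is None:
        populations = ["pop1"] * n
    samples = [
        SampleMetadata(sample_id=i, population=p) for i, p in zip(ids, populations)
    ]
    return GenotypeDataset(loci, samples, g)


@pytest.fixture(scope="session")
def field_survey():
    """407 individuals, 19 loci, 4 weakly differentiated populations."""
    return sim.field_survey_dataset(seed=11)


@pytest.fixture(scope="session")
def field_survey_freqs(field_survey):
    return allele_frequencies(field_survey)
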