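import numpy as np
import pytest

from genefp.corpus_io import (
    AnnotationCorpus,
    DiseasePubmedRecord,
    GenePubmedRecord,
    build_corpus,
)
from genefp.synthetic import SyntheticSpec, generate


@pytest.fixture
def small_corpus() -> AnnotationCorpus:
    """Hand-built corpus: 2 diseases, 6 PMIDs, 3 genes.

    DA on pmids {1,2,3}, DB on {4,5}, pmid 6 carries no universe disease.
    Gene 10 co-occurs with DA on {1,2}; gene 20 with DA on {3} and DB on {4};
    gene 30 only on pmid 6 (outside the universe).
    """
    gene_records = [
        GenePubmedRecord(9606, 10, 1),
        GenePubmedRecord(9606, 10, 2),
        GenePubmedRecord(9606, 20, 3),
        GenePubmedRecord(9606, 20, 4),
        GenePubmedRecord(9606, 30, 6),
    ]
    disease_records = [
        DiseasePubmedRecord(1, "DA"),
        DiseasePubmedRecord(2, "DA"),
        DiseasePubmedRecord(3, "DA"),
        DiseasePubmedRecord(4, "DB"),
        DiseasePubmedRecord(5, "DB"),
        DiseasePubmedRecord(6, "DX"),
    ]
    return build_corpus(gene_records, disease_records, ["DA", "DB"])


@pytest.fixture(scope="session")
def planted_corpus():
    """Default synthetic corpus (3 clusters x 6 diseases) with its truth."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
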