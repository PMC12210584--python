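import numpy as np
import pytest

from anosurv.io import GeneModel, GenotypeMatrix, HaplotypeMatrix, SampleRecord


@pytest.fixture
def toy_haplotypes() -> HaplotypeMatrix:
    """3 samples x 5 phased sites with a mix of frequencies."""
    m = np.array(
        [
            [0, 1, 0, 1, 1],
            [0, 1, 0, 0, 1],
            [1, 0, 0, 1, 0],
            [0, 0, 0, 1, 0],
            [1, 1, 1, 1, 0],
            [0, 1, 0, 1, 1],
        ],
        dtype=np.int8,
    )
    return HaplotypeMatrix(
        contig="2R",
        positions=np.array([100, 205, 333, 560, 1200]),
        ref=np.array(list("ACGTA")),
        alt=np.array(list("TGCAC")),
        matrix=m,
        sample_ids=("s1", "s2", "s3"),
    )


@pytest.fixture
def toy_genotypes(toy_haplotypes) -> GenotypeMatrix:
    return toy_haplotypes.to_genotypes()


def make_sample(sid="s1", **kw) -> SampleRecord:
    defaults = dict(
        sample_id=sid,
        location="Turkana",
        year=2019,
        latitude=3.717,
        longitude=34.857,
        sex="F",
        insecticide="alpha-cypermethrin",
        outcome="alive",
        median_coverage=30.0,
        missingness=0.05,
        contamination=0.01,
    )
    defaults.update(kw)
    return SampleRecord(**defaults)


@pytest.fixture
def plus_strand_gene() -> GeneModel:
    # 12-codon CDS on the + strand starting at position 10
    return GeneModel(gene_id="AGAP_TEST", contig="2R", strand="+", cds=((10, 46),))
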