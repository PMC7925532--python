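import pytest

from kddcall import ExonInterval, GeneModel, load_packaged_gene_models


def make_gene(
    gene_id: str,
    intervals,
    kinase_domain,
    chrom: str = "chrT",
    strand: str = "+",
) -> GeneModel:
    """Build a GeneModel from genomic-order (start, end) exon intervals."""
    order = intervals if strand == "+" else list(reversed(intervals))
    exons = tuple(
        ExonInterval(chrom, s, e, i) for i, (s, e) in enumerate(order, 1)
    )
    return GeneModel(
        gene_id=gene_id,
        transcript_id=f"{gene_id}.t1",
        chrom=chrom,
        strand=strand,
        exons=exons,
        kinase_domain=tuple(kinase_domain),
    )


@pytest.fixture(scope="session")
def models():
    return load_packaged_gene_models()


@pytest.fixture(scope="session")
def egfr(models):
    return models["EGFR"]


@pytest.fixture(scope="session")
def toy_gene():
    """10 exons of 100 bp spaced 1 kb apart; kinase domain = exons 4-7."""
    ivs = [(1000 + i * 1000, 1100 + i * 1000) for i in range(10)]
    return make_gene("TOY", ivs, (4000, 7100))


@pytest.fixture(scope="session")
def gene70():
    """5-exon gene whose kinase domain has 1000 exonic bases split 700/300.

    The kinase domain spans exons 2 and 3 exactly, so a high cluster
    containing only exon 2 covers exactly 70% of the kinase domain.
    """
    ivs = [
        (1000, 1100),   # exon 1
        (2000, 2700),   # exon 2: 700 KD bases
        (3000, 3300),   # exon 3: 300 KD bases
        (4000, 4100),   # exon 4
        (5000, 5100),   # exon 5
    ]
    return make_gene("G70", ivs, (2000, 3300))
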