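import numpy as np
import pytest

from mbchip.models import GeneModel, Peak
from mbchip.regions import GenomicInterval


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_101)


def make_peak(contig="ctg1", start=1000, end=1400, name="p", q=5.0, fold=4.0,
              p=7.0, summit=200):
    return Peak(
        interval=GenomicInterval(contig, start, end),
        name=name,
        fold_enrichment=fold,
        neg_log10_p=p,
        neg_log10_q=q,
        summit_offset=summit,
    )


@pytest.fixture()
def two_exon_plus_gene():
    """+ strand gene: exons [1000,1500) and [2500,3000), CDS starting mid-exon-1."""
    c = "ctg1"
    return GeneModel(
        gene_id="LOC000001",
        span=GenomicInterval(c, 1000, 3000, "+"),
        exons=(GenomicInterval(c, 1000, 1500, "+"), GenomicInterval(c, 2500, 3000, "+")),
        cds=(GenomicInterval(c, 1200, 1500, "+"), GenomicInterval(c, 2500, 2800, "+")),
        description="two-exon plus gene",
    )


@pytest.fixture()
def two_exon_minus_gene():
    c = "ctg1"
    return GeneModel(
        gene_id="LOC000002",
        span=GenomicInterval(c, 10_000, 12_000, "-"),
        exons=(GenomicInterval(c, 10_000, 10_600, "-"), GenomicInterval(c, 11_400, 12_000, "-")),
        cds=(GenomicInterval(c, 10_200, 10_600, "-"), GenomicInterval(c, 11_400, 11_800, "-")),
        description="two-exon minus gene",
    )
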