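import pytest

from nascentrip.intervals import GeneModel, GenomicInterval


@pytest.fixture
def toy_genes():
    """Two genes on a 10 kb contig: a coding gene with UTR/CDS/intron
    structure and a noncoding gene, leaving intergenic space around them."""
    chrom = "chr1"
    coding = GeneModel(
        gene_id="gA",
        biotype="coding",
        span=GenomicInterval(chrom, 1000, 4000, "+"),
        exons=[
            GenomicInterval(chrom, 1000, 1500, "+"),
            GenomicInterval(chrom, 2500, 3000, "+"),
            GenomicInterval(chrom, 3600, 4000, "+"),
        ],
        utr5=[GenomicInterval(chrom, 1000, 1200, "+")],
        cds=[
            GenomicInterval(chrom, 1200, 1500, "+"),
            GenomicInterval(chrom, 2500, 3000, "+"),
            GenomicInterval(chrom, 3600, 3800, "+"),
        ],
        utr3=[GenomicInterval(chrom, 3800, 4000, "+")],
    )
    noncoding = GeneModel(
        gene_id="gB",
        biotype="noncoding",
        span=GenomicInterval(chrom, 6000, 9000, "-"),
        exons=[
            GenomicInterval(chrom, 6000, 6800, "-"),
            GenomicInterval(chrom, 8200, 9000, "-"),
        ],
    )
    for g in (coding, noncoding):
        g.validate()
    return [coding, noncoding]
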