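"""Hand-built annotation objects for unit tests."""

from circbalance.genome import (
    BindingSite,
    CircRNA,
    Exon,
    GeneModel,
    GenomicInterval,
    derive_introns,
)


def make_gene(
    gene_id,
    exon_spans,
    strand="+",
    chrom="chr1",
    biotype="coding",
    cds=None,
):
    """Gene model from genomic (start, end) exon spans, ordinals by strand."""
    spans = sorted(exon_spans)
    n = len(spans)
    exons = []
    for i, (s, e) in enumerate(spans):
        ordinal = i + 1 if strand == "+" else n - i
        exons.append(
            Exon(
                interval=GenomicInterval(chrom, s, e, strand),
                gene_id=gene_id,
                transcript_id=f"{gene_id}.t1",
                ordinal=ordinal,
            )
        )
    exons.sort(key=lambda e: e.ordinal)
    cds_start, cds_end = cds if cds else (None, None)
    if biotype == "coding" and cds is None:
        cds_start, cds_end = spans[0][0], spans[-1][1]
    return GeneModel(
        gene_id=gene_id,
        name=gene_id,
        biotype=biotype,
        chrom=chrom,
        strand=strand,
        exons=exons,
        introns=derive_introns(exons),
        cds_start=cds_start,
        cds_end=cds_end,
        transcript_id=f"{gene_id}.t1",
    )


def make_circ(circ_id, gene, acceptor, donor, counts=None):
    block = [e for e in gene.exons if acceptor <= e.ordinal <= donor]
    start = min(e.interval.start for e in block)
    end = max(e.interval.end for e in block)
    return CircRNA(
        circ_id=circ_id,
        gene_id=gene.gene_id,
        acceptor_exon_ordinal=acceptor,
        donor_exon_ordinal=donor,
        bsj_interval=GenomicInterval(gene.chrom, start, end, gene.strand),
        counts=counts or {},
    )


def make_site(site_id, start, end, chrom="chr1", strand="+", reads=10, p=0.01):
    return BindingSite(
        site_id=site_id,
        interval=GenomicInterval(chrom, start, end, strand),
        reads=reads,
        p_value=p,
    )
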