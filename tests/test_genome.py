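"""Annotation model: coordinate conversion, strand-aware ordinals, intervals."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from circbalance.genome import (
    GenomicInterval,
    ValidationError,
    assign_exon_ordinals,
    derive_introns,
    overlap,
)
from circbalance.io import read_gtf, write_gtf

from _factories import make_gene


def _gtf_text(strand):
    lines = [
        f'chr1\tx\tgene\t101\t400\t.\t{strand}\t.\tgene_id "g1"; gene_biotype "protein_coding";',
        f'chr1\tx\texon\t101\t200\t.\t{strand}\t.\tgene_id "g1"; transcript_id "t1";',
        f'chr1\tx\texon\t301\t400\t.\t{strand}\t.\tgene_id "g1"; transcript_id "t1";',
    ]
    return "\n".join(lines) + "\n"


@pytest.mark.parametrize(
    "strand,expected_ordinals",
    [("+", {(100, 200): 1, (300, 400): 2}), ("-", {(100, 200): 2, (300, 400): 1})],
)
def test_gtf_coordinates_and_strand_ordinals(tmp_path, strand, expected_ordinals):
    """1-based inclusive GTF becomes 0-based half-open; ordinals follow transcription."""
    p = tmp_path / "g.gtf"
    p.write_text(_gtf_text(strand))
    (gene,) = read_gtf(p)
    got = {(e.interval.start, e.interval.end): e.ordinal for e in gene.exons}
    assert got == expected_ordinals
    assert len(gene.introns) == 1
    assert (gene.introns[0].interval.start, gene.introns[0].interval.end) == (200, 300)


def test_three_exon_gene_introns_abut_neighbours(tmp_path):
    gene = make_gene("g", [(0, 10), (20, 30), (40, 50)])
    assert len(gene.introns) == 2
    # brute-force adjacency: every intron boundary coincides with an exon boundary
    exon_bounds = {b for e in gene.exons for b in (e.interval.start, e.interval.end)}
    for i in gene.introns:
        assert i.interval.start in exon_bounds and i.interval.end in exon_bounds
    # and exons+introns tile the span without gaps or overlaps
    pieces = sorted(
        [(e.interval.start, e.interval.end) for e in gene.exons]
        + [(i.interval.start, i.interval.end) for i in gene.introns]
    )
    for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
        assert e1 == s2
    assert pieces[0][0] == gene.start and pieces[-1][1] == gene.end


def test_derive_introns_cases():
    single = make_gene("g", [(0, 10)])
    assert single.introns == []

    plus = make_gene("g", [(0, 10), (20, 30), (40, 50)], strand="+")
    spans = [(i.interval.start, i.interval.end) for i in plus.introns]
    assert spans == [(10, 20), (30, 40)]

    minus = make_gene("g", [(0, 10), (20, 30)], strand="-")
    (intron,) = minus.introns
    assert (intron.interval.start, intron.interval.end) == (10, 20)
    # the (20,30) exon is transcriptionally first on "-": ordinal 1
    assert intron.upstream_exon_ordinal == 1


def test_overlapping_exons_rejected():
    with pytest.raises(ValidationError):
        make_gene("g", [(0, 10), (5, 20)])


def test_malformed_gtf_reports_line_number(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text("chr1\tonly three\tfields\n")
    with pytest.raises(ValueError, match=":1:"):
        read_gtf(p)


def test_exon_outside_gene_span_rejected(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text(
        'chr1\tx\tgene\t101\t200\t.\t+\t.\tgene_id "g1";\n'
        'chr1\tx\texon\t101\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    )
    with pytest.raises(ValidationError):
        read_gtf(p)


def test_representative_transcript_longest_then_lexicographic(tmp_path):
    p = tmp_path / "g.gtf"
    p.write_text(
        'chr1\tx\tgene\t1\t1000\t.\t+\t.\tgene_id "g1";\n'
        'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "g1"; transcript_id "tB";\n'
        'chr1\tx\texon\t1\t300\t.\t+\t.\tgene_id "g1"; transcript_id "tA";\n'
        'chr1\tx\texon\t1\t300\t.\t+\t.\tgene_id "g1"; transcript_id "tC";\n'
    )
    (gene,) = read_gtf(p)
    assert gene.transcript_id == "tA"  # longest wins; tie broken by smaller id


@pytest.mark.parametrize(
    "a,b,expected",
    [((0, 10), (10, 20), 0), ((0, 10), (5, 8), 3), ((0, 10), (20, 30), 0)],
)
def test_overlap_examples(a, b, expected):
    ia = GenomicInterval("chr1", *a)
    ib = GenomicInterval("chr1", *b)
    assert overlap(ia, ib) == expected


def test_overlap_different_chrom_is_zero():
    assert overlap(GenomicInterval("chr1", 0, 10), GenomicInterval("chr2", 0, 10)) == 0


@given(
    st.tuples(st.integers(0, 1000), st.integers(1, 60)),
    st.tuples(st.integers(0, 1000), st.integers(1, 60)),
)
def test_overlap_matches_per_base_oracle(a, b):
    """Overlap equals a per-base membership count and is symmetric and bounded."""
    ia = GenomicInterval("chr1", a[0], a[0] + a[1])
    ib = GenomicInterval("chr1", b[0], b[0] + b[1])
    brute = len(set(range(ia.start, ia.end)) & set(range(ib.start, ib.end)))
    assert overlap(ia, ib) == brute == overlap(ib, ia)
    assert overlap(ia, ib) <= min(len(ia), len(ib))


def test_gtf_round_trip_preserves_models(tmp_path, small_sim_dir):
    result, _ = small_sim_dir
    out = tmp_path / "rt.gtf"
    write_gtf(result.genes, out)
    back = read_gtf(out)
    assert len(back) == len(result.genes)
    by_id = {g.gene_id: g for g in back}
    for g in result.genes:
        h = by_id[g.gene_id]
        assert h.strand == g.strand and h.chrom == g.chrom
        assert [
            (e.interval.start, e.interval.end, e.ordinal) for e in h.exons
        ] == [(e.interval.start, e.interval.end, e.ordinal) for e in g.exons]
        assert h.biotype == g.biotype


def test_exons_and_introns_tile_transcript_span(default_sim):
    for g in default_sim.genes[:100]:
        pieces = sorted(
            [(e.interval.start, e.interval.end) for e in g.exons]
            + [(i.interval.start, i.interval.end) for i in g.introns]
        )
        for (s1, e1), (s2, e2) in zip(pieces, pieces[1:]):
            assert e1 == s2, g.gene_id
        assert pieces[0][0] == g.start and pieces[-1][1] == g.end


def test_assign_exon_ordinals_boundary_matching():
    gene = make_gene("g", [(0, 10), (20, 30), (40, 50)], strand="-")
    # genomic span 20..50 covers the two transcriptionally first exons (ord 1,2)
    assert assign_exon_ordinals(20, 50, gene) == (1, 2)
    assert assign_exon_ordinals(21, 50, gene) is None  # not an exon start
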