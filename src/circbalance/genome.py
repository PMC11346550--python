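"""Strand-aware annotation model and interval algebra.

All internal coordinates are 0-based half-open (BED convention); GTF I/O
converts at the boundary. "Upstream"/"downstream" always refer to the
direction of transcription, so on the minus strand exon ordinal 1 is the
genomically rightmost exon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "GenomicInterval",
    "Exon",
    "Intron",
    "GeneModel",
    "CircRNA",
    "BindingSite",
    "overlap",
    "derive_introns",
    "assign_exon_ordinals",
    "ValidationError",
]


class ValidationError(ValueError):
    """An annotation object violates a structural invariant."""


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValidationError(f"negative start: {self}")
        if self.end <= self.start:
            raise ValidationError(f"empty or inverted interval: {self}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"strand must be '+' or '-': {self!r}")

    def __len__(self) -> int:
        return self.end - self.start


def overlap(a: GenomicInterval, b: GenomicInterval) -> int:
    """Length in bp of the intersection of two intervals.

    Half-open semantics: touching intervals overlap by 0. Strand is
    ignored; intervals on different chromosomes never overlap.
    """
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


@dataclass(frozen=True)
class Exon:
    interval: GenomicInterval
    gene_id: str
    transcript_id: str
    ordinal: int  # 1-based, transcription order


@dataclass(frozen=True)
class Intron:
    interval: GenomicInterval
    gene_id: str
    upstream_exon_ordinal: int  # ordinal of the transcriptionally preceding exon


@dataclass
class GeneModel:
    """One gene reduced to a single representative transcript.

    ``cds_start``/``cds_end`` give the genomic CDS span of the representative
    transcript for coding genes (None for noncoding). Exon portions outside
    the CDS span are UTR; which side is 5' depends on strand.
    """

    gene_id: str
    name: str
    biotype: str  # "coding" | "noncoding"
    chrom: str
    strand: str
    exons: list[Exon] = field(default_factory=list)
    introns: list[Intron] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None
    transcript_id: str = ""

    @property
    def start(self) -> int:
        return min(e.interval.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.interval.end for e in self.exons)

    @property
    def length(self) -> int:
        """Gene span in bp (max exon end minus min exon start)."""
        return self.end - self.start

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    def exon_by_ordinal(self, ordinal: int) -> Exon:
        for e in self.exons:
            if e.ordinal == ordinal:
                return e
        raise KeyError(f"{self.gene_id}: no exon with ordinal {ordinal}")

    def intron_after(self, exon_ordinal: int) -> Intron | None:
        """Intron transcriptionally following the given exon, if any."""
        for i in self.introns:
            if i.upstream_exon_ordinal == exon_ordinal:
                return i
        return None

    def feature_intervals(self) -> dict[str, list[tuple[int, int]]]:
        """Genomic (start, end) tuples per feature class of this gene.

        Coding exon bases are split into CDS / 5'UTR / 3'UTR by the CDS
        span; all exon bases of noncoding genes are ``noncoding_exon``.
        """
        out: dict[str, list[tuple[int, int]]] = {
            "CDS": [],
            "5'UTR": [],
            "3'UTR": [],
            "noncoding_exon": [],
            "intron": [(i.interval.start, i.interval.end) for i in self.introns],
        }
        if self.biotype != "coding" or self.cds_start is None:
            out["noncoding_exon"] = [
                (e.interval.start, e.interval.end) for e in self.exons
            ]
            return out
        cs, ce = self.cds_start, self.cds_end
        assert ce is not None
        # genomic left of CDS is 5'UTR on "+", 3'UTR on "-"
        left_utr = "5'UTR" if self.strand == "+" else "3'UTR"
        right_utr = "3'UTR" if self.strand == "+" else "5'UTR"
        for e in self.exons:
            s, t = e.interval.start, e.interval.end
            if s < cs:
                out[left_utr].append((s, min(t, cs)))
            if max(s, cs) < min(t, ce):
                out["CDS"].append((max(s, cs), min(t, ce)))
            if t > ce:
                out[right_utr].append((max(s, ce), t))
        return out


@dataclass
class CircRNA:
    """A backsplice junction with per-sample BSJ read counts.

    The acceptor exon is the transcriptionally first circularised exon and
    the donor the last; ``bsj_interval`` is the genomic span covered by the
    circularised exon block.
    """

    circ_id: str
    gene_id: str
    acceptor_exon_ordinal: int
    donor_exon_ordinal: int
    bsj_interval: GenomicInterval
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.acceptor_exon_ordinal > self.donor_exon_ordinal:
            raise ValidationError(
                f"{self.circ_id}: acceptor ordinal {self.acceptor_exon_ordinal} "
                f"after donor ordinal {self.donor_exon_ordinal}"
            )
        for s, c in self.counts.items():
            if c < 0:
                raise ValidationError(f"{self.circ_id}: negative count in {s}")

    @property
    def exon_ordinals(self) -> range:
        return range(self.acceptor_exon_ordinal, self.donor_exon_ordinal + 1)


@dataclass(frozen=True)
class BindingSite:
    """A protein-RNA crosslink peak with read support and a p-value."""

    site_id: str
    interval: GenomicInterval
    reads: int
    p_value: float

    def __post_init__(self) -> None:
        if self.reads < 0:
            raise ValidationError(f"{self.site_id}: negative read count")
        if not (0.0 <= self.p_value <= 1.0):
            raise ValidationError(f"{self.site_id}: p-value outside [0, 1]")


def derive_introns(exons: Iterable[Exon]) -> list[Intron]:
    """Introns as the gaps between consecutive exons of one transcript.

    Intron ordinals follow transcription order: the intron after exon k
    (transcriptionally) carries ``upstream_exon_ordinal = k``. Overlapping
    exons raise :class:`ValidationError`.
    """
    exs = sorted(exons, key=lambda e: e.interval.start)
    if not exs:
        return []
    strand = exs[0].interval.strand
    gene_id = exs[0].gene_id
    introns: list[Intron] = []
    for left, right in zip(exs, exs[1:]):
        if right.interval.start < left.interval.end:
            raise ValidationError(
                f"{gene_id}: overlapping exons "
                f"{left.interval.start}-{left.interval.end} and "
                f"{right.interval.start}-{right.interval.end}"
            )
        if right.interval.start == left.interval.end:
            continue  # abutting exons leave no intron
        # transcriptionally upstream exon: left on "+", right on "-"
        up = left if strand == "+" else right
        introns.append(
            Intron(
                interval=GenomicInterval(
                    left.interval.chrom,
                    left.interval.end,
                    right.interval.start,
                    strand,
                ),
                gene_id=gene_id,
                upstream_exon_ordinal=up.ordinal,
            )
        )
    return introns


def assign_exon_ordinals(
    circ_start: int, circ_end: int, gene: GeneModel
) -> tuple[int, int] | None:
    """Map a BSJ genomic span onto the gene's exon ordinals.

    The acceptor boundary must coincide with an exon start and the donor
    boundary with an exon end (in genomic coordinates the span runs from an
    exon start to an exon end regardless of strand). Returns
    ``(acceptor_ordinal, donor_ordinal)`` in transcription order, or None
    when no exon boundaries match.
    """
    start_exon = next(
        (e for e in gene.exons if e.interval.start == circ_start), None
    )
    end_exon = next((e for e in gene.exons if e.interval.end == circ_end), None)
    if start_exon is None or end_exon is None:
        return None
    ords = sorted((start_exon.ordinal, end_exon.ordinal))
    return ords[0], ords[1]
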