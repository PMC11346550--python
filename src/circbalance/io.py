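"""Readers and writers for the formats the pipeline exchanges.

GTF is the Ensembl dialect (1-based inclusive coordinates, ``gene_id``/
``transcript_id`` attributes); binding peaks are BED6 plus two extra
columns (read count, p-value); count tables are TSV with a header. All
coordinates are converted to 0-based half-open at the boundary.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable

import pandas as pd

from .genome import (
    BindingSite,
    CircRNA,
    Exon,
    GeneModel,
    GenomicInterval,
    ValidationError,
    derive_introns,
)

__all__ = [
    "GTFParseError",
    "read_gtf",
    "write_gtf",
    "read_sites_bed",
    "write_sites_bed",
    "read_circ_table",
    "write_circ_table",
    "read_gene_counts",
    "write_gene_counts",
    "write_fasta",
]

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


class GTFParseError(ValueError):
    """A malformed GTF line, reported with its line number."""


def _parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Load gene models from a GTF file, one representative transcript each.

    The representative transcript is the one with the largest summed exon
    length (ties broken by lexicographically smallest transcript_id). Exon
    ordinals are assigned in transcription order and introns derived as the
    gaps between consecutive exons.
    """
    genes: dict[str, dict] = {}
    # transcript_id -> list of (start, end); CDS spans per transcript
    tx_exons: dict[tuple[str, str], list[tuple[int, int]]] = {}
    tx_cds: dict[tuple[str, str], list[tuple[int, int]]] = {}

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"{path}:{lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            try:
                start = int(start_s) - 1  # GTF is 1-based inclusive
                end = int(end_s)
            except ValueError as exc:
                raise GTFParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            if strand not in ("+", "-"):
                raise GTFParseError(f"{path}:{lineno}: bad strand {strand!r}")
            attrs = _parse_attributes(attrs_s)
            gid = attrs.get("gene_id")
            if gid is None:
                raise GTFParseError(f"{path}:{lineno}: missing gene_id")

            if feature == "gene":
                genes[gid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "start": start,
                    "end": end,
                    "name": attrs.get("gene_name", gid),
                    "biotype": attrs.get("gene_biotype", "protein_coding"),
                }
            elif feature in ("exon", "CDS"):
                tid = attrs.get("transcript_id")
                if tid is None:
                    raise GTFParseError(
                        f"{path}:{lineno}: {feature} without transcript_id"
                    )
                key = (gid, tid)
                target = tx_exons if feature == "exon" else tx_cds
                target.setdefault(key, []).append((start, end))
            # transcript and other feature lines carry no extra information

    out: list[GeneModel] = []
    by_gene: dict[str, list[str]] = {}
    for gid, tid in tx_exons:
        by_gene.setdefault(gid, []).append(tid)

    for gid, tids in by_gene.items():
        meta = genes.get(gid)
        if meta is None:
            # gene line absent; metadata cannot be inferred reliably
            meta = {
                "chrom": None,
                "strand": None,
                "start": None,
                "end": None,
                "name": gid,
                "biotype": "protein_coding",
            }
        # representative transcript: longest summed exon length, then id
        def _key(tid: str) -> tuple[int, str]:
            exs = tx_exons[(gid, tid)]
            return (-sum(e - s for s, e in exs), tid)

        rep = sorted(tids, key=_key)[0]
        exon_spans = sorted(tx_exons[(gid, rep)])
        gene = _build_gene(gid, rep, meta, exon_spans, tx_cds.get((gid, rep)))
        out.append(gene)
    out.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return out


def _build_gene(
    gid: str,
    tid: str,
    meta: dict,
    exon_spans: list[tuple[int, int]],
    cds_spans: list[tuple[int, int]] | None,
) -> GeneModel:
    chrom = meta["chrom"]
    strand = meta["strand"]
    if chrom is None or strand is None:
        raise GTFParseError(f"gene {gid}: no gene line and no inferable metadata")
    if meta["start"] is not None:
        gspan = (meta["start"], meta["end"])
        for s, e in exon_spans:
            if s < gspan[0] or e > gspan[1]:
                raise ValidationError(
                    f"gene {gid}: exon {s}-{e} outside gene span {gspan}"
                )
    n = len(exon_spans)
    exons = []
    for i, (s, e) in enumerate(exon_spans):
        ordinal = i + 1 if strand == "+" else n - i
        exons.append(
            Exon(
                interval=GenomicInterval(chrom, s, e, strand),
                gene_id=gid,
                transcript_id=tid,
                ordinal=ordinal,
            )
        )
    exons.sort(key=lambda e: e.ordinal)
    introns = derive_introns(exons)
    biotype = "coding" if meta["biotype"] == "protein_coding" else "noncoding"
    cds_start = cds_end = None
    if cds_spans:
        cds_start = min(s for s, _ in cds_spans)
        cds_end = max(e for _, e in cds_spans)
    return GeneModel(
        gene_id=gid,
        name=meta["name"],
        biotype=biotype,
        chrom=chrom,
        strand=strand,
        exons=exons,
        introns=introns,
        cds_start=cds_start,
        cds_end=cds_end,
        transcript_id=tid,
    )


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Emit gene/transcript/exon (and CDS) lines, 1-based inclusive."""
    with open(path, "w") as fh:
        for g in genes:
            tid = g.transcript_id or f"{g.gene_id}.t1"
            bt = "protein_coding" if g.biotype == "coding" else "lncRNA"
            attrs = (
                f'gene_id "{g.gene_id}"; gene_name "{g.name}"; '
                f'gene_biotype "{bt}";'
            )
            tattrs = f'gene_id "{g.gene_id}"; transcript_id "{tid}"; gene_biotype "{bt}";'
            fh.write(
                f"{g.chrom}\tcircbalance\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            fh.write(
                f"{g.chrom}\tcircbalance\ttranscript\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{tattrs}\n"
            )
            for e in sorted(g.exons, key=lambda e: e.interval.start):
                fh.write(
                    f"{g.chrom}\tcircbalance\texon\t{e.interval.start + 1}\t"
                    f"{e.interval.end}\t.\t{g.strand}\t.\t{tattrs} "
                    f'exon_number "{e.ordinal}";\n'
                )
            if g.biotype == "coding" and g.cds_start is not None:
                for e in sorted(g.exons, key=lambda e: e.interval.start):
                    s = max(e.interval.start, g.cds_start)
                    t = min(e.interval.end, g.cds_end)
                    if s < t:
                        fh.write(
                            f"{g.chrom}\tcircbalance\tCDS\t{s + 1}\t{t}\t.\t"
                            f"{g.strand}\t.\t{tattrs}\n"
                        )


def read_sites_bed(path: str | Path) -> list[BindingSite]:
    """BED6+2 (chrom, start, end, name, score, strand, reads, p_value)."""
    sites: list[BindingSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                raise ValueError(
                    f"{path}:{lineno}: expected 8 columns (BED6+reads,p), got {len(f)}"
                )
            sites.append(
                BindingSite(
                    site_id=f[3],
                    interval=GenomicInterval(f[0], int(f[1]), int(f[2]), f[5]),
                    reads=int(f[6]),
                    p_value=float(f[7]),
                )
            )
    return sites


def write_sites_bed(sites: Iterable[BindingSite], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sites:
            iv = s.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.site_id}\t{s.reads}\t"
                f"{iv.strand}\t{s.reads}\t{s.p_value:.6g}\n"
            )


_CIRC_FIXED = ["circ_id", "chrom", "start", "end", "strand", "gene_id"]


def read_circ_table(path: str | Path) -> pd.DataFrame:
    """BSJ count table: circ_id, chrom, start, end, strand, gene_id, count_*."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _CIRC_FIXED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if not [c for c in df.columns if c.startswith("count_")]:
        raise ValueError(f"{path}: no count_<sample> columns")
    return df


def circs_from_table(df: pd.DataFrame, genes: dict[str, GeneModel]) -> list[CircRNA]:
    """Materialise CircRNA objects, mapping BSJ spans to exon ordinals.

    Rows whose junctions match no exon boundary of the annotated gene are
    skipped (the caller sees them dropped; a warnings list is not kept —
    use :func:`circbalance.genome.assign_exon_ordinals` directly to audit).
    """
    from .genome import assign_exon_ordinals

    count_cols = [c for c in df.columns if c.startswith("count_")]
    out: list[CircRNA] = []
    for row in df.itertuples(index=False):
        gene = genes.get(row.gene_id)
        if gene is None:
            continue
        ords = assign_exon_ordinals(int(row.start), int(row.end), gene)
        if ords is None:
            continue
        counts = {c[len("count_"):]: int(getattr(row, c)) for c in count_cols}
        out.append(
            CircRNA(
                circ_id=row.circ_id,
                gene_id=row.gene_id,
                acceptor_exon_ordinal=ords[0],
                donor_exon_ordinal=ords[1],
                bsj_interval=GenomicInterval(
                    row.chrom, int(row.start), int(row.end), row.strand
                ),
                counts=counts,
            )
        )
    return out


def write_circ_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_gene_counts(path: str | Path) -> pd.DataFrame:
    """Gene-level count table: gene_id, count_<sample>..."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: missing gene_id column")
    return df


def write_gene_counts(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
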