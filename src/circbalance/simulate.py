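"""Self-contained synthetic study generator with planted, known effects.

Emits a small multi-chromosome genome, a strand-mixed gene annotation,
crosslink-style binding peaks, and WT/KO steady-state and nascent count
tables, together with truth tables recording every planted effect. The
planted structure mirrors the biology under study:

* a subset of genes produces circRNAs from internal exon blocks;
* "regulated" circRNA genes have longer flanking introns (FI) around the
  circularised block, a higher density of binding sites in those FIs, and
  stronger sites there;
* knockout of the binding protein multiplies circRNA count means by
  ``ko_circ_boost`` for regulated genes while mRNA means stay put — except
  for a small "cdk1-like" subset where the circRNA gain is coupled to an
  mRNA loss;
* site p-values come from a null/alternative mixture (Uniform vs Beta) so
  the high-confidence filter has known operating characteristics;
* an A/U-rich motif is written into the genome under a configurable
  fraction of sites.

Counts are negative-binomial (gamma-Poisson) with a shared dispersion.
Everything is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import (
    BindingSite,
    CircRNA,
    Exon,
    GeneModel,
    GenomicInterval,
    derive_introns,
)
from .io import (
    write_circ_table,
    write_fasta,
    write_gene_counts,
    write_gtf,
    write_sites_bed,
)

__all__ = ["SimConfig", "SimResult", "simulate_genome_annotation",
           "simulate_binding_sites", "simulate_counts", "simulate_study"]

_RNA2DNA = str.maketrans("Uu", "Tt")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    n_genes: int = 500
    n_chroms: int = 4
    exon_count_range: tuple[int, int] = (3, 8)
    exon_len_range: tuple[int, int] = (100, 300)
    intron_len_lognormal: tuple[float, float] = (6.0, 0.6)  # (mu, sigma), bp
    intergenic_len_range: tuple[int, int] = (500, 2000)
    frac_coding: float = 0.85
    frac_circ_genes: float = 0.6
    frac_regulated: float = 0.3  # of circ-producing genes
    frac_cdk1_like: float = 0.05  # of circ-producing genes; subset of regulated
    frac_second_circ: float = 0.1  # circ genes with a second circRNA
    site_rate_bg: float = 0.25  # sites per kb, genome-wide
    site_rate_fi_up: float | None = None  # default 4x background
    site_len_range: tuple[int, int] = (20, 50)
    intensity_nb: tuple[float, float] = (30.0, 0.5)  # (mean reads, dispersion)
    intensity_fi_up_mult: float = 2.0
    frac_null_sites: float = 0.3  # of background sites
    motif: str = "UAUUUA"
    motif_freq: float = 0.8
    fi_len_multiplier_up: float = 2.0
    ko_circ_boost: float = 3.0
    ko_mrna_effect: float = 1.0
    cdk1_mrna_effect: float = 0.6
    nb_dispersion: float = 0.02
    library_size: int = 2_000_000
    nascent_library_size: int = 200_000
    circ_to_mrna_lognormal: tuple[float, float] = (np.log(0.03), 0.5)

    def __post_init__(self) -> None:
        if not (0 <= self.frac_circ_genes <= 1 and 0 <= self.frac_regulated <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.site_rate_bg < 0:
            raise ValueError("site rates must be non-negative")
        if self.exon_count_range[0] < 1 or self.exon_len_range[0] < 10:
            raise ValueError("infeasible exon ranges")

    @property
    def rate_fi_up(self) -> float:
        return (
            self.site_rate_fi_up
            if self.site_rate_fi_up is not None
            else 4.0 * self.site_rate_bg
        )


@dataclass
class SimResult:
    genes: list[GeneModel]
    circs: list[CircRNA]
    sites: list[BindingSite]
    chrom_seqs: dict[str, str]
    circ_steady: pd.DataFrame
    mrna_steady: pd.DataFrame
    circ_nascent: pd.DataFrame
    gene_nascent: pd.DataFrame
    truth_genes: pd.DataFrame
    truth_circs: pd.DataFrame
    truth_fis: pd.DataFrame
    truth_sites: pd.DataFrame


def _nb(rng: np.random.Generator, mean, dispersion: float, size=None):
    """Gamma-Poisson draw with var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size=size)
    return rng.poisson(lam)


def simulate_genome_annotation(
    config: SimConfig, rng: np.random.Generator | None = None
):
    """Genes on both strands with planted circRNA blocks and lengthened FIs.

    Returns (genes, circs, chrom_seqs_mutable, truth_genes, truth_fis).
    Chromosome sequences are returned as bytearrays so the site simulator
    can plant motifs before the FASTA is written.
    """
    rng = rng or np.random.default_rng(config.seed)
    cursors = {f"chr{i + 1}": 1000 for i in range(config.n_chroms)}
    genes: list[GeneModel] = []
    circs: list[CircRNA] = []
    truth_gene_rows = []
    truth_fi_rows = []

    n_circ_target = int(round(config.frac_circ_genes * config.n_genes))
    circ_flags = np.zeros(config.n_genes, dtype=bool)
    circ_flags[:n_circ_target] = True
    rng.shuffle(circ_flags)

    for gi in range(config.n_genes):
        gid = f"G{gi + 1:04d}"
        chrom = f"chr{gi % config.n_chroms + 1}"
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() < config.frac_coding
        n_exons = int(
            rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1)
        )
        is_circ = bool(circ_flags[gi]) and n_exons >= 3
        regulated = is_circ and rng.random() < config.frac_regulated
        cdk1_like = (
            regulated and rng.random() < config.frac_cdk1_like / max(
                config.frac_regulated, 1e-9
            )
        )

        exon_lens = rng.integers(
            config.exon_len_range[0], config.exon_len_range[1] + 1, size=n_exons
        )
        mu, sigma = config.intron_len_lognormal
        intron_lens = np.maximum(
            50, np.round(rng.lognormal(mu, sigma, size=n_exons - 1)).astype(int)
        )

        # circ exon block in transcription order, away from the termini so
        # that both flanking introns exist
        blocks: list[tuple[int, int]] = []
        if is_circ:
            first = int(rng.integers(2, n_exons))  # 2 .. n_exons-1
            last = min(n_exons - 1, first + int(rng.integers(0, 2)))
            blocks.append((first, last))
            if rng.random() < config.frac_second_circ:
                f2 = int(rng.integers(2, n_exons))
                l2 = min(n_exons - 1, f2 + int(rng.integers(0, 2)))
                if (f2, l2) != (first, last):
                    blocks.append((f2, l2))
        # FI introns (transcription indices): intron k lies after exon k
        fi_tx_idx = set()
        for first, last in blocks:
            fi_tx_idx.add(first - 1)
            fi_tx_idx.add(last)
        if regulated:
            for k in fi_tx_idx:
                intron_lens[k - 1] = int(
                    round(intron_lens[k - 1] * config.fi_len_multiplier_up)
                )

        # lay out genomically: transcription order equals genomic order on
        # "+"; reversed on "-"
        tx_exon_lens = list(exon_lens)
        tx_intron_lens = list(intron_lens)
        if strand == "+":
            g_exon_lens, g_intron_lens = tx_exon_lens, tx_intron_lens
        else:
            g_exon_lens = tx_exon_lens[::-1]
            g_intron_lens = tx_intron_lens[::-1]

        pos = cursors[chrom]
        exon_spans = []
        for i, el in enumerate(g_exon_lens):
            exon_spans.append((pos, pos + int(el)))
            pos += int(el)
            if i < len(g_intron_lens):
                pos += int(g_intron_lens[i])
        gap = int(
            rng.integers(
                config.intergenic_len_range[0], config.intergenic_len_range[1] + 1
            )
        )
        cursors[chrom] = pos + gap

        exons = []
        for i, (s, e) in enumerate(exon_spans):
            ordinal = i + 1 if strand == "+" else n_exons - i
            exons.append(
                Exon(
                    interval=GenomicInterval(chrom, s, e, strand),
                    gene_id=gid,
                    transcript_id=f"{gid}.t1",
                    ordinal=ordinal,
                )
            )
        exons.sort(key=lambda e: e.ordinal)
        introns = derive_introns(exons)

        cds_start = cds_end = None
        if coding:
            left = exon_spans[0]
            right = exon_spans[-1]
            cds_start = left[0] + max(1, (left[1] - left[0]) // 3)
            cds_end = right[1] - max(1, (right[1] - right[0]) // 3)

        gene = GeneModel(
            gene_id=gid,
            name=gid,
            biotype="coding" if coding else "noncoding",
            chrom=chrom,
            strand=strand,
            exons=exons,
            introns=introns,
            cds_start=cds_start,
            cds_end=cds_end,
            transcript_id=f"{gid}.t1",
        )
        genes.append(gene)

        for bi, (first, last) in enumerate(blocks):
            block_exons = [e for e in exons if first <= e.ordinal <= last]
            bstart = min(e.interval.start for e in block_exons)
            bend = max(e.interval.end for e in block_exons)
            circs.append(
                CircRNA(
                    circ_id=f"circ_{gid}_{bi + 1}",
                    gene_id=gid,
                    acceptor_exon_ordinal=first,
                    donor_exon_ordinal=last,
                    bsj_interval=GenomicInterval(chrom, bstart, bend, strand),
                )
            )

        for intron in introns:
            k = intron.upstream_exon_ordinal
            is_fi = k in fi_tx_idx
            truth_fi_rows.append(
                {
                    "gene_id": gid,
                    "intron_upstream_ordinal": k,
                    "chrom": chrom,
                    "start": intron.interval.start,
                    "end": intron.interval.end,
                    "length": len(intron.interval),
                    "is_circ_fi": is_fi,
                    "planted_site_rate": config.rate_fi_up
                    if (is_fi and regulated)
                    else config.site_rate_bg,
                }
            )

        truth_gene_rows.append(
            {
                "gene_id": gid,
                "chrom": chrom,
                "strand": strand,
                "coding": coding,
                "circ_producing": is_circ,
                "regulated": regulated,
                "cdk1_like": cdk1_like,
                "length": gene.length,
            }
        )

    chrom_lens = {c: cursors[c] + 1000 for c in cursors}
    bases = np.frombuffer(b"ACGT", dtype="S1")
    chrom_seqs = {
        c: bytearray(rng.choice(bases, size=n).tobytes())
        for c, n in chrom_lens.items()
    }
    return (
        genes,
        circs,
        chrom_seqs,
        pd.DataFrame(truth_gene_rows),
        pd.DataFrame(truth_fi_rows),
    )


def simulate_binding_sites(
    config: SimConfig,
    genes: list[GeneModel],
    truth_genes: pd.DataFrame,
    truth_fis: pd.DataFrame,
    chrom_seqs: dict[str, bytearray],
    rng: np.random.Generator,
) -> tuple[list[BindingSite], pd.DataFrame]:
    """Poisson site placement with FI enrichment, NB intensities, mixed p-values.

    Background sites land uniformly along every chromosome at
    ``site_rate_bg`` per kb; flanking introns of regulated circ blocks
    receive additional sites so their total rate is ``rate_fi_up``. Planted
    FI sites are all "alternative" (small Beta p-values, boosted intensity);
    background sites are null with probability ``frac_null_sites``. The
    motif is written into the genome sequence under ``motif_freq`` of sites.
    """
    regulated = set(truth_genes.loc[truth_genes.regulated, "gene_id"])
    gene_by_span: list[GeneModel] = sorted(genes, key=lambda g: (g.chrom, g.start))
    mean_reads, disp = config.intensity_nb
    motif_dna = config.motif.translate(_RNA2DNA).upper()

    sites: list[BindingSite] = []
    truth_rows = []
    sid = 0

    def gene_at(chrom: str, pos: int) -> GeneModel | None:
        for g in gene_by_span:
            if g.chrom == chrom and g.start <= pos < g.end:
                return g
        return None

    def add_site(chrom, start, end, strand, origin, is_alt, intensity_mult):
        nonlocal sid
        sid += 1
        site_id = f"S{sid:05d}"
        reads = int(_nb(rng, mean_reads * intensity_mult, disp))
        p = (
            float(rng.beta(0.2, 5.0))
            if is_alt
            else float(rng.uniform(0.0, 1.0))
        )
        p = min(max(p, 1e-12), 1.0)
        has_motif = False
        if rng.random() < config.motif_freq and end - start >= len(motif_dna):
            off = int(rng.integers(0, end - start - len(motif_dna) + 1))
            planted = motif_dna
            if strand == "-":
                planted = motif_dna.translate(_COMPLEMENT)[::-1]
            chrom_seqs[chrom][start + off : start + off + len(planted)] = (
                planted.encode()
            )
            has_motif = True
        sites.append(
            BindingSite(
                site_id=site_id,
                interval=GenomicInterval(chrom, start, end, strand),
                reads=reads,
                p_value=p,
            )
        )
        truth_rows.append(
            {
                "site_id": site_id,
                "origin": origin,
                "is_alternative": is_alt,
                "has_motif": has_motif,
            }
        )

    lo, hi = config.site_len_range
    for chrom in sorted(chrom_seqs):
        clen = len(chrom_seqs[chrom])
        n_bg = rng.poisson(config.site_rate_bg * clen / 1000.0)
        for _ in range(n_bg):
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, max(1, clen - length)))
            g = gene_at(chrom, start)
            strand = g.strand if g is not None else ("+" if rng.random() < 0.5 else "-")
            is_alt = rng.random() >= config.frac_null_sites
            add_site(chrom, start, start + length, strand, "background", is_alt, 1.0)

    extra_rate = max(0.0, config.rate_fi_up - config.site_rate_bg)
    planted_fis = truth_fis[
        truth_fis.is_circ_fi & truth_fis.gene_id.isin(regulated)
    ]
    strand_of = {g.gene_id: g.strand for g in genes}
    for row in planted_fis.itertuples(index=False):
        n_extra = rng.poisson(extra_rate * row.length / 1000.0)
        for _ in range(n_extra):
            length = int(rng.integers(lo, hi + 1))
            length = min(length, row.length)
            start = int(rng.integers(row.start, max(row.start + 1, row.end - length)))
            add_site(
                row.chrom,
                start,
                start + length,
                strand_of[row.gene_id],
                "planted_fi",
                True,
                config.intensity_fi_up_mult,
            )
    return sites, pd.DataFrame(truth_rows)


def simulate_counts(
    config: SimConfig,
    genes: list[GeneModel],
    circs: list[CircRNA],
    truth_genes: pd.DataFrame,
    rng: np.random.Generator,
):
    """Steady and nascent WT/KO count tables with the planted KO effects.

    Returns (circ_steady, mrna_steady, circ_nascent, gene_nascent,
    truth_circs). Nascent gene totals are linear reads plus the gene's BSJ
    reads, so the circRNA fraction of a gene never exceeds 1.
    """
    tg = truth_genes.set_index("gene_id")
    rel = rng.lognormal(0.0, 1.0, size=len(genes))
    rel /= rel.sum()
    mrna_mean = {g.gene_id: rel[i] * config.library_size for i, g in enumerate(genes)}

    mu_c, sd_c = config.circ_to_mrna_lognormal
    circ_ratio = {
        c.circ_id: min(0.2, float(rng.lognormal(mu_c, sd_c))) for c in circs
    }

    disp = config.nb_dispersion
    nas_scale = config.nascent_library_size / config.library_size

    circ_rows, truth_circ_rows, nas_circ_rows = [], [], []
    nas_circ_by_gene: dict[str, dict[str, int]] = {}
    for c in circs:
        reg = bool(tg.loc[c.gene_id, "regulated"])
        boost = config.ko_circ_boost if reg else 1.0
        mean_wt = mrna_mean[c.gene_id] * circ_ratio[c.circ_id]
        wt = int(_nb(rng, mean_wt, disp))
        ko = int(_nb(rng, mean_wt * boost, disp))
        nwt = int(_nb(rng, mean_wt * nas_scale, disp))
        nko = int(_nb(rng, mean_wt * nas_scale * boost, disp))
        iv = c.bsj_interval
        base = {
            "circ_id": c.circ_id,
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "strand": iv.strand,
            "gene_id": c.gene_id,
        }
        circ_rows.append({**base, "count_WT": wt, "count_KO": ko})
        nas_circ_rows.append({**base, "count_WT": nwt, "count_KO": nko})
        acc = nas_circ_by_gene.setdefault(c.gene_id, {"WT": 0, "KO": 0})
        acc["WT"] += nwt
        acc["KO"] += nko
        truth_circ_rows.append(
            {
                "circ_id": c.circ_id,
                "gene_id": c.gene_id,
                "regulated": reg,
                "true_fc": boost,
            }
        )

    mrna_rows, nas_gene_rows = [], []
    for g in genes:
        cdk1 = bool(tg.loc[g.gene_id, "cdk1_like"])
        eff = config.cdk1_mrna_effect if cdk1 else config.ko_mrna_effect
        mean = mrna_mean[g.gene_id]
        mrna_rows.append(
            {
                "gene_id": g.gene_id,
                "count_WT": int(_nb(rng, mean, disp)),
                "count_KO": int(_nb(rng, mean * eff, disp)),
            }
        )
        lin_wt = int(_nb(rng, mean * nas_scale, disp))
        lin_ko = int(_nb(rng, mean * nas_scale * eff, disp))
        bsj = nas_circ_by_gene.get(g.gene_id, {"WT": 0, "KO": 0})
        nas_gene_rows.append(
            {
                "gene_id": g.gene_id,
                "count_WT": lin_wt + bsj["WT"],
                "count_KO": lin_ko + bsj["KO"],
            }
        )

    cols = ["circ_id", "chrom", "start", "end", "strand", "gene_id",
            "count_WT", "count_KO"]
    circ_steady = pd.DataFrame(circ_rows, columns=cols)
    circ_nascent = pd.DataFrame(nas_circ_rows, columns=cols)
    return (
        circ_steady,
        pd.DataFrame(mrna_rows, columns=["gene_id", "count_WT", "count_KO"]),
        circ_nascent,
        pd.DataFrame(nas_gene_rows, columns=["gene_id", "count_WT", "count_KO"]),
        pd.DataFrame(
            truth_circ_rows, columns=["circ_id", "gene_id", "regulated", "true_fc"]
        ),
    )


def simulate_study(config: SimConfig, outdir: str | Path | None = None) -> SimResult:
    """Run the full generator; optionally write every artefact to ``outdir``."""
    rng = np.random.default_rng(config.seed)
    genes, circs, chrom_seqs, truth_genes, truth_fis = simulate_genome_annotation(
        config, rng
    )
    sites, truth_sites = simulate_binding_sites(
        config, genes, truth_genes, truth_fis, chrom_seqs, rng
    )
    circ_steady, mrna_steady, circ_nascent, gene_nascent, truth_circs = (
        simulate_counts(config, genes, circs, truth_genes, rng)
    )
    seqs = {c: chrom_seqs[c].decode() for c in sorted(chrom_seqs)}
    result = SimResult(
        genes=genes,
        circs=circs,
        sites=sites,
        chrom_seqs=seqs,
        circ_steady=circ_steady,
        mrna_steady=mrna_steady,
        circ_nascent=circ_nascent,
        gene_nascent=gene_nascent,
        truth_genes=truth_genes,
        truth_circs=truth_circs,
        truth_fis=truth_fis,
        truth_sites=truth_sites,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(seqs, outdir / "genome.fa")
        write_gtf(genes, outdir / "annotation.gtf")
        write_sites_bed(sites, outdir / "sites.bed")
        write_circ_table(circ_steady, outdir / "circ_steady.tsv")
        write_gene_counts(mrna_steady, outdir / "mrna_steady.tsv")
        write_circ_table(circ_nascent, outdir / "circ_nascent.tsv")
        write_gene_counts(gene_nascent, outdir / "gene_nascent.tsv")
        truth_genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        truth_circs.to_csv(outdir / "truth_circs.tsv", sep="\t", index=False)
        truth_fis.to_csv(outdir / "truth_fis.tsv", sep="\t", index=False)
        truth_sites.to_csv(outdir / "truth_sites.tsv", sep="\t", index=False)
    return result
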