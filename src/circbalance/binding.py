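"""Binding-site filtering, feature annotation, and flanking-intron enrichment.

Crosslink-derived binding peaks come with a read count (intensity) and a
p-value from the upstream peak caller. High-confidence sites must satisfy
both filters strictly (p < max_p AND reads > min_reads). Filtered sites are
annotated to genomic features, their sequence composition summarised, and —
the central analysis — compared between the flanking introns (FI) of
backsplicing exon groups (circ-E) and the non-backsplicing exons (NE) of
the same circRNA-producing genes.

Feature assignment uses a fixed precedence (CDS > 3'UTR > 5'UTR >
noncoding_exon > intron > intergenic) when a site touches several features
of a gene; a site overlapping two genes is annotated once per gene. FI
profiling, by contrast, counts any site with >= 1 bp intersection with the
intron, because the question there is presence in the intron, not an
exclusive assignment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .genome import (
    BindingSite,
    CircRNA,
    GeneModel,
    GenomicInterval,
    Intron,
    overlap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PeakFilterConfig",
    "FeatureAnnotation",
    "ExonClassRecord",
    "FlankingIntronProfile",
    "FEATURE_PRECEDENCE",
    "filter_high_confidence",
    "annotate_feature",
    "annotate_sites",
    "feature_distribution",
    "nucleotide_composition",
    "kmer_top",
    "classify_exons",
    "flanking_introns_of",
    "profile_flanking_introns",
    "compare_flanking_groups",
    "exonic_binding_fraction",
    "gene_length_comparison",
    "genes_with_binding_fraction",
]

FEATURE_PRECEDENCE = ["CDS", "3'UTR", "5'UTR", "noncoding_exon", "intron"]


@dataclass(frozen=True)
class PeakFilterConfig:
    max_p: float = 0.05  # strict: keep p < max_p
    min_reads: int = 5  # strict: keep reads > min_reads

    def __post_init__(self) -> None:
        if not (0 < self.max_p <= 1):
            raise ValueError("max_p must be in (0, 1]")


@dataclass(frozen=True)
class FeatureAnnotation:
    site_id: str
    feature: str  # intron | CDS | 5'UTR | 3'UTR | noncoding_exon | intergenic
    gene_id: str | None


@dataclass(frozen=True)
class ExonClassRecord:
    """A group of exons of one gene classified as circ-E or NE.

    circ-E groups are the contiguous exon blocks of detected circRNAs; NE
    records are single exons of the same circRNA-producing genes that fall
    inside no detected circRNA.
    """

    gene_id: str
    exon_ordinals: tuple[int, ...]
    klass: str  # "circ-E" | "NE"
    source_circ_ids: tuple[str, ...] = ()


@dataclass(frozen=True)
class FlankingIntronProfile:
    gene_id: str
    klass: str  # circ-E | NE
    group: str | None  # up | non-up for circ-E; None for NE
    intron_upstream_ordinal: int
    length: int
    n_sites: int
    total_intensity: int

    @property
    def has_binding(self) -> bool:
        return self.n_sites > 0


def filter_high_confidence(
    sites: Iterable[BindingSite], config: PeakFilterConfig = PeakFilterConfig()
) -> list[BindingSite]:
    """Keep sites with p_value < max_p and reads > min_reads (both strict)."""
    out = []
    for s in sites:
        if s.p_value is None or np.isnan(s.p_value):
            raise ValueError(f"{s.site_id}: missing p-value")
        if s.p_value < config.max_p and s.reads > config.min_reads:
            out.append(s)
    return out


class _GeneIndex:
    """Per-chromosome interval tree over gene spans."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.trees: dict[str, IntervalTree] = {}
        for g in genes:
            self.trees.setdefault(g.chrom, IntervalTree()).addi(
                g.start, g.end, g
            )

    def overlapping(self, iv: GenomicInterval) -> list[GeneModel]:
        tree = self.trees.get(iv.chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(iv.start, iv.end)]
        hits.sort(key=lambda g: g.gene_id)
        return hits


def _feature_for_pair(site: BindingSite, gene: GeneModel) -> str:
    """Highest-precedence feature of ``gene`` the site touches by >= 1 bp."""
    iv = site.interval
    feats = gene.feature_intervals()
    for feature in FEATURE_PRECEDENCE:
        for s, e in feats[feature]:
            if iv.chrom == gene.chrom and min(iv.end, e) > max(iv.start, s):
                return feature
    # overlaps the gene span but no modelled feature (possible only at the
    # span margins of degenerate models); treat as intron of the gene
    return "intron"


def annotate_feature(
    site: BindingSite,
    genes: Sequence[GeneModel] | _GeneIndex,
) -> list[FeatureAnnotation]:
    """Annotate one site against gene models; one record per overlapped gene.

    A site overlapping no gene yields a single intergenic record with
    ``gene_id=None``.
    """
    index = genes if isinstance(genes, _GeneIndex) else _GeneIndex(genes)
    hits = index.overlapping(site.interval)
    if not hits:
        return [FeatureAnnotation(site.site_id, "intergenic", None)]
    return [
        FeatureAnnotation(site.site_id, _feature_for_pair(site, g), g.gene_id)
        for g in hits
    ]


def annotate_sites(
    sites: Iterable[BindingSite], genes: Sequence[GeneModel]
) -> list[FeatureAnnotation]:
    index = _GeneIndex(genes)
    out: list[FeatureAnnotation] = []
    for s in sites:
        out.extend(annotate_feature(s, index))
    return out


def feature_distribution(
    annotations: Sequence[FeatureAnnotation],
    genes: Mapping[str, GeneModel] | None = None,
) -> dict:
    """Feature proportions plus coding-gene site statistics.

    Proportions are over (site, gene) annotation records and sum to 1.
    ``pct_coding_genes`` is the percentage of distinct sites annotated to at
    least one protein-coding gene; ``prop_intronic_coding`` the intron share
    among records on coding genes (the paper-style "fraction of binding
    sites in intronic regions of protein-coding genes").
    """
    if not annotations:
        raise ValueError("no annotations given")
    features = FEATURE_PRECEDENCE + ["intergenic"]
    counts = {f: 0 for f in features}
    for a in annotations:
        counts[a.feature] += 1
    total = sum(counts.values())
    proportions = {f: counts[f] / total for f in features}

    out: dict = {"counts": counts, "proportions": proportions}
    if genes is not None:
        coding = {gid for gid, g in genes.items() if g.biotype == "coding"}
        all_sites = {a.site_id for a in annotations}
        coding_recs = [
            a for a in annotations if a.gene_id in coding
        ]
        sites_on_coding = {a.site_id for a in coding_recs}
        n_intronic_coding = sum(1 for a in coding_recs if a.feature == "intron")
        out["n_coding_genes"] = len({a.gene_id for a in coding_recs})
        out["pct_coding_genes"] = round(
            100.0 * len(sites_on_coding) / len(all_sites), 1
        )
        out["prop_intronic_coding"] = (
            n_intronic_coding / len(coding_recs) if coding_recs else float("nan")
        )
    return out


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def _site_sequence(site: BindingSite, genome) -> str:
    """Strand-corrected RNA-sense sequence of a site (T reported as U)."""
    iv = site.interval
    chrom_seq = genome[iv.chrom]
    if iv.end > len(chrom_seq):
        raise ValueError(
            f"{site.site_id}: interval end {iv.end} beyond chromosome "
            f"{iv.chrom} length {len(chrom_seq)}"
        )
    seq = str(chrom_seq[iv.start : iv.end]).upper()
    if iv.strand == "-":
        seq = seq.translate(_COMPLEMENT)[::-1]
    return seq.replace("T", "U")


def nucleotide_composition(
    sites: Sequence[BindingSite], genome
) -> dict[str, float]:
    """A/C/G/U frequencies over strand-corrected site sequences (sum to 1)."""
    tallies = {b: 0 for b in "ACGU"}
    for s in sites:
        for base in _site_sequence(s, genome):
            if base in tallies:
                tallies[base] += 1
    total = sum(tallies.values())
    if total == 0:
        raise ValueError("no sequence content in sites")
    return {b: tallies[b] / total for b in "ACGU"}


def kmer_top(sites: Sequence[BindingSite], genome, k: int):
    """Ranked k-mer counts over strand-corrected site sequences.

    Returns a DataFrame (kmer, count, frequency) sorted by descending count
    (ties lexicographic). k-mers containing ambiguous bases are skipped.
    """
    import pandas as pd

    if k < 3:
        raise ValueError("k must be >= 3")
    counts: dict[str, int] = {}
    for s in sites:
        seq = _site_sequence(s, genome)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if set(kmer) <= set("ACGU"):
                counts[kmer] = counts.get(kmer, 0) + 1
    df = pd.DataFrame(
        sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])),
        columns=["kmer", "count"],
    )
    total = int(df["count"].sum()) if len(df) else 0
    df["frequency"] = df["count"] / total if total else 0.0
    return df


def classify_exons(
    gene: GeneModel, circs: Sequence[CircRNA]
) -> list[ExonClassRecord]:
    """Partition a circRNA-producing gene's exons into circ-E and NE records.

    One circ-E record per circRNA (its contiguous exon block); one NE record
    per remaining exon. Genes with no (mappable) circRNA contribute nothing.
    circRNAs whose ordinals fall outside the gene's exon ordinals are
    skipped with a warning.
    """
    ordinals = {e.ordinal for e in gene.exons}
    records: list[ExonClassRecord] = []
    covered: set[int] = set()
    for c in circs:
        if c.gene_id != gene.gene_id:
            continue
        block = tuple(range(c.acceptor_exon_ordinal, c.donor_exon_ordinal + 1))
        if not set(block) <= ordinals:
            logger.warning(
                "%s: circRNA %s exon block %s outside gene exons; skipped",
                gene.gene_id,
                c.circ_id,
                block,
            )
            continue
        records.append(
            ExonClassRecord(
                gene_id=gene.gene_id,
                exon_ordinals=block,
                klass="circ-E",
                source_circ_ids=(c.circ_id,),
            )
        )
        covered.update(block)
    if not records:
        return []
    for o in sorted(ordinals - covered):
        records.append(
            ExonClassRecord(
                gene_id=gene.gene_id, exon_ordinals=(o,), klass="NE"
            )
        )
    return records


def flanking_introns_of(
    gene: GeneModel, exon_ordinals: Sequence[int]
) -> tuple[Intron | None, Intron | None]:
    """(upstream FI, downstream FI) of an exon group, transcription order.

    The upstream FI immediately precedes the group's first exon; the
    downstream FI immediately follows its last. Either is None at a
    transcript terminus.
    """
    first, last = min(exon_ordinals), max(exon_ordinals)
    return gene.intron_after(first - 1), gene.intron_after(last)


class _SiteIndex:
    def __init__(self, sites: Iterable[BindingSite]):
        self.trees: dict[str, IntervalTree] = {}
        for s in sites:
            iv = s.interval
            self.trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, s
            )

    def overlapping(self, iv: GenomicInterval) -> list[BindingSite]:
        tree = self.trees.get(iv.chrom)
        if tree is None:
            return []
        return [h.data for h in tree.overlap(iv.start, iv.end)]


def profile_flanking_introns(
    records: Sequence[ExonClassRecord],
    genes: Mapping[str, GeneModel],
    sites: Sequence[BindingSite],
    circ_groups: Mapping[str, str] | None = None,
) -> list[FlankingIntronProfile]:
    """Length, site count, and binding intensity of each flanking intron.

    ``circ_groups`` maps circ_id -> "up" / "non-up" (regulation group from
    the steady or nascent fold-change classification); circ-E records
    inherit the group of their source circRNA, NE records carry None. Both
    FIs of a group are profiled as separate records; duplicate (gene,
    intron, class, group) combinations — e.g. two circRNAs sharing an FI —
    are emitted once.
    """
    index = _SiteIndex(sites)
    seen: set[tuple] = set()
    out: list[FlankingIntronProfile] = []
    for rec in records:
        gene = genes[rec.gene_id]
        group: str | None = None
        if rec.klass == "circ-E" and circ_groups is not None:
            labels = {circ_groups.get(c) for c in rec.source_circ_ids}
            group = "up" if "up" in labels else "non-up"
        for intron in flanking_introns_of(gene, rec.exon_ordinals):
            if intron is None:
                continue
            key = (rec.gene_id, intron.upstream_exon_ordinal, rec.klass, group)
            if key in seen:
                continue
            seen.add(key)
            hits = [
                s
                for s in index.overlapping(intron.interval)
                if overlap(s.interval, intron.interval) >= 1
            ]
            out.append(
                FlankingIntronProfile(
                    gene_id=rec.gene_id,
                    klass=rec.klass,
                    group=group,
                    intron_upstream_ordinal=intron.upstream_exon_ordinal,
                    length=len(intron.interval),
                    n_sites=len(hits),
                    total_intensity=sum(s.reads for s in hits),
                )
            )
    return out


def _chi2_2x2(a_pos: int, a_neg: int, b_pos: int, b_neg: int) -> float:
    table = np.array([[a_pos, a_neg], [b_pos, b_neg]])
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        margin = "column" if (table.sum(axis=0) == 0).any() else "row"
        raise ValueError(f"degenerate contingency table: zero {margin} margin")
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def _binned_counts(ns: Sequence[int], edges=(1, 2, 3)) -> np.ndarray:
    """Counts per site-number bin (1, 2, >=3) for binding-positive FIs."""
    arr = np.asarray(ns)
    return np.array(
        [
            int(np.sum(arr == 1)),
            int(np.sum(arr == 2)),
            int(np.sum(arr >= 3)),
        ]
    )


def compare_flanking_groups(
    profiles: Mapping[str, Sequence[FlankingIntronProfile]],
) -> dict:
    """Pairwise comparisons of FI groups.

    For each pair of groups: chi-square on the has-binding proportion (all
    FIs); and — on binding-positive FIs only, matching how the per-FI
    quantities are displayed — chi-square on binned site numbers (1 / 2 /
    >=3) and two-tailed t-tests on intron length and binding intensity.
    """
    names = sorted(profiles)
    if len(names) < 2:
        raise ValueError("need at least two groups")
    for name in names:
        if not profiles[name]:
            raise ValueError(f"group {name!r} is empty")

    summaries = {}
    for name in names:
        ps = profiles[name]
        bound = [p for p in ps if p.has_binding]
        summaries[name] = {
            "n_fi": len(ps),
            "n_with_binding": len(bound),
            "prop_with_binding": len(bound) / len(ps),
            "mean_length": float(np.mean([p.length for p in bound]))
            if bound
            else float("nan"),
            "mean_n_sites": float(np.mean([p.n_sites for p in bound]))
            if bound
            else float("nan"),
            "mean_intensity": float(np.mean([p.total_intensity for p in bound]))
            if bound
            else float("nan"),
        }

    comparisons = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            pa, pb = profiles[a], profiles[b]
            ba = [p for p in pa if p.has_binding]
            bb = [p for p in pb if p.has_binding]
            rep: dict = {}
            rep["p_has_binding_chi2"] = _chi2_2x2(
                len(ba), len(pa) - len(ba), len(bb), len(pb) - len(bb)
            )
            if ba and bb:
                table = np.vstack(
                    [
                        _binned_counts([p.n_sites for p in ba]),
                        _binned_counts([p.n_sites for p in bb]),
                    ]
                )
                keep = table.sum(axis=0) > 0
                table = table[:, keep]
                if table.shape[1] >= 2 and (table.sum(axis=1) > 0).all():
                    _, p, _, _ = stats.chi2_contingency(table, correction=False)
                    rep["p_n_sites_chi2"] = float(p)
                else:
                    rep["p_n_sites_chi2"] = float("nan")
                la = [p.length for p in ba]
                lb = [p.length for p in bb]
                ia = [p.total_intensity for p in ba]
                ib = [p.total_intensity for p in bb]
                rep["p_length_t"] = float(stats.ttest_ind(la, lb)[1])
                rep["p_intensity_t"] = float(stats.ttest_ind(ia, ib)[1])
                rep["mean_length"] = (float(np.mean(la)), float(np.mean(lb)))
                rep["mean_intensity"] = (float(np.mean(ia)), float(np.mean(ib)))
            comparisons[f"{a}_vs_{b}"] = rep
    return {"groups": summaries, "comparisons": comparisons}


def exonic_binding_fraction(
    circs: Sequence[CircRNA],
    genes: Mapping[str, GeneModel],
    sites: Sequence[BindingSite],
) -> dict:
    """Fraction of circRNAs with a binding site in a composing exon."""
    index = _SiteIndex(sites)
    n_with = 0
    for c in circs:
        gene = genes[c.gene_id]
        hit = False
        for o in c.exon_ordinals:
            try:
                exon = gene.exon_by_ordinal(o)
            except KeyError:
                continue
            if any(
                overlap(s.interval, exon.interval) >= 1
                for s in index.overlapping(exon.interval)
            ):
                hit = True
                break
        n_with += hit
    n_total = len(circs)
    frac = n_with / n_total if n_total else float("nan")
    return {
        "n_with": n_with,
        "n_total": n_total,
        "fraction": frac,
        "pct": round(100.0 * frac, 1) if n_total else float("nan"),
    }


def gene_length_comparison(
    lengths_with: Sequence[float], lengths_without: Sequence[float]
) -> dict:
    """Wilcoxon rank-sum comparison of gene lengths, bound vs unbound."""
    if len(lengths_with) < 3 or len(lengths_without) < 3:
        raise ValueError("each group needs at least 3 genes")
    stat, p = stats.mannwhitneyu(
        lengths_with, lengths_without, alternative="two-sided"
    )
    return {
        "n_with": len(lengths_with),
        "n_without": len(lengths_without),
        "median_with": float(np.median(lengths_with)),
        "median_without": float(np.median(lengths_without)),
        "statistic": float(stat),
        "p_value": float(p),
        "test": "two-sided Wilcoxon rank-sum",
    }


def genes_with_binding_fraction(
    genes: Sequence[GeneModel], sites: Sequence[BindingSite]
) -> dict:
    """How many genes carry at least one binding site within their span."""
    index = _SiteIndex(sites)
    n_with = sum(
        1
        for g in genes
        if any(
            overlap(s.interval, g.span) >= 1 for s in index.overlapping(g.span)
        )
    )
    n_total = len(genes)
    frac = n_with / n_total if n_total else float("nan")
    return {
        "n_with": n_with,
        "n_total": n_total,
        "fraction": frac,
        "pct": round(100.0 * frac, 1) if n_total else float("nan"),
    }
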