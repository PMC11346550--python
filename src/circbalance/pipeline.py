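"""End-to-end orchestration: simulate -> quantify -> nascent -> binding -> ratio.

Each stage is a plain function over in-memory objects so the steps compose
in scripts and tests; :func:`run_pipeline` wires them together from a
:class:`RunConfig`, writes every stage's table, and returns the report
dictionary that also lands in ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import binding as B
from .genome import CircRNA, GeneModel
from .io import (
    circs_from_table,
    read_circ_table,
    read_gene_counts,
    read_gtf,
    read_sites_bed,
)
from .nascent import (
    NascentDEConfig,
    NascentGeneRecord,
    classify_nascent_up,
    compare_fractions,
    nascent_circ_fraction,
)
from .quantify import (
    DEConfig,
    classify_de,
    cumulative_fraction,
    detected_set,
    overlap_sets,
    summarize_de,
)
from .ratio import compute_ratio_records, summarize_ratio_labels, zscore_rows
from .simulate import SimConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "library_sizes", "quantify_stage",
           "nascent_stage", "binding_stage", "ratio_stage"]


@dataclass
class RunConfig:
    outdir: Path = Path("circbalance_run")
    seed: int = 0
    simulate: bool = True
    annotation: Path | None = None
    genome: Path | None = None
    sites: Path | None = None
    circ_steady: Path | None = None
    mrna_steady: Path | None = None
    circ_nascent: Path | None = None
    gene_nascent: Path | None = None
    sim: SimConfig = field(default_factory=SimConfig)
    de: DEConfig = field(default_factory=DEConfig)
    nascent_de: NascentDEConfig = field(default_factory=NascentDEConfig)
    peaks: B.PeakFilterConfig = field(default_factory=B.PeakFilterConfig)
    ratio_pseudocount: float = 0.5
    kmer_k: int = 6
    nascent_min_bsj: int = 1
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {}
        for key, val in raw.items():
            if key == "sim":
                kwargs["sim"] = SimConfig(**{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in val.items()
                })
            elif key == "de":
                kwargs["de"] = DEConfig(**val)
            elif key == "nascent_de":
                kwargs["nascent_de"] = NascentDEConfig(**val)
            elif key == "peaks":
                kwargs["peaks"] = B.PeakFilterConfig(**val)
            elif key in ("outdir",):
                kwargs[key] = Path(val)
            else:
                kwargs[key] = val
        return cls(**kwargs)

    def validate_paths(self) -> None:
        if self.simulate:
            return
        required = {
            "annotation": self.annotation,
            "sites": self.sites,
            "circ_steady": self.circ_steady,
            "mrna_steady": self.mrna_steady,
        }
        for name, p in required.items():
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"required input {name!r} missing: {p}")


def _samples(df: pd.DataFrame, prefix: str) -> list[str]:
    return sorted(
        c[len("count_"):]
        for c in df.columns
        if c.startswith("count_") and c[len("count_"):].startswith(prefix)
    )


def library_sizes(mrna_df: pd.DataFrame, circ_df: pd.DataFrame) -> dict[str, int]:
    """Total mapped reads per sample: gene-level plus BSJ counts."""
    sizes: dict[str, int] = {}
    for df in (mrna_df, circ_df):
        for c in df.columns:
            if c.startswith("count_"):
                sizes[c[len("count_"):]] = sizes.get(c[len("count_"):], 0) + int(
                    df[c].sum()
                )
    return sizes


def _mean_rpm(
    counts: Mapping[str, int], lib: Mapping[str, int], samples: Sequence[str]
) -> float:
    return float(np.mean([counts[s] / lib[s] * 1e6 for s in samples]))


def quantify_stage(
    circs: Sequence[CircRNA],
    lib: Mapping[str, int],
    wt_samples: Sequence[str],
    ko_samples: Sequence[str],
    config: DEConfig,
) -> dict:
    """Detection, WT/KO overlap, and fold-change classification."""
    wt_det = set().union(
        *[detected_set(circs, s, config.min_bsj_reads) for s in wt_samples]
    )
    ko_det = set().union(
        *[detected_set(circs, s, config.min_bsj_reads) for s in ko_samples]
    )
    shared, wt_only, ko_only = overlap_sets(wt_det, ko_det)
    shared_circs = [c for c in circs if c.circ_id in shared]
    results = classify_de(shared_circs, lib, wt_samples, ko_samples, config)
    wt_rpm = [r.norm_wt for r in results]
    ko_rpm = [r.norm_ko for r in results]
    ks = (
        stats.ks_2samp(wt_rpm, ko_rpm)
        if len(results) >= 3
        else None
    )
    return {
        "detected_wt": wt_det,
        "detected_ko": ko_det,
        "shared": shared,
        "wt_only": wt_only,
        "ko_only": ko_only,
        "shared_circs": shared_circs,
        "results": results,
        "summary": summarize_de(results),
        "cumfrac_wt": cumulative_fraction(wt_rpm) if wt_rpm else [],
        "cumfrac_ko": cumulative_fraction(ko_rpm) if ko_rpm else [],
        "ks_p_value": float(ks.pvalue) if ks else float("nan"),
    }


def nascent_stage(
    gene_nascent: pd.DataFrame,
    circ_nascent: pd.DataFrame,
    genes: Mapping[str, GeneModel],
    wt_samples: Sequence[str],
    ko_samples: Sequence[str],
    config: NascentDEConfig,
    min_bsj: int = 1,
    pseudocount: float = 0.5,
) -> dict:
    """Per-gene circRNA fractions of nascent reads and nascent up-labels."""
    count_cols = [c for c in gene_nascent.columns if c.startswith("count_")]
    samples = [c[len("count_"):] for c in count_cols]
    recs: dict[str, NascentGeneRecord] = {}
    for row in gene_nascent.itertuples(index=False):
        recs[row.gene_id] = NascentGeneRecord(
            gene_id=row.gene_id,
            total_nascent_reads={
                s: int(getattr(row, f"count_{s}")) for s in samples
            },
        )
    for row in circ_nascent.itertuples(index=False):
        rec = recs.get(row.gene_id)
        if rec is None:
            continue
        for s in samples:
            rec.circ_nascent_reads[(row.circ_id, s)] = int(
                getattr(row, f"count_{s}")
            )

    def fractions(cond_samples: Sequence[str]) -> dict[str, float]:
        out = {}
        for gid, rec in recs.items():
            # require both linear splicing and backsplicing in the condition
            tot = sum(rec.total_nascent_reads.get(s, 0) for s in cond_samples)
            circ = sum(rec.circ_reads(s) for s in cond_samples)
            lin = tot - circ
            if tot > 0 and circ >= 1 and lin >= 1:
                fr = [
                    nascent_circ_fraction(rec, s)
                    for s in cond_samples
                    if rec.total_nascent_reads.get(s, 0) > 0
                ]
                out[gid] = float(np.mean(fr))
        return out

    wt_fracs = fractions(wt_samples)
    ko_fracs = fractions(ko_samples)
    try:
        comparison = compare_fractions(wt_fracs, ko_fracs)
    except ValueError as exc:
        logger.warning("nascent fraction comparison skipped: %s", exc)
        comparison = {"error": str(exc)}

    # nascent circRNA fold changes on the shared detected set
    nas_circs = []
    if len(circ_nascent):
        dummy_genes = genes
        nas_circs = circs_from_table(circ_nascent, dict(dummy_genes))
    lib = {
        s: int(gene_nascent[f"count_{s}"].sum()) for s in samples
    }
    wt_det = set().union(
        *[detected_set(nas_circs, s, min_bsj) for s in wt_samples]
    ) if nas_circs else set()
    ko_det = set().union(
        *[detected_set(nas_circs, s, min_bsj) for s in ko_samples]
    ) if nas_circs else set()
    shared = wt_det & ko_det
    shared_circs = [c for c in nas_circs if c.circ_id in shared]
    de_cfg = DEConfig(
        min_bsj_reads=max(min_bsj, 1),
        fc_up=config.fc_up_nascent,
        fc_down=1.0 / config.fc_up_nascent,
        pseudocount=pseudocount,
    )
    results = classify_de(shared_circs, lib, wt_samples, ko_samples, de_cfg)
    fcs = {r.circ_id: r.fold_change for r in results}
    labels = classify_nascent_up(fcs, config)
    return {
        "records": recs,
        "wt_fractions": wt_fracs,
        "ko_fractions": ko_fracs,
        "comparison": comparison,
        "shared_circs": shared_circs,
        "fold_changes": fcs,
        "labels": labels,
    }


def binding_stage(
    sites,
    genes: Sequence[GeneModel],
    steady_circs: Sequence[CircRNA],
    steady_groups: Mapping[str, str],
    nascent_circs: Sequence[CircRNA],
    nascent_groups: Mapping[str, str],
    genome,
    peaks: B.PeakFilterConfig,
    kmer_k: int = 6,
    nascent_wt_genes: set[str] | None = None,
) -> dict:
    """Filtering, feature annotation, composition, and FI enrichment."""
    hc = B.filter_high_confidence(sites, peaks)
    gene_map = {g.gene_id: g for g in genes}
    annotations = B.annotate_sites(hc, genes)
    dist = B.feature_distribution(annotations, gene_map)

    comp = B.nucleotide_composition(hc, genome) if genome is not None else None
    kmers = B.kmer_top(hc, genome, kmer_k) if genome is not None else None

    def fi_analysis(circs, groups):
        by_gene: dict[str, list[CircRNA]] = {}
        for c in circs:
            by_gene.setdefault(c.gene_id, []).append(c)
        records = []
        for gid, cs in by_gene.items():
            records.extend(B.classify_exons(gene_map[gid], cs))
        profiles = B.profile_flanking_introns(records, gene_map, hc, groups)
        grouped: dict[str, list] = {}
        for p in profiles:
            key = "NE" if p.klass == "NE" else f"circ-E:{p.group}"
            grouped.setdefault(key, []).append(p)
        comparison = None
        if len(grouped) >= 2 and all(grouped.values()):
            try:
                comparison = B.compare_flanking_groups(grouped)
            except ValueError as exc:
                logger.warning("FI comparison failed: %s", exc)
        return {"records": records, "profiles": profiles,
                "grouped": grouped, "comparison": comparison}

    steady_fi = fi_analysis(steady_circs, steady_groups)
    nascent_fi = fi_analysis(nascent_circs, nascent_groups)
    exonic = B.exonic_binding_fraction(nascent_circs, gene_map, hc)

    coding = [g for g in genes if g.biotype == "coding"]
    bound_ids = {
        a.gene_id for a in annotations if a.gene_id is not None
    }
    with_b = [g.length for g in coding if g.gene_id in bound_ids]
    without_b = [g.length for g in coding if g.gene_id not in bound_ids]
    try:
        length_cmp = B.gene_length_comparison(with_b, without_b)
    except ValueError as exc:
        length_cmp = {"error": str(exc)}

    nascent_gene_binding = None
    if nascent_wt_genes:
        subset = [g for g in genes if g.gene_id in nascent_wt_genes]
        nascent_gene_binding = B.genes_with_binding_fraction(subset, hc)

    return {
        "n_sites_raw": len(list(sites)),
        "n_sites_hc": len(hc),
        "hc_sites": hc,
        "feature_distribution": dist,
        "composition": comp,
        "kmers": kmers,
        "steady_fi": steady_fi,
        "nascent_fi": nascent_fi,
        "exonic_binding": exonic,
        "gene_length": length_cmp,
        "nascent_gene_binding": nascent_gene_binding,
    }


def ratio_stage(
    circ_steady: pd.DataFrame,
    mrna_steady: pd.DataFrame,
    gene_set: set[str],
    lib: Mapping[str, int],
    wt_samples: Sequence[str],
    ko_samples: Sequence[str],
    pseudocount: float = 0.5,
    nascent_gene: pd.DataFrame | None = None,
) -> dict:
    """circRNA:mRNA ratio fold changes for the focus gene set.

    circRNA RPM is summed over each gene's circRNAs and averaged over
    replicates before the ratio.
    """
    circ_rpm: dict[str, dict[str, float]] = {}
    ccols = [c for c in circ_steady.columns if c.startswith("count_")]
    sums = circ_steady.groupby("gene_id")[ccols].sum()
    for gid, row in sums.iterrows():
        if gid not in gene_set:
            continue
        counts = {c[len("count_"):]: int(row[c]) for c in ccols}
        circ_rpm[gid] = {
            "WT": _mean_rpm(counts, lib, wt_samples),
            "KO": _mean_rpm(counts, lib, ko_samples),
        }
    mrna_rpm: dict[str, dict[str, float]] = {}
    mcols = [c for c in mrna_steady.columns if c.startswith("count_")]
    for row in mrna_steady.itertuples(index=False):
        if row.gene_id not in gene_set:
            continue
        counts = {c[len("count_"):]: int(getattr(row, c)) for c in mcols}
        mrna_rpm[row.gene_id] = {
            "WT": _mean_rpm(counts, lib, wt_samples),
            "KO": _mean_rpm(counts, lib, ko_samples),
        }
    records = compute_ratio_records(circ_rpm, mrna_rpm, pseudocount)
    out = {"records": records, "label_counts": summarize_ratio_labels(records)}

    # Z-scored nascent levels of the increased-ratio genes (heatmap input)
    if nascent_gene is not None and records:
        inc = [r.gene_id for r in records if r.label == "increased"]
        sub = nascent_gene[nascent_gene.gene_id.isin(inc)].set_index("gene_id")
        cols = [c for c in sub.columns if c.startswith("count_")]
        sub = sub[cols].astype(float)
        sub = sub[sub.std(axis=1, ddof=0) > 0]
        if len(sub):
            out["nascent_zscores"] = zscore_rows(sub)
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage, write tables and summary.json, return the report."""
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        simdir = outdir / "sim"
        sim = simulate_study(
            dataclasses.replace(config.sim, seed=config.seed), simdir
        )
        genes = sim.genes
        circ_steady, mrna_steady = sim.circ_steady, sim.mrna_steady
        circ_nascent, gene_nascent = sim.circ_nascent, sim.gene_nascent
        sites = sim.sites
        genome = sim.chrom_seqs
    else:
        genes = read_gtf(config.annotation)
        circ_steady = read_circ_table(config.circ_steady)
        mrna_steady = read_gene_counts(config.mrna_steady)
        circ_nascent = (
            read_circ_table(config.circ_nascent)
            if config.circ_nascent
            else circ_steady.iloc[0:0]
        )
        gene_nascent = (
            read_gene_counts(config.gene_nascent)
            if config.gene_nascent
            else mrna_steady.iloc[0:0]
        )
        sites = read_sites_bed(config.sites)
        genome = None
        if config.genome:
            import pyfaidx

            genome = pyfaidx.Fasta(str(config.genome))

    gene_map = {g.gene_id: g for g in genes}
    wt_s, ko_s = _samples(circ_steady, "WT"), _samples(circ_steady, "KO")
    lib = library_sizes(mrna_steady, circ_steady)
    circs = circs_from_table(circ_steady, gene_map)

    quant = quantify_stage(circs, lib, wt_s, ko_s, config.de)
    steady_groups = {
        r.circ_id: ("up" if r.label == "up" else "non-up")
        for r in quant["results"]
    }

    nwt_s = _samples(gene_nascent, "WT") or wt_s
    nko_s = _samples(gene_nascent, "KO") or ko_s
    nas = nascent_stage(
        gene_nascent,
        circ_nascent,
        gene_map,
        nwt_s,
        nko_s,
        config.nascent_de,
        config.nascent_min_bsj,
        config.de.pseudocount,
    )

    nascent_wt_genes = {
        row.gene_id
        for row in gene_nascent.itertuples(index=False)
        if any(getattr(row, f"count_{s}") > 0 for s in nwt_s)
    }
    bind = binding_stage(
        sites,
        genes,
        quant["shared_circs"],
        steady_groups,
        nas["shared_circs"],
        nas["labels"],
        genome,
        config.peaks,
        config.kmer_k,
        nascent_wt_genes,
    )

    # focus set: nascent-expressed genes with binding that generate circRNAs
    bound_genes = {
        a.gene_id
        for a in B.annotate_sites(bind["hc_sites"], genes)
        if a.gene_id is not None
    }
    circ_genes = {c.gene_id for c in quant["shared_circs"]}
    focus = nascent_wt_genes & bound_genes & circ_genes
    rat = ratio_stage(
        circ_steady,
        mrna_steady,
        focus,
        lib,
        wt_s,
        ko_s,
        config.ratio_pseudocount,
        gene_nascent,
    )

    # global mRNA shift check (KS on the RPM distributions)
    mrna_wt = np.mean(
        [mrna_steady[f"count_{s}"] / lib[s] * 1e6 for s in wt_s], axis=0
    )
    mrna_ko = np.mean(
        [mrna_steady[f"count_{s}"] / lib[s] * 1e6 for s in ko_s], axis=0
    )
    mrna_ks = stats.ks_2samp(mrna_wt, mrna_ko)

    report = _write_outputs(
        outdir, config, quant, nas, bind, rat, float(mrna_ks.pvalue), focus
    )
    return report


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return v if np.isfinite(v) else None
    return x


def _write_outputs(outdir, config, quant, nas, bind, rat, mrna_ks_p, focus):
    de_df = pd.DataFrame([dataclasses.asdict(r) for r in quant["results"]])
    de_df.to_csv(outdir / "de_circ.tsv", sep="\t", index=False)

    frac_rows = [
        {"gene_id": g, "condition": "WT", "fraction": f}
        for g, f in nas["wt_fractions"].items()
    ] + [
        {"gene_id": g, "condition": "KO", "fraction": f}
        for g, f in nas["ko_fractions"].items()
    ]
    pd.DataFrame(frac_rows).to_csv(
        outdir / "nascent_fractions.tsv", sep="\t", index=False
    )

    prof_rows = [
        dataclasses.asdict(p) | {"has_binding": p.has_binding}
        for p in bind["steady_fi"]["profiles"]
    ]
    pd.DataFrame(prof_rows).to_csv(
        outdir / "fi_profiles_steady.tsv", sep="\t", index=False
    )
    if bind["composition"] is not None:
        pd.DataFrame([bind["composition"]]).to_csv(
            outdir / "nucleotide_composition.tsv", sep="\t", index=False
        )
    if bind["kmers"] is not None:
        bind["kmers"].head(100).to_csv(
            outdir / "kmer_top.tsv", sep="\t", index=False
        )
    ratio_df = pd.DataFrame([dataclasses.asdict(r) for r in rat["records"]])
    ratio_df.to_csv(outdir / "ratio_records.tsv", sep="\t", index=False)

    comparison = nas["comparison"]
    report = {
        "quantify": {
            "n_detected_wt": len(quant["detected_wt"]),
            "n_detected_ko": len(quant["detected_ko"]),
            "n_shared": len(quant["shared"]),
            "n_wt_only": len(quant["wt_only"]),
            "n_ko_only": len(quant["ko_only"]),
            "summary": quant["summary"],
            "ks_p_value": quant["ks_p_value"],
        },
        "nascent": {
            "n_wt_fraction_genes": len(nas["wt_fractions"]),
            "n_ko_fraction_genes": len(nas["ko_fractions"]),
            "comparison": {
                k: v for k, v in comparison.items() if k != "genes"
            },
            "n_shared_nascent_circs": len(nas["shared_circs"]),
            "n_nascent_up": sum(
                1 for v in nas["labels"].values() if v == "up"
            ),
        },
        "binding": {
            "n_sites_raw": bind["n_sites_raw"],
            "n_sites_high_confidence": bind["n_sites_hc"],
            "feature_distribution": {
                "proportions": bind["feature_distribution"]["proportions"],
                "pct_coding_genes": bind["feature_distribution"].get(
                    "pct_coding_genes"
                ),
                "n_coding_genes": bind["feature_distribution"].get(
                    "n_coding_genes"
                ),
                "prop_intronic_coding": bind["feature_distribution"].get(
                    "prop_intronic_coding"
                ),
            },
            "composition": bind["composition"],
            "steady_fi_comparison": bind["steady_fi"]["comparison"],
            "nascent_fi_comparison": bind["nascent_fi"]["comparison"],
            "exonic_binding": bind["exonic_binding"],
            "gene_length": bind["gene_length"],
            "nascent_gene_binding": bind["nascent_gene_binding"],
        },
        "ratio": {
            "n_focus_genes": len(focus),
            "label_counts": rat["label_counts"],
        },
        "mrna_ks_p_value": mrna_ks_p,
        "seed": config.seed,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    report["_objects"] = {"quant": quant, "nascent": nas, "binding": bind,
                          "ratio": rat, "focus": focus}
    return report
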