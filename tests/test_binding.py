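"""Peak filtering, feature annotation, composition, and FI enrichment."""

import numpy as np
import pytest

from circbalance import binding as B
from circbalance.genome import GenomicInterval, overlap
from circbalance.simulate import SimConfig, simulate_study

from _factories import make_circ, make_gene, make_site


# ---------------------------------------------------------------- filtering
def test_filter_high_confidence_is_strict_on_both_boundaries():
    sites = [
        make_site("boundary_p", 0, 10, p=0.05, reads=10),
        make_site("boundary_reads", 0, 10, p=0.01, reads=5),
        make_site("kept", 0, 10, p=0.01, reads=6),
        make_site("null", 0, 10, p=0.9, reads=100),
    ]
    kept = {s.site_id for s in B.filter_high_confidence(sites)}
    assert kept == {"kept"}


def test_filter_rejects_missing_p_value():
    s = make_site("s", 0, 10, reads=10, p=0.5)
    object.__setattr__(s, "p_value", float("nan"))
    with pytest.raises(ValueError):
        B.filter_high_confidence([s])


# ----------------------------------------------------------- feature labels
def _oracle_feature(site, genes):
    """Independent per-base feature derivation under the precedence rule."""
    recs = []
    iv = site.interval
    for g in genes:
        if g.chrom != iv.chrom or iv.end <= g.start or iv.start >= g.end:
            continue
        feats = set()
        for base in range(max(iv.start, g.start), min(iv.end, g.end)):
            exon = next(
                (
                    e
                    for e in g.exons
                    if e.interval.start <= base < e.interval.end
                ),
                None,
            )
            if exon is None:
                feats.add("intron")
            elif g.biotype != "coding" or g.cds_start is None:
                feats.add("noncoding_exon")
            elif g.cds_start <= base < g.cds_end:
                feats.add("CDS")
            elif base < g.cds_start:
                feats.add("5'UTR" if g.strand == "+" else "3'UTR")
            else:
                feats.add("3'UTR" if g.strand == "+" else "5'UTR")
        chosen = next(f for f in B.FEATURE_PRECEDENCE if f in feats)
        recs.append((g.gene_id, chosen))
    return recs or [(None, "intergenic")]


def test_annotate_feature_examples():
    gene = make_gene("g", [(100, 200), (400, 500)], cds=(150, 450))
    (a,) = B.annotate_feature(make_site("in_intron", 250, 270), [gene])
    assert a.feature == "intron" and a.gene_id == "g"
    (a,) = B.annotate_feature(make_site("outside", 900, 950), [gene])
    assert a.feature == "intergenic" and a.gene_id is None
    # straddles CDS/intron boundary: CDS wins by precedence
    (a,) = B.annotate_feature(make_site("straddle", 190, 220), [gene])
    assert a.feature == "CDS"


def test_annotate_feature_matches_per_base_oracle(default_sim):
    rng = np.random.default_rng(42)
    genes = default_sim.genes
    chroms = sorted(default_sim.chrom_seqs)
    sites = []
    for i in range(500):
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = len(default_sim.chrom_seqs[chrom])
        start = int(rng.integers(0, L - 60))
        sites.append(make_site(f"r{i}", start, start + int(rng.integers(1, 60)), chrom=chrom))
    anns = B.annotate_sites(sites, genes)
    got = {}
    for a in anns:
        got.setdefault(a.site_id, set()).add((a.gene_id, a.feature))
    for s in sites:
        assert got[s.site_id] == set(_oracle_feature(s, genes)), s.site_id


def test_feature_distribution_properties():
    anns = [B.FeatureAnnotation(f"s{i}", "intron", "g") for i in range(5)]
    dist = B.feature_distribution(anns)
    assert dist["proportions"]["intron"] == 1.0
    mixed = anns + [B.FeatureAnnotation("x", "CDS", "g"), B.FeatureAnnotation("y", "intergenic", None)]
    d1 = B.feature_distribution(mixed)
    d2 = B.feature_distribution(list(reversed(mixed)))  # order invariance
    assert d1["proportions"] == d2["proportions"]
    assert sum(d1["proportions"].values()) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        B.feature_distribution([])


# -------------------------------------------------------- sequence content
def test_nucleotide_composition_strand_aware():
    genome = {"chr1": "ATATAAAA"}
    comp = B.nucleotide_composition([make_site("s", 0, 4, strand="+")], genome)
    assert comp == {"A": 0.5, "C": 0.0, "G": 0.0, "U": 0.5}
    comp = B.nucleotide_composition([make_site("s", 4, 8, strand="-")], genome)
    assert comp["U"] == 1.0  # AAAA reverse-complements to UUUU
    assert sum(comp.values()) == pytest.approx(1.0)


def test_nucleotide_composition_matches_tally_oracle():
    rng = np.random.default_rng(5)
    genome = {"chr1": "".join(rng.choice(list("ACGT"), 3000))}
    sites = []
    for i in range(60):
        s = int(rng.integers(0, 2950))
        sites.append(
            make_site(f"s{i}", s, s + int(rng.integers(5, 50)),
                      strand="+" if rng.random() < 0.5 else "-")
        )
    comp = B.nucleotide_composition(sites, genome)
    tally = {b: 0 for b in "ACGU"}
    comp_map = {"A": "U", "C": "G", "G": "C", "T": "A"}
    for s in sites:
        seq = genome["chr1"][s.interval.start : s.interval.end]
        if s.interval.strand == "-":
            rna = [comp_map[b] for b in reversed(seq)]
        else:
            rna = ["U" if b == "T" else b for b in seq]
        for b in rna:
            tally[b] += 1
    total = sum(tally.values())
    for b in "ACGU":
        assert comp[b] == pytest.approx(tally[b] / total)


def test_nucleotide_composition_out_of_bounds_errors():
    with pytest.raises(ValueError):
        B.nucleotide_composition([make_site("s", 0, 100)], {"chr1": "ACGT"})


def test_kmer_top_counts_and_ranking():
    genome = {"chr1": "TTTTT"}
    df = B.kmer_top([make_site("s", 0, 5)], genome, k=5)
    assert df.iloc[0]["kmer"] == "UUUUU" and df.iloc[0]["count"] == 1
    genome = {"chr1": "ACGTACGTACG"}
    sites = [make_site("s", 0, 11)]
    df = B.kmer_top(sites, genome, k=4)
    assert df["count"].sum() == 11 - 4 + 1  # sum equals len - k + 1
    with pytest.raises(ValueError):
        B.kmer_top(sites, genome, k=2)


# ---------------------------------------------------- circ-E / NE partition
def test_classify_exons_examples():
    gene = make_gene("g", [(i * 100, i * 100 + 50) for i in range(5)])
    circ = make_circ("c", gene, 2, 3)
    recs = B.classify_exons(gene, [circ])
    circ_e = {o for r in recs if r.klass == "circ-E" for o in r.exon_ordinals}
    ne = {o for r in recs if r.klass == "NE" for o in r.exon_ordinals}
    assert circ_e == {2, 3} and ne == {1, 4, 5}

    full = make_circ("c2", gene, 1, 5)
    recs = B.classify_exons(gene, [full])
    assert all(r.klass == "circ-E" for r in recs)

    assert B.classify_exons(gene, []) == []  # no circRNA -> contributes nothing


def test_classify_exons_partition_matches_membership_oracle():
    rng = np.random.default_rng(9)
    for trial in range(50):
        n = int(rng.integers(3, 9))
        gene = make_gene(
            "g", [(i * 100, i * 100 + 50) for i in range(n)],
            strand="+" if rng.random() < 0.5 else "-",
        )
        circs = []
        for j in range(int(rng.integers(1, 4))):
            a = int(rng.integers(1, n + 1))
            d = int(rng.integers(a, n + 1))
            circs.append(make_circ(f"c{j}", gene, a, d))
        recs = B.classify_exons(gene, circs)
        circ_e = {o for r in recs if r.klass == "circ-E" for o in r.exon_ordinals}
        ne = {o for r in recs if r.klass == "NE" for o in r.exon_ordinals}
        oracle = {
            o
            for o in range(1, n + 1)
            if any(c.acceptor_exon_ordinal <= o <= c.donor_exon_ordinal for c in circs)
        }
        assert circ_e == oracle
        assert ne == set(range(1, n + 1)) - oracle  # exact partition


def test_flanking_introns_strand_cases():
    plus = make_gene("g", [(i * 100, i * 100 + 50) for i in range(5)], strand="+")
    up, down = B.flanking_introns_of(plus, [2, 3])
    assert up.upstream_exon_ordinal == 1 and down.upstream_exon_ordinal == 3
    assert (up.interval.start, up.interval.end) == (50, 100)
    assert (down.interval.start, down.interval.end) == (250, 300)

    minus = make_gene("g", [(i * 100, i * 100 + 50) for i in range(5)], strand="-")
    up_m, down_m = B.flanking_introns_of(minus, [2, 3])
    # genomically mirrored: transcription ordinal 2 on "-" is the 4th exon
    assert (up_m.interval.start, up_m.interval.end) == (350, 400)
    assert (down_m.interval.start, down_m.interval.end) == (150, 200)

    up, down = B.flanking_introns_of(plus, [1, 2])
    assert up is None  # first-exon group has no upstream FI
    up, down = B.flanking_introns_of(plus, [5])
    assert down is None


def test_profile_flanking_introns_tallies():
    gene = make_gene("g", [(0, 50), (150, 200), (400, 450), (600, 650)])
    circ = make_circ("c", gene, 2, 3)
    sites = [
        make_site("a", 60, 80, reads=7),
        make_site("b", 100, 120, reads=9),
        make_site("elsewhere", 5000, 5050, reads=50),
    ]
    recs = B.classify_exons(gene, [circ])
    profs = B.profile_flanking_introns(recs, {"g": gene}, sites, {"c": "up"})
    by_key = {(p.klass, p.intron_upstream_ordinal): p for p in profs}
    fi_up = by_key[("circ-E", 1)]  # intron (50,150) holds both sites
    assert fi_up.n_sites == 2 and fi_up.total_intensity == 16
    fi_down = by_key[("circ-E", 3)]
    assert fi_down.n_sites == 0 and not fi_down.has_binding


def test_profile_matches_interval_overlap_oracle(default_sim):
    genes = {g.gene_id: g for g in default_sim.genes}
    circs_by_gene = {}
    for c in default_sim.circs:
        circs_by_gene.setdefault(c.gene_id, []).append(c)
    recs = []
    for gid, cs in list(circs_by_gene.items())[:150]:
        recs.extend(B.classify_exons(genes[gid], cs))
    profs = B.profile_flanking_introns(recs, genes, default_sim.sites, {})
    assert len(profs) >= 500
    for p in profs:
        intron = next(
            i
            for i in genes[p.gene_id].introns
            if i.upstream_exon_ordinal == p.intron_upstream_ordinal
        )
        hits = [
            s
            for s in default_sim.sites
            if overlap(s.interval, intron.interval) >= 1
        ]
        assert p.n_sites == len(hits)
        assert p.total_intensity == sum(s.reads for s in hits)
        assert p.length == len(intron.interval)


# ------------------------------------------------------- group comparisons
def _null_profiles(rng, n, group):
    out = []
    for i in range(n):
        ns = int(rng.poisson(0.8))
        out.append(
            B.FlankingIntronProfile(
                gene_id=f"{group}{i}",
                klass="circ-E",
                group=group,
                intron_upstream_ordinal=1,
                length=int(rng.lognormal(6, 0.6)),
                n_sites=ns,
                total_intensity=int(rng.gamma(2, 15) * ns),
            )
        )
    return out


def test_compare_flanking_groups_identical_groups():
    rng = np.random.default_rng(3)
    a = _null_profiles(rng, 60, "a")
    rep = B.compare_flanking_groups({"a": a, "b": list(a)})
    c = rep["comparisons"]["a_vs_b"]
    assert c["p_has_binding_chi2"] == pytest.approx(1.0)
    assert c["p_length_t"] == pytest.approx(1.0)


def test_compare_flanking_groups_degenerate_margin():
    rng = np.random.default_rng(4)
    a = _null_profiles(rng, 30, "a")
    none_bound = [
        B.FlankingIntronProfile("g", "NE", None, 1, 500, 0, 0) for _ in range(30)
    ]
    all_zero = {"a": none_bound, "b": list(none_bound)}
    with pytest.raises(ValueError, match="margin"):
        B.compare_flanking_groups(all_zero)


def test_planted_fi_enrichment_detected_at_strict_alpha():
    """Longer, denser, stronger binding in up-circ-E FIs is detected (α=0.001)."""
    sim = simulate_study(SimConfig(seed=0, n_genes=1500))
    genes = {g.gene_id: g for g in sim.genes}
    hc = B.filter_high_confidence(sim.sites)
    truth = sim.truth_circs.set_index("circ_id")
    groups = {
        c: ("up" if truth.loc[c, "regulated"] else "non-up") for c in truth.index
    }
    recs = []
    by_gene = {}
    for c in sim.circs:
        by_gene.setdefault(c.gene_id, []).append(c)
    for gid, cs in by_gene.items():
        recs.extend(B.classify_exons(genes[gid], cs))
    profs = B.profile_flanking_introns(recs, genes, hc, groups)
    grouped = {}
    for p in profs:
        key = "NE" if p.klass == "NE" else f"circ-E:{p.group}"
        grouped.setdefault(key, []).append(p)
    rep = B.compare_flanking_groups(grouped)
    c = rep["comparisons"]["NE_vs_circ-E:up"]
    assert c["p_has_binding_chi2"] < 1e-3
    assert c["p_n_sites_chi2"] < 1e-3
    assert c["p_length_t"] < 1e-3
    assert c["p_intensity_t"] < 1e-3
    # directions match the plant
    g = rep["groups"]
    assert g["circ-E:up"]["prop_with_binding"] > g["NE"]["prop_with_binding"]
    assert g["circ-E:up"]["mean_length"] > g["NE"]["mean_length"]
    assert g["circ-E:up"]["mean_intensity"] > g["NE"]["mean_intensity"]


# --------------------------------------------------- per-gene binding stats
def test_exonic_binding_fraction():
    gene = make_gene("g", [(0, 50), (100, 150), (200, 250)])
    circ = make_circ("c", gene, 2, 2)
    hit = [make_site("s", 120, 130)]
    miss = [make_site("s", 60, 80)]  # intronic: not in a composing exon
    assert B.exonic_binding_fraction([circ], {"g": gene}, hit)["n_with"] == 1
    assert B.exonic_binding_fraction([circ], {"g": gene}, miss)["n_with"] == 0
    assert B.exonic_binding_fraction([circ], {"g": gene}, [])["pct"] == 0.0


def test_gene_length_comparison():
    rng = np.random.default_rng(6)
    base = rng.lognormal(9, 0.4, 100)
    same = B.gene_length_comparison(base, base.copy())
    assert same["p_value"] > 0.9
    longer = base * 2
    rep = B.gene_length_comparison(longer, base)
    assert rep["p_value"] < 1e-6
    assert rep["median_with"] / rep["median_without"] == pytest.approx(2.0, rel=0.05)
    flipped = B.gene_length_comparison(base, longer)
    assert flipped["p_value"] == pytest.approx(rep["p_value"])  # two-sided
    with pytest.raises(ValueError):
        B.gene_length_comparison([1, 2], base)


def test_genes_with_binding_fraction():
    genes = [make_gene(f"g{i}", [(i * 1000, i * 1000 + 100)]) for i in range(10)]
    sites = [make_site("s0", 10, 20), make_site("s1", 1010, 1020)]
    rep = B.genes_with_binding_fraction(genes, sites)
    assert rep == {"n_with": 2, "n_total": 10, "fraction": 0.2, "pct": 20.0}


# ------------------------------------------------------- mirror symmetry
def _mirror_interval(iv, L):
    return GenomicInterval(iv.chrom, L - iv.end, L - iv.start,
                           "-" if iv.strand == "+" else "+")


def test_strand_mirror_leaves_fi_statistics_unchanged(small_sim_dir):
    """Reverse-complementing the genome mirrors coordinates but not statistics."""
    sim, _ = small_sim_dir
    L = {c: len(s) for c, s in sim.chrom_seqs.items()}
    mirrored_genes = {}
    for g in sim.genes:
        flipped = "-" if g.strand == "+" else "+"
        spans = [
            (L[g.chrom] - e.interval.end, L[g.chrom] - e.interval.start)
            for e in g.exons
        ]
        mirrored_genes[g.gene_id] = make_gene(
            g.gene_id, spans, strand=flipped, chrom=g.chrom, biotype=g.biotype
        )
    mirrored_circs = []
    for c in sim.circs:
        mirrored_circs.append(
            make_circ(
                c.circ_id,
                mirrored_genes[c.gene_id],
                c.acceptor_exon_ordinal,
                c.donor_exon_ordinal,
            )
        )
    from circbalance.genome import BindingSite

    mirrored_sites = [
        BindingSite(s.site_id, _mirror_interval(s.interval, L[s.interval.chrom]),
                    s.reads, s.p_value)
        for s in sim.sites
    ]

    truth = sim.truth_circs.set_index("circ_id")
    groups = {c: ("up" if truth.loc[c, "regulated"] else "non-up") for c in truth.index}

    def profiles(genes_map, circs, sites):
        by_gene = {}
        for c in circs:
            by_gene.setdefault(c.gene_id, []).append(c)
        recs = []
        for gid, cs in by_gene.items():
            recs.extend(B.classify_exons(genes_map[gid], cs))
        profs = B.profile_flanking_introns(recs, genes_map, sites, groups)
        return sorted(
            (p.gene_id, p.klass, p.group, p.length, p.n_sites, p.total_intensity)
            for p in profs
        )

    original = profiles({g.gene_id: g for g in sim.genes}, sim.circs, sim.sites)
    mirrored = profiles(mirrored_genes, mirrored_circs, mirrored_sites)
    assert original == mirrored
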