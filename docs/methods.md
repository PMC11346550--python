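# Methods

## The problem

Exonic circRNAs arise when a downstream splice donor is joined back to an
upstream acceptor (backsplicing). Backsplicing competes with linear splicing
of the same pre-mRNA, and RNA-binding proteins acting on the introns that
flank a circularised exon block can tip that competition. `circbalance`
implements the computational side of a knockout study of such a suppressor:
given backsplice-junction (BSJ) count tables, gene-level count tables, a gene
annotation, crosslink-derived binding peaks, and a genome sequence, it asks
(i) whether circRNA steady-state and nascent levels rise when the protein is
removed, (ii) whether the protein's binding sites are enriched in the
flanking introns of the circularised exons whose circRNAs respond, and
(iii) for which genes the circRNA:mRNA balance shifts enough to move the
mRNA.

## Coordinate model

All internal coordinates are 0-based half-open (BED convention); GTF I/O
converts at the boundary. One representative transcript per gene is kept:
the transcript with the largest summed exon length, ties broken by the
lexicographically smallest transcript id (annotation sources rarely state a
collapsing rule; this one is deterministic and favours the most complete
model). Exon ordinals count in transcription order, so "upstream" always
means 5'-ward on the transcribed strand; on the minus strand ordinal 1 is
the genomically rightmost exon. Introns are the gaps between consecutive
exons and must tile the transcript span exactly.

## Steady-state quantification

Counts are normalised to reads per million mapped reads (RPM), where the
library size is the sum of gene-level and BSJ counts per sample. A circRNA
is *detected* in a sample at >= 2 BSJ reads (configurable); the analysis set
is the intersection of the WT- and KO-detected sets. Replicates, when
present, are averaged on the RPM scale. The fold change is
`(KO_RPM + pc) / (WT_RPM + pc)` with pseudocount `pc = 0.5`; the pseudocount
enters only the ratio, never the reported RPM. Labels use the inclusive
thresholds FC >= 2 (up) and FC <= 0.5 (down). No significance test is
attached to the per-circRNA classification — it is a pure threshold rule —
while the distribution-level WT/KO comparison uses the two-sample
Kolmogorov–Smirnov test.

RPM is the simplest defensible library-size correction for junction counts;
a junction-spanning-read normalisation would differ by a constant per sample
and not change any label, so the choice is configuration, not substance.

## Nascent fractions

For metabolically labelled (nascent) RNA, each gene's circRNA fraction is
its BSJ reads divided by all nascent reads assigned to the gene (linear plus
backspliced). Genes enter the WT/KO fraction comparison only if they show
both linear splicing and backsplicing (>= 1 read of each) in the condition;
the comparison is an unpaired two-tailed t-test (the pairing of genes across
conditions is incidental to the question of whether backsplicing output as a
whole rises, and the unpaired test is the more conservative default; the
report records which test was used). Nascent fold changes are computed like
the steady ones and dichotomised at FC >= 1.4 into "up" vs "non-up"; the
1.4 threshold is applied to the normalised circRNA level, not to the
fraction. Nascent detection requires >= 1 BSJ read (nascent libraries are
shallow; the steady-state 2-read rule would discard most of the signal).

## Binding sites

High-confidence peaks must satisfy `p < 0.05` and `reads > 5`, both strict.
Feature annotation assigns each (site, gene) pair exactly one feature by the
precedence CDS > 3'UTR > 5'UTR > noncoding exon > intron, requiring >= 1 bp
of overlap; a site overlapping no gene is intergenic, and a site overlapping
two genes is annotated once per gene. Assignment ignores the site's strand:
crosslink peaks are stranded, but a precedence assignment against the host
gene's own features is strand-consistent by construction, and the synthetic
generator places intragenic sites on the host strand. Sequence composition
(A/C/G/U frequencies, k-mer tables, default k = 6) is computed over
strand-corrected site sequences, reverse-complemented for minus-strand sites
and reported in the RNA alphabet.

## Flanking-intron analysis

Exons of circRNA-producing genes are partitioned into circ-E (inside the
contiguous exon block of at least one detected circRNA) and NE (the rest);
genes without detected circRNAs contribute nothing. Each exon group's
flanking introns (FI) are the introns immediately before its first and after
its last exon in transcription order; groups touching a transcript terminus
lack that FI. Each FI record carries its length, the number of
high-confidence sites overlapping it by >= 1 bp, and the binding intensity,
defined as the summed read counts of those sites (a sum, rather than a
maximum, keeps the quantity additive over sites). Unlike feature annotation,
FI profiling does not demand exclusive assignment: a site straddling the
exon/intron boundary counts for the intron it touches, because the question
is presence of binding in the intron.

Group comparisons (NE vs non-up circ-E vs up circ-E) use a chi-square test
without continuity correction on the has-binding proportions over all FIs,
and, on binding-positive FIs only, a chi-square on binned site numbers
(1 / 2 / >= 3) and two-tailed t-tests on length and intensity. Gene-length
comparisons between bound and unbound coding genes use the two-sided
Wilcoxon rank-sum test.

Note that an intron between an NE exon and a circularised block flanks both
groups and therefore appears in both; this is inherent to the FI definition
and dilutes the NE-vs-circ-E contrast rather than inflating it.

## circRNA:mRNA ratio classes

Per gene, the ratio is `(summed circRNA RPM + pc) / (mRNA RPM + pc)` in each
condition, and the KO/WT ratio fold change is classified by the printed
boundaries taken literally: increased when fc > 2, decreased when fc < 1,
unchanged when 1 <= fc <= 2 (so a gene whose circRNA exactly doubles against
a flat mRNA is "unchanged"). The focus set mirrors the study design: genes
with nascent expression in WT, at least one high-confidence binding site,
and at least one detected circRNA. Heatmap normalisation is a per-row
Z-score with the population standard deviation (ddof = 0); a zero-variance
row is an error naming the row.

## The synthetic study

The generator emits a four-chromosome genome, 500 genes (3–8 exons of
100–300 bp, lognormal(6.0, 0.6) intron lengths, both strands, 85% coding),
binding peaks, and WT/KO steady and nascent count tables, with every planted
effect recorded in truth tables. 60% of genes produce a circRNA from an
internal contiguous exon block (10% of them a second one); 30% of the
circRNA genes are "regulated": their flanking introns are 2x longer, receive
binding sites at 4x the background rate of 0.25 sites/kb with 2x intensity,
and their circRNA count means rise 3x in the KO. mRNA means are unchanged
except in a small cdk1-like subset (5% of circRNA genes, drawn from the
regulated ones) where the KO multiplies the mRNA mean by 0.6 — the
circRNA-gain-coupled-to-mRNA-loss pattern the ratio analysis is built to
catch. Site p-values are a mixture (background sites: 30% Uniform(0,1) null;
planted FI sites and the rest: Beta(0.2, 5)), so the high-confidence filter
has known operating characteristics, and an AU-rich hexamer (UAUUUA) is
written into the genome under 80% of sites.

Counts are negative-binomial via gamma–Poisson with variance
`mu + alpha * mu^2` and a shared dispersion `alpha = 0.02`. The emulated
design compares one WT and one KO library from isogenic clonal cell lines,
so the per-count noise relevant to a fold-change threshold is shot noise
plus technical dispersion, not the ~0.1 biological dispersion of independent
replicates; 0.02 is in the range routinely estimated for technical/clonal
RNA-seq and is the regime in which a 3x effect is reliably separable from a
2x threshold. Expected mRNA totals are 2,000,000 reads (nascent: 200,000),
with per-gene relative abundances lognormal(0, 1) and circRNA:mRNA count
ratios lognormal(ln 0.03, 0.5) capped at 0.2.

What the generator does *not* emulate: multi-isoform transcription,
positional biases within introns, correlated site placement (clustered
crosslink peaks), sequence-dependent backsplicing efficiency, Alu-pairing
structure, and batch effects. Passing tests therefore demonstrate the
correctness and calibration of the computations, not the biological truth of
any claim about real data. One emergent property worth knowing: because
planted binding concentrates on regulated genes, the focus set of the ratio
analysis is enriched for regulated genes, and the "increased" fraction
within that set is higher than in real data; the claim that the increased
set is small is therefore evaluated against the whole gene universe.

## Problem sizes and numerical choices

The default study (500 genes) runs the full pipeline in about one second.
Two analyses use dedicated sizes chosen for the property under test: the FI
site-rate recovery uses 1,200 genes so that at least 300 planted
(enriched-rate) FIs contribute to the rate estimate, and the
planted-enrichment significance check uses 1,500 genes, where all four group
comparisons have comfortable power at alpha = 0.001. Type-I calibration uses
200 null replicates of 80 FIs per group (expected cell counts stay above the
chi-square approximation's comfort zone). Chi-square tests are computed
without Yates correction — the correction is conservative and would distort
the 5% calibration check. Ties in k-mer ranking break lexicographically.
Degenerate inputs (zero library sizes, empty DE sets, zero-variance rows,
zero-margin contingency tables) raise errors naming the offending object
rather than propagating NaNs.
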