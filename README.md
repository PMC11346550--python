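# circbalance

Tools for studying how an RNA-binding protein suppresses exonic circRNA
biogenesis. Exonic circRNAs form when a downstream splice donor joins back
to an upstream acceptor (a backsplice junction, BSJ); backsplicing competes
with linear splicing, and proteins binding the introns that flank a
circularised exon block can suppress it. Given BSJ count tables, gene-level
count tables, a GTF annotation, crosslink-derived binding peaks (BED6 plus
read count and p-value), and a genome FASTA, `circbalance`:

- detects and classifies differentially expressed circRNAs between wild-type
  (WT) and knockout (KO) conditions by RPM fold change
  (up: FC ≥ 2, down: FC ≤ 0.5, detection at ≥ 2 BSJ reads);
- measures per-gene nascent circRNA fractions (BSJ reads / all nascent reads
  of the gene) and nascent fold-change classes (up: FC ≥ 1.4);
- filters binding sites to high confidence (p < 0.05, reads > 5), annotates
  them to genomic features (CDS/UTR/exon/intron/intergenic), summarises
  their nucleotide and k-mer composition, and compares flanking-intron (FI)
  length, site number, and binding intensity between backsplicing exon
  groups (circ-E) and non-backsplicing exons (NE) of the same genes;
- classifies each gene's circRNA:mRNA ratio fold change (KO/WT) into
  increased (> 2), decreased (< 1), or unchanged ([1, 2]);
- simulates a complete synthetic study — genome, annotation, peaks, WT/KO
  steady and nascent counts — with planted, truth-tracked effects, so every
  stage is testable without external data.

The scientific model and all parameter choices are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Run the whole pipeline on the built-in synthetic study:

```bash
circbalance report --seed 17 --out demo_run
```

or equivalently from Python:

```python
from circbalance.pipeline import RunConfig, run_pipeline
report = run_pipeline(RunConfig(outdir="demo_run", seed=17))
print(report["quantify"]["summary"])
```

which prints

```
{'n_tested': 313, 'n_de': 96, 'n_up': 95, 'n_down': 1,
 'pct_up': 99.0, 'pct_down': 1.0}
```

— of 313 circRNAs detected in both conditions, 96 pass the fold-change
thresholds and 99% of those are up in the KO: the planted suppressor
signature. The full report (`demo_run/summary.json`) also shows, for this
seed:

- the circRNA RPM distribution shifts up in KO (KS p = 0.0071) while the
  mRNA distribution does not (KS p = 0.96);
- the nascent circRNA fraction rises from 3.6% to 6.1% of a gene's nascent
  output (t-test p = 7.1e-13 over 283 genes) — biogenesis, not just
  stability;
- 61.6% of high-confidence binding sites are intronic and binding peaks are
  A/U-rich, with `UAUUUA` the top hexamer;
- FIs of up-regulated circ-Es carry binding more often than NE introns
  (47.9% vs 12.0%, chi-square p < 1e-15) and are longer with stronger
  binding;
- of 147 focus genes (nascent-expressed, bound, circRNA-producing), 69 have
  an increased circRNA:mRNA ratio in KO — a set that contains the planted
  "cdk1-like" genes whose circRNA gain is coupled to an mRNA loss.

Per-stage tables (`de_circ.tsv`, `nascent_fractions.tsv`,
`fi_profiles_steady.tsv`, `ratio_records.tsv`, …) and figures (MA plot,
cumulative fraction curves, FI boxplots) are written next to the summary.
To analyse real data instead, point `RunConfig` (or a YAML config with
`--config`) at your GTF/BED/TSV/FASTA files and set `simulate: false`.

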