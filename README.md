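# nucquant

Intron-aware UMI quantification, quality control, and diagnostics for
droplet-based single-cell (Drop-seq-style) and single-nucleus
(DroNc-seq-style) 3′ RNA-seq.

## Why introns matter for single-nucleus RNA-seq

Single-nucleus libraries sample the nuclear transcriptome, which is rich in
unspliced pre-mRNA: up to ~50% of aligned reads fall in introns, versus
~7% for whole-cell libraries. Discarding those reads wastes half the data
and depresses gene detection in already-shallow nuclear libraries.
`nucquant` derives per-gene intron annotations by strand-aware interval
subtraction (gene span minus the exon union over all transcripts), assigns
each barcoded read to a gene and a region class (exonic, intronic,
ambiguous, intergenic), and counts distinct UMIs per gene and cell in two
modes — exon-only and exon+intron — where a UMI seen in both regions of
the same gene counts once:

```
count(g, c) = |{ UMI u : some read of cell c with UMI u maps to an
                 admitted region of gene g }|
```

Around that core the package provides:

- **Read tagging** — cell-barcode whitelisting (barcodes with ≥ 30,000
  reads), fusing of paired reads (12 bp barcode + 8 bp UMI on read 1, 60 bp
  cDNA on read 2) into tagged records, and 3′ polyA trimming.
- **QC filters** — cells/nuclei with < 400/300 detected genes removed, then
  genes detected in < 10 surviving cells; per-cell summaries; the per-cell
  *detection gain* of intron inclusion, genes_both(c)/genes_exon(c).
- **Internal-priming diagnostics** — scan the genome for maximal A-runs
  (and T-runs for the reverse strand) of ≥ 5 bp, intersect intronic reads
  extended by 20 bp with those tracts strand-specifically, and histogram the
  tract 3′-end positions along the read. Oligo-dT priming at genomic
  A-stretches piles tract positions up at read 3′ ends.
- **Expression comparison** — TP10k / log1p / per-gene standardization
  ladder, binned-dispersion highly-variable-gene selection (dispersion
  z ≥ 1.5, log-mean ≥ 0.15), pseudo-bulk aggregation, Pearson correlation
  profiles, and hierarchical bi-clustering.
- **Droplet loading model** — Poisson co-encapsulation: λ = concentration ×
  droplet volume (200,000 cells/mL × 380 pL ⇒ λ = 0.076), occupancy pmf,
  the doublet fraction among occupied droplets
  (1 − e^{−λ} − λe^{−λ})/(1 − e^{−λ}), and a barnyard (two-species mixing)
  doublet estimator with the 1/(2f(1−f)) cross-species correction.
- **Synthetic data** — a seeded generator that emits a toy genome, GTF,
  planted polyA tracts, and aligned barcoded reads (SAM) with a per-read
  truth table, so every stage is testable without external downloads.

## Worked example

Simulate 100 nuclei under nucleus-mode defaults (mean 721 UMIs per
nucleus, 50% intronic reads, 40% of intronic reads internally primed) and
run the full pipeline:

```bash
nucquant simulate --mode nucleus --seed 7 --n-cells 100 --outdir demo/sim
# 40 genes, 100 cells, 86635 reads -> demo/sim
```

```yaml
# demo/cfg.yaml
gtf: demo/sim/annotation.gtf
reads: demo/sim/reads.sam
genome: demo/sim/genome.fa
outdir: demo/out
mode: nucleus
min_genes_nucleusmode: 30   # desk-scale thresholds for a 40-gene toy genome
min_cells_per_gene: 5
seed: 7
```

```bash
nucquant run --config demo/cfg.yaml
```

`demo/out/qc_report.json` then reads (abridged):

```json
{
  "n_cells_raw": 100,
  "n_cells_filtered": 94,
  "region_fractions": {"exonic": 0.497, "intronic": 0.503,
                       "ambiguous": 0.0, "intergenic": 0.0},
  "mean_detection_gain": 1.119
}
```

and `demo/out/priming_report.json`:

```json
{
  "n_tracts": 80,
  "n_intronic_reads": 43566,
  "polya_read_fraction": 0.397,
  "three_prime_mass_share": 1.0
}
```

Reading: the pipeline recovers the configured 50% intronic read fraction
(0.503 observed) and the 40% polyA co-occurrence rate among intronic reads
(0.397), and every polyA hit sits in the 3′ half of the read axis — the
internal-priming signature. The mean detection gain of 1.12 on this toy
genome is modest because 40 genes saturate quickly; gene detection gains
grow with annotation size and shallower per-gene coverage.

The loading model is available standalone:

```bash
nucquant loading --concentration 200000 --droplet-volume 380
# {"lambda": 0.076, "droplets_per_ml": 2631578.9...,
#  "droplets_per_ml_rounded": 2600000.0,
#  "doublet_fraction_occupied": 0.0375...}
```

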