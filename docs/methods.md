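# Methods

This note documents the models and procedures implemented in `nucquant`,
the parameters that matter, the design choices made where more than one
convention was defensible, and what the synthetic-data generator does and
does not emulate.

## Coordinates and annotation model

All internal coordinates are 0-based half-open; GTF input (1-based closed)
is converted at the parsing boundary and converted back when GTF is
emitted. A gene is modeled as a span plus the union of its exons over all
transcripts; introns are the strand-aware set difference span ∖ exon-union,
so exons and introns tile the span exactly. No biotype or annotation-level
filter is applied before subtraction. Overlapping genes are kept
independent: a base may be exonic in one gene and intronic in another, and
the ambiguity is resolved per read at assignment time, not in the
annotation.

## Read tagging

The whitelist is a hard count threshold (default 30,000 reads per
barcode), not a knee-point detector; the threshold is a parameter so
desk-scale simulations can lower it. Barcodes containing N are excluded —
an ambiguous base in the barcode makes the bead identity unreliable — and
no barcode error-correction is attempted. PolyA trimming removes only a
maximal 3′-terminal run of at least `min_run` adenines (default 6, the
shortest run unlikely to occur by chance at the end of a 60 bp read);
general adapter trimming is out of scope and expected upstream.

## Feature assignment and UMI counting

A read is an interval, not a split alignment. Assignment rules, in order:

1. Features overlapping the read are collected per gene (optionally
   restricted to the read's strand; default unstranded, matching common
   gene-level counters).
2. One gene hit → exonic if any exon of that gene is touched (exon
   precedence within a gene), else intronic.
3. Two or more distinct gene hits → ambiguous, counted toward nothing.
   With `exon_priority`, a read exonically overlapping exactly one gene
   wins over other genes' introns; the conservative default is ambiguous.
4. No hit (or unknown chromosome, with a warning) → intergenic.

Exon precedence within a gene is harmless for gene-level counts: after UMI
deduplication the gene total is the same whether a boundary-spanning read
is called exonic or intronic. Only primary alignments are counted. UMI
deduplication is exact string identity per (cell, gene); no edit-distance
collapsing. In exon+intron mode a UMI observed in both an exonic and an
intronic read of one gene counts once — the "sum of exon and intron UMIs"
is the size of the union of distinct molecules, not an exonic count plus
an intronic count, which would double-count molecules spanning both
evidence classes. This guarantees the entrywise dominance
exon+intron ≥ exon-only that the detection-gain statistic relies on.

Matrices are sparse genes × cells with a recorded counting mode; merging
runs takes the sorted union of genes, fills absent entries with zero, and
refuses duplicate barcodes unless per-run suffixes are supplied.

## QC filters and summaries

Filter order is fixed and matters: cells (nuclei) with fewer than 400
(300) detected genes are removed first, then genes detected in fewer than
10 of the *surviving* cells. Both thresholds are strict "less than"
removals, so a cell at exactly the minimum survives. Detection uses ≥ 1
UMI. The top-cells selection keeps ⌈fraction × n⌉ cells by detected genes
with deterministic tie-breaks (total UMI, then barcode); the fraction is a
parameter (default 0.30) because published selections of "top 30%" do not
always correspond to an exact 0.30 quantile. Detection-gain ratios with
zero exon-only detection are infinite; they are excluded from the mean and
reported as a separate count.

## Internal-priming diagnostic

The genome scan finds maximal runs of ≥ 5 consecutive adenines as +
tracts and ≥ 5 thymines as − tracts (a T-run is an A-run on the reverse
strand); runs are broken by N, case is ignored, and soft-masked bases are
treated as ordinary. A `forward_only` switch restricts to A-runs.
Intronic reads are extended by 20 bp on each side and intersected with
tracts on the same chromosome and (by default) the same strand —
"strand-specific" here means tract strand equals read alignment strand,
because oligo-dT priming targets A-runs on the transcript strand.

Position histograms use the tract 3′ end relative to the read 5′ end in
read orientation (mirrored for − reads), binned at 5 bp over
[−flank, read_len + flank]. The summary statistic is the ratio of
histogram mass 3′ of the axis midpoint to the mass 5′ of it; genuine
internal priming drives this far above 1, while uniformly placed tracts
give a flat histogram and a ratio near 1.

## Normalization, HVG selection, correlation

The ladder is TP10k (per-cell totals scaled to 10⁴) → natural-log(1 + x)
→ per-gene standardization (zero mean, unit variance; constant genes
become zero rows and are flagged). Each rung is a separate, composable
step. Dispersion for variable-gene selection is variance/mean on the
exponentiated scale, z-scored within 20 equal-frequency bins of the mean
(bin count is a config field, reduced with a warning when genes are
scarce); selection requires dispersion z ≥ 1.5 and log-scale mean ≥ 0.15,
and zero-variance genes are never selected. Pseudo-bulk sums raw counts
over a group before log-TP10k — summing before normalizing weights cells
by depth, which is the intended bulk-like behavior. Pearson correlation is
computed over an explicit gene set (default: genes shared by both sides;
optionally capped to top-N by mean expression); zero-variance profiles
yield missing values rather than spurious coefficients. Bi-clustering
applies hierarchical agglomeration independently to rows and columns,
defaulting to complete linkage on Euclidean distance (the convention of
the classic correlation-heatmap function), with average linkage on 1 − r
selectable.

## Droplet loading

λ = concentration[mL⁻¹] × droplet volume[pL] × 10⁻⁹. The doublet fraction
is defined among *occupied* droplets — what a sequencing run can observe —
as (1 − e^{−λ} − λe^{−λ})/(1 − e^{−λ}), computed with `expm1` for
numerical stability at small λ and verified by a Monte-Carlo twin. The
barnyard estimator classifies a barcode as a cross-species collision when
its minor-species read fraction exceeds 1 − purity_threshold (default
threshold 0.9) and scales the observed collision rate by 1/(2f(1−f)),
since only that fraction of doublets mixes species at mixing fraction f;
the result is capped at 1. Threshold and correction are parameters because
published mixing experiments rarely state their classifier.

## Synthetic-data generator

The generator emulates the features of cell vs nucleus libraries that the
pipeline measures, with defaults set to the study conditions: mean UMIs
per cell 1474 (cell mode) and 721 (nucleus mode); intronic read fractions
0.07 and 0.50; internal-priming rate 0.4 among intronic reads; nucleus
mode up-weights lncRNA genes (15% of genes, 4× enrichment) and cell mode
up-weights mitochondrial/ribosomal genes (5% + 10% of genes, 4×).
Expression is gamma-Poisson (gamma-distributed per-cell totals and
per-gene-per-cell rate multipliers over gamma base weights) — standard
overdispersion for UMI counts; the pipeline fits no expression model, so
the generator only needs plausible variability. Optional features: two
populations with perturbed gene weights (for correlation-separability
tests), doublet barcodes merging two cells' molecules, and a two-species
label per cell for barnyard runs.

Several geometric guarantees make truth recovery exact rather than
approximate:

- background sequence has all A/T homopolymers capped at 4 bp, below the
  polyA scan threshold, so the only tracts are the planted ones (a
  `tract_free_background=False` switch restores natural background runs);
- genes never overlap and are separated by ≥ 500 bp, so no read is
  ambiguous;
- every gene has ≥ 2 introns; polyA tracts are planted only in the first
  intron, primed reads are placed with their 3′ ends 1–4 bp into a tract
  of their gene, and non-primed intronic reads go to later introns, out of
  flanking reach of any tract;
- exons and introns are long enough (≥ read length, and ≥ read length +
  2 × flank respectively) that every read fits inside a single feature.

Reads are emitted pre-aligned (SAM dialect with barcode/UMI in the read
name; alignment itself is out of scope), each molecule yielding
1 + Poisson(0.3) identical PCR copies; a FASTQ emitter supports testing
the tagging stage. All outputs are byte-reproducible under the config
seed, which feeds independent per-stage random streams.

What the generator does **not** emulate — and therefore what passing tests
do not establish about real data: sequencing errors and base qualities,
barcode collisions or bead-synthesis errors, multi-mapping and split
alignments, overlapping gene models (except via the dedicated overlap
layouts built in tests), realistic transcriptome-scale gene counts, and
ambient RNA. Parameter-recovery results show the pipeline is correct under
its stated assignment rules, not that those rules are optimal for any
particular tissue.

## Problem sizes and numerical choices

The heavyweight recovery check simulates 500 nuclei at the default 721
mean UMIs (~470k reads) — comfortably above the floors of 500 cells and
50k reads and large enough that 3-binomial-s.e. recovery bands are a few
tenths of a percent. The Monte-Carlo loading check uses 10⁶ droplets.
Statistical assertions in tests use seeded generators and 3-s.e. (or
χ², α = 0.01) bounds; exact assertions (interval algebra, UMI set counts,
QC filters, MTX/SAM round-trips) use brute-force oracles or round-trip
identity. Degenerate inputs are defined rather than crashed on: empty
whitelists warn, empty QC results return empty matrices with a warning,
single-row bi-clustering returns the identity order, and constant genes
standardize to zero and are flagged.

## Known limitations

GTF only (no GFF3); no transcript-level quantification; no barcode
mismatch rescue or UMI edit-distance collapsing; reads are treated as
single intervals, so spliced alignments spanning multiple features are
assigned by their full span; the HVG binning uses equal-frequency bins,
which will differ in detail from tools that bin by equal width; counts
correction for internal priming is diagnosed but not applied.
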