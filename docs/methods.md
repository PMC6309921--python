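# Methods

This note documents the models, conventions, parameter defaults and
numerical choices behind `lnctx`, and what the synthetic-data tests do
and do not establish about real data.

## Coordinates and signal model

All coordinates are 0-based, half-open. GTF input (1-based inclusive)
is converted on read; BED and narrowPeak are consumed natively. A TU's
TSS is `start` on the + strand and `end` on the − strand.

`StrandedSignalTrack` stores per-base signal as one dense numpy array
per (chromosome, strand) with an attached library size. Dense storage
was chosen over a sparse position map because the package targets
desk-scale genomes (the default synthetic genome is 3 × 2 Mb, and
windows of interest are ≤ a few Mb even on real chromosomes); it makes
region sums, metagene slicing and the brute-force oracle comparisons
exact array operations. Memory is ~16 MB per track per 2-Mb chromosome.

**mNET-seq reduction.** Each proper pair adds +1 at the 3'-terminal
aligned base of read 2 (rightmost base of a plus-strand alignment,
leftmost of a minus-strand one; soft-clipped bases are excluded, and a
spliced alignment would contribute its final aligned block). The
signal strand is derived from read 1 under the `reverse_of_read1`
convention by default (dUTP-style first-strand libraries); the
generator uses the same setting, so recovery results are
convention-independent. The reduction conserves mass exactly: track
total = retained pair count.

**Coverage reduction.** RNA-seq, mNuc-seq and ChIP-seq pairs add +1
over the union span of the two mates. mNuc/ChIP tracks are unstranded
and duplicate-filtered; mNET-seq is not duplicate-filtered (a
single-nucleotide assay legitimately stacks identical positions).

## Quantification

The unit throughout is count × (10⁸ / library size) / region length,
log2-transformed for comparisons. Class windows: PROMPT = TSS→+3 kb,
eRNA = center ± 2 kb, CRI window = TSS→+5 kb, all strand-aware; gene
classes use TSS→TES. mNET-seq/RNA-seq counts use the region's
annotated strand; chromatin marks are unstranded.

**IP − input.** Normalised input is subtracted from normalised IP and
divided by length. Within one region set: regions non-positive in
every sample are dropped; remaining non-positive values are imputed at
half the smallest positive value of the same sample. The imputation is
applied per region set per sample — pooling heterogeneous sets (e.g.
coding genes with PROMPTs) would let the larger class set the
pseudo-floor and can invert class comparisons. When a sample has no
positive value at all over a set (a mark absent from that class), the
fallback floor is half the smallest positive value across all samples
of the set; such cells are flagged.

**CRI.** `log2(chromatin / nucleoplasm)` over the 5-kb PROMPT window,
both sides normalised to library and length. The length terms cancel;
the log of the ratio is used (not a ratio of logs). Zero values are
replaced by half the smallest positive value of their own fraction and
flagged.

**Mark ratios.** `log2(mark / denominator)`, and when a Pol II level
is supplied the ratio is divided by it before the log —
`log2((mark/denom)/polii)` — i.e. transcription-normalised enrichment.

**Binned correlation.** Genome-wide 10-kb bin totals (strands pooled),
all-zero bins skipped, Spearman by default.

**Tests.** Wilcoxon rank-sum (Mann–Whitney U, two-sided) for unpaired
comparisons, Wilcoxon signed-rank for paired ones; degenerate all-tied
input is rejected rather than given an arbitrary p-value.

## Transcription-unit selection

The non-overlapping coding set requires: no other annotated feature of
any biotype, on either strand, within 2.5 kb of the TU span (the
stricter of the two readings of "non-overlapping"); length > 2 kb; and
membership in the top 3 of 4 k-means clusters of chromatin RNA
coverage. Coverage is the normalised base count divided by TU length,
log2(x+1)-transformed before clustering — k-means on raw coverage
spanning three orders of magnitude is dominated by the extreme tier,
and the log stabilises it. k-means uses Lloyd's algorithm with 10
restarts and a fixed seed; clusters are ranked by mean transformed
coverage. Under ≥10× tier separation the partition is seed-invariant
(asserted in tests).

PROMPT pairing takes the nearest opposite-strand coding gene by
TSS-to-TSS distance, ties broken toward the smaller start coordinate.
mRNA–lincRNA pairs require opposite strands, TSS distance < 3 kb, and
≥10 raw nascent reads over each partner's span in at least one
condition (each partner may satisfy this in a different condition).
Histone genes are recognised by gene-name prefixes
(HIST\*, H1-, H2A-, H2B-, H3-, H4-), configurable since annotations
differ in their naming schemes.

## Metagene profiles

10-bp bins; rows oriented 5'→3' by strand. Bins falling off the
chromosome are missing (NaN) and excluded from column means —
zero-filling would bias window edges downward. Scaled-region mode bins
the flanks natively and rescales the body by linear interpolation of
the cumulative signal, which conserves body mass exactly under any
body-bin count.

## R-loop peak annotation

Peak strand = strand with the majority of overlapping strand-specific
read signal; exact ties and read-free peaks get ".". Genomic category
is decided at the summit with precedence exon > intron > upstream >
downstream > distal (upstream/downstream = 2-kb strand-aware flanks).
Summit-based assignment guarantees the categories partition the peak
set, which any-overlap assignment does not. Summit co-location between
two peak sets reports the fraction of A summits within a window of any
B summit; the null repositions A's summits uniformly on their own
chromosomes `n_random` times, and the empirical p-value is
`(1 + #null ≥ observed) / (n_random + 1)`.

## Origin collision analysis

An origin window is intergenic iff it overlaps no TU span on either
strand. Pol II signal per window is the strand-summed, normalised
mNET-seq signal per condition; windows positive in at least one
condition enter the fold analysis. Induction: depleted/control ≥ fold
(default 2, boundary inclusive); zero-control windows use a
pseudo-count of half the smallest positive control signal in the set,
mirroring the quantification imputation. Distances to PROMPTs/eRNAs
are edge-to-edge.

"Extended lncRNA" is operationalised as signal: walking downstream
from the TSS in the transcription direction, a base extends the
interval while the normalised depleted signal is ≥ `min_signal`
(default 1 normalised unit) and exceeds the control, bridging gaps up
to `max_gap` (default 500 bp). Each lncRNA yields one interval
covering at least its annotated span. This is one of several possible
operational definitions (a fixed-distance rule is another); the
parameters are config-exposed and logged.

## Synthetic-data generator

The generator emulates the statistical structure of the experiment,
not sequence-level realism (no nucleotide content, mappability or
spliced alignments).

Layout: features are placed left-to-right with 6–18 kb random gaps,
round-robin over 3 × 2 Mb chromosomes. PROMPTs sit divergently 60 bp
upstream of coding TSSs; paired lincRNAs divergently at 500 bp; eRNAs,
snRNAs, histone and intronless genes are standalone. Replication
origins (1 kb) are planted intergenic (80% by default), a subset
inside lncRNA extension footprints, the rest inside gene bodies.

Expression: per-region relative rates, protein-coding genes dominating
the library (default 50 genes × 100 vs ~2% for all lncRNA classes
combined — as in real nascent libraries, where lncRNA is a small
fraction of Pol II signal). Read counts per library are multinomial at
the configured depth — Poisson rates conditioned on the total, because
a sequencer fixes the library total — so each library has exactly
`depth` pairs. Positions are uniform within regions, except
coding-gene 3' ends in the depleted condition, which decay
exponentially from the TSS (decay length 2 kb) to emulate the
elongation defect; the decay redistributes signal without changing
gene totals by default.

Condition structure: PROMPTs/eRNAs 4× induced and lincRNAs 2× induced
on depletion by default (folds assignable per region, cyclically, for
multi-fold designs). Half of the PROMPTs/eRNAs acquire a 20-kb
termination-defect extension transcribed only in the depleted
condition at 0.3× the body density (readthrough polymerase density is
lower than the gene body's). Chromatin:nucleoplasm retention ratio r
partitions a region's rate as r/(1+r) vs 1/(1+r); default r = 2 for
lncRNA classes, 1 elsewhere. IP libraries sample a uniform genomic
background plus per-region extra mass length × (fold − 1), default
H3K36me3 folds 8× on coding in control redistributing to 2× coding /
4× lncRNA on depletion. R-loop peaks are planted with exact per-category
counts at construction-verified positions; damage peaks are planted at
80% of R-loop summits (jitter ≤ 100 bp) plus one quarter as many
background peaks, so 80% of damage peaks co-locate.

Because library composition shifts when classes are induced,
library-size normalisation carries a real bias of
log2(W_ctrl/W_depleted) (W = total rate). With defaults this is
≈ −0.05 without extensions and ≈ −0.2 with them — a faithful property
of depth-normalised designs, visible in the flat classes of any run.
Recovery tests for planted folds therefore run extension-free configs.

## Problem sizes and statistical design

Depths were chosen by power analysis before running the recovery
tests: fold recovery uses 600k pairs/condition (≈ 200–400 reads per
induced region; sem of the per-fold mean log2 ratio ≈ 0.03, against a
±0.2 acceptance band and ≈ 0.05 composition bias); CRI uses 400k
pairs/fraction (≈ 180 fragments per PROMPT window; median sem ≈ 0.04
against bands of ±0.2 and ±0.1); origin induction uses ≈ 22 reads per
window in control (miss probability per induced origin ≈ 0.2%, false
positive ≈ 1% per flat origin, comfortably inside the ≥38/40 and ≤2/60
bounds). Category and co-location fractions are planted as exact
counts, so their recovery error is the categorisation itself, not
sampling.

## What passing tests do and do not show

Synthetic recovery demonstrates that the formulas, windows, filters
and flags are implemented correctly and that the pipeline is
deterministic and mass-conserving. It does not demonstrate robustness
to alignment artefacts, mappability gaps, PCR duplication structure,
overlapping gene models, or annotation errors — none of which the
generator emulates. Counts from published annotations (gene-set sizes,
origin tallies) depend on external data and are out of scope here.

## Known limitations

* Dense track storage bounds practical genome size to ~100 Mb per
  process; a chunked or sparse backend would be needed beyond that.
* Read-pair emission is pure Python; libraries beyond ~5M pairs are
  slow. The simulators are vectorised per region but pair objects are
  constructed individually.
* `categorize_peaks` and the layout planner are O(peaks × genes) per
  chromosome — fine at desk scale, quadratic in principle.
* The extended-lncRNA definition is signal-thresholded and therefore
  depth-dependent; at very low depth extensions fragment into gaps
  longer than `max_gap` and are truncated.
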