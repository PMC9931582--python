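# Methods

## Problem setting

Open-fluidics, mostly-natural sequencing-by-synthesis (mnSBS) instruments
produce single-end reads. A droplet scRNA-seq library read therefore
carries every construct element in one sequence: 16-base cell barcode
(CBC), UMI (12 bases for 3' v3.1 chemistry, 10 for 5'), an anchor — the
poly(T) run from the mRNA poly(A) tail (3') or the 13-base template-switch
oligo (5') — and the cDNA insert. Standard droplet pre-processors expect
paired-end input. The core of this package converts single-end reads into
simulated pairs (R1 = CBC+UMI, R2 = antisense cDNA) and provides the
surrounding analyses used to compare such data against conventional
paired-end data at matched depth.

## Read restructuring

Stage order: quality trim, anchor, split/clip/mask, length filter, 90-base
cap.

1. **3' quality trimming.** For cut point `i`, the partial sum
   `S_i = Σ_{j≥i}(q_j − T)` is computed from the 3' end with threshold
   `T = 30`; the read is cut at the `i` minimising `S_i`, and left intact
   when the minimum is non-negative. Among tied minima the longest prefix
   is kept (the tie-break is a convention of this implementation; the
   exhaustive-enumeration oracle in the tests uses the same rule).
2. **Anchor detection** at the *fixed* offset `cbc_len + umi_len`. The
   construct places the anchor immediately after the UMI, so no scanning is
   performed — scanning would admit chimeric molecules. Poly(T) requires at
   least 8 consecutive Ts and the span runs to the end of the maximal
   contiguous T run (matched exactly; homopolymer-length noise is absorbed
   by the post-anchor clip). The TSO is matched with a Hamming budget of 2
   mismatches (configurable; no tolerance is canonical for this step).
3. **Split, clip, mask.** R1 is the first `cbc_len + umi_len` bases. For
   3' chemistry the last 3 UMI bases — the positions adjacent to the
   poly(T), where base quality drops — are replaced by `A` at quality 40
   (substitution rather than deletion keeps R1 length fixed for downstream
   tools; a hard-trim mode exists). The cDNA starts 5 bases (3') or 3
   bases (5') after the anchor end.
4. **Length rules.** cDNA shorter than 50 bases → discard; otherwise the
   *anchor-proximal* 90 bases are kept — these carry the highest base
   quality and preserve the 3'-proximal positional signature of the
   chemistry — and emitted as R2 in reverse complement with reversed
   qualities.

Discards are return values with explicit reasons (`too_short_after_trim`,
`no_anchor`, `short_cdna`); the conversion report counters always sum to
the input count.

## UMI diagnostics

Molecule tables are one row per unique (CBC, UMI, gene) with a read count.
Shortening a UMI to length `L` keeps its prefix (the degraded bases are
terminal). Collapse statistics count molecules absorbed within a gene and
(CBC, short-UMI) keys observed in more than one gene; multi-gene keys are
counted but not removed, since resolving them is the counting pipeline's
policy, not this package's. Trimmed/full count ratios are reported per
cell and per gene; 1.0 means trimming is lossless for that entity. The
UMI base-quality read filter removes pairs with any UMI base below Q10.

## Depth matching

Comparing platforms requires equal UMI totals. A molecule with `r` reads
survives read sampling at proportion `p` with probability `1−(1−p)^r`.
Rather than resampling reads at every candidate proportion, each molecule
draws one `min`-of-`r`-uniforms variate (`Beta(1, r)`) — the proportion at
which it first survives — so UMI counts are evaluated at any `p` by
counting draws below `p`. This couples all grid evaluations: survival is
exactly monotone in `p` and the two-step search (5% coarse grid, then 1%
steps over the next 5% window, choosing the largest proportion with fewer
UMIs than the target) brackets the target deterministically. If the full
table already has fewer UMIs than the target no sampling is performed
(`chosen_p = 1`). Split-half resampling partitions individual reads into
two uniform halves whose sizes differ by at most one and rebuilds a
molecule table per half.

## Gene models and bias analyses

Gene models are per-gene unions of exon intervals (0-based half-open
internally; GTF I/O converts at the boundary). Exonic offsets are
strand-aware cumulative exonic positions divided by collapsed length.
Read-end profiles use 101 bins labelled 0–100 (bin `b` covers
`[b/100,(b+1)/100)`, bin 100 holds exactly 1.0); the read 5' end
contributes the offset of its first base (range `[0,1)`), the 3' end
one-past-its-last-base (range `(0,1]`), so bin 100 is empty for 5' ends
and bin 0 for 3' ends by construction. Contributions are weighted
`1/reads-per-gene` so each gene carries unit mass; multimappers, reads
without CBC/UMI, and unassigned reads are excluded; intronic read ends
are skipped (offsets are block-aware).

Read categorisation emulates exon-overlap counting: any ≥1 bp overlap with
a strand-compatible gene's exons; exactly one gene → assigned, several →
ambiguous, none → no-feature; multimapping takes precedence over
ambiguity; per-gene modes additionally credit multimapping or ambiguous
reads to every overlapped gene. This is deliberately simpler than
transcript-compatibility counting and is documented as such.

The bias classifier takes depth-matched per-gene counts and assignment
rates (assigned / reads mapped within the gene body ±100 bp). Genes with
max count ≤ 100 are excluded. Normalised logFC is
`ln(c_a+1) − ln(c_b+1)` minus the median over included genes (the
normalisation is stated only as "by the median difference"; median
subtraction on the log scale is this package's reading). Count classes
use a 5-fold threshold. The assignment-rate class requires a >3-fold rate
ratio *and* a two-sided binomial test at α = 0.01 of one platform's
assigned count against the other platform's rate; both directional
p-values are reported. This one-sample form is exact when the reference
platform's rate is deep enough to be noise-free (the regime of the
unfiltered deep reference it emulates) and anti-conservative when both
platforms are equally shallow — the fold-ratio gate, not the p-value,
then controls the call.

Pseudobulk logFC sums counts per gene, scales to counts-per-million, and
takes `ln(tpm_a+10) − ln(tpm_b+10)`; the differential flag is a strict
`|logFC| > ln 2` (boundary values within float tolerance are not flagged).
All logs are natural.

## Annotation extension

Reads that overlap a gene's exons but spill past its boundaries are
evidence of unannotated transcribed sequence. Uniquely assigned reads
without large gaps (>10 N bases) become stranded intervals tagged with
their gene — *all* assigned reads, not only overflowing ones; interior
envelopes duplicate existing exons harmlessly. Intervals are single-linkage
clustered (same chromosome and strand, ≥1 shared base; book-ended
half-open intervals do **not** cluster, a documented divergence risk from
interval tools that merge abutting features). Each (cluster, gene) group
yields one envelope exon, appended to the GTF with transcript id
`<gene_id>.ext.<n>`; original records are preserved byte-verbatim and the
output is coordinate-sorted.

## Guide-effect estimation (Perturb-Seq)

Cells with exactly one guide and one hash label are retained; guides with
10 or fewer cells are dropped with their cells; genes must be expressed in
>5% of retained cells. The design matrix is the z-scored per-cell UMI
count plus complete one-hot blocks for guide, hash and cluster labels (no
reference coding — the ridge component of the elastic net handles the
collinearity; the intercept is unpenalised and absorbs baseline
expression). Per-gene elastic nets use `l1_ratio = 0.5`,
`alpha = 5e-4`, `max_iter = 10000` (solver: scikit-learn coordinate
descent).

The permutation null shuffles guide labels *within each hash stratum*,
which preserves the guide × hash contingency margins of every permutation
exactly. Each gene is scored by its maximum absolute coefficient over
targeting-guide columns (named control guides excluded); genes are ranked
by mean expression into 20 equal-size bins, and the empirical p-value
compares the observed score to all null scores in the gene's bin across
all permutations with the add-one convention
`p = (1 + #{null ≥ obs}) / (1 + N_bin)`, so `p > 0` always. Guide
similarity is the Pearson correlation between guide coefficient vectors
over genes with `p < 0.05`; zero-variance columns yield missing entries.

## Gene-program transfer (NMF)

Expression is logTPM: `ln(1 + 10⁶·count/total)` per cell, pseudocount 1,
natural log; genes expressed in >1% of cells pass the filter. NMF
(`K = 15` by default, seeded random initialisation, coordinate descent)
gives non-negative cell loadings (cells × K) and gene loadings
(genes × K). Projection fixes one loading matrix and solves the other by
per-row non-negative least squares.

Transfer evaluation splits each dataset into a 5,000-cell training set
(scaled down in the test fixtures) and a held-out test set, fits models on
each training set and on a within-gene-permuted copy (each gene's values
scrambled across cells, destroying covariance while keeping marginals),
and measures the MSE of reconstructing a dataset with gene loadings fixed:
on the training matrix for gene-loading quality, on the test matrix for
cell-loading quality; self (own model), cross (other dataset's model) and
null (permuted model) are compared over 10 repeats with different seeds.
Identical inputs use coupled per-repeat splits, so self and cross coincide
exactly in that degenerate case.

Consensus NMF pools gene-loading vectors from 100 seeded restarts,
L2-normalises them, clusters with k-means into K groups, drops factors
whose distance to their centroid exceeds the 0.9 quantile, takes
component-wise medians per cluster, and refits cell loadings by
projection. The clustering method and outlier quantile are this package's
choices (exposed as configuration); the aggregation outline follows the
consensus-factorisation idea of pooling restarts, run here on logTPM with
an externally supplied variable-gene list.

## Synthetic fixtures

Every consumer is testable without external data:

- **Reads**: CBC+UMI+anchor+cDNA with jittered poly(T) lengths (10–16),
  optional substitution errors, and a quality profile with a fixed-depth
  drop over configurable windows flanking the anchor — a simple model of
  the poly(T)-adjacent quality loss (depth/width constants, not a
  flow-cycle error model). Planted defect fractions (7-T anchors,
  short cDNA) with per-read expected outcomes.
- **Genomes**: random contigs, multi-exon genes on both strands, a stated
  fraction of same-strand overlapping gene pairs to exercise ambiguity.
- **Alignments**: exon-interior reads plus planted boundary-overflow reads
  whose envelope is known in closed form, and stated fractions of gapped
  and multimapping reads.
- **Molecule tables**: uniform UMIs, constant or geometric read depth.
- **Perturb expression**: logTPM = baseline + planted guide effects
  (±magnitude on a random gene subset; optional guides sharing effect
  rows) + hash effects + Gaussian noise, clipped at 0. Default conditions
  for recovery checks: effect 1.0 vs noise sd 0.3 (3.3× noise), ≥30 cells
  per guide.
- **Programs**: two Poisson count matrices sharing gene loadings W*, with
  independent per-dataset activities and a per-dataset log-normal per-gene
  capture bias (sd 0.1) emulating platform-specific biases — this gives
  each dataset's own model a systematic (small) advantage, the regime the
  transfer comparison is about. A `separated` mode plants disjoint
  near-constant gene modules and single-program-dominated cells, the
  well-separated regime in which consensus factorisation can recover the
  truth through the log transform.

What the fixtures do *not* model: real flow-cycle error processes and
homopolymer miscalls, barcode whitelists and error correction, transcript
isoform structure, ambient RNA, doublets. Passing tests therefore
demonstrate the correctness and calibration of the *procedures*, not
end-to-end performance on real sequencing data.

## Numerical and scale choices

- Problem sizes in tests and in `scripts/acceptance.py` are desk-scale
  choices: 10⁵ reads for round trips, 10⁴ molecules/reads for oracle
  comparisons, 2000 genes × 100 permutations for p-value calibration,
  700 × 200 (train 500) for transfer, K = 10 at 400 × 150 with 100
  restarts for consensus.
- All randomness flows through `numpy.random.default_rng` with explicit
  seeds; CLI commands with a fixed seed emit byte-identical outputs.
- Phred+33 encoding is assumed for FASTQ I/O; qualities are capped at 93.
- Degenerate inputs: empty reads trim to empty; zero-total cells are
  rejected by logTPM with the offending cell names; zero-variance guide
  columns and constant factors propagate as missing correlations rather
  than errors.

## Known limitations

- Assignment emulation is exon-overlap based; it will differ from
  transcript-aware counters near overlapping transcripts.
- The depth-matching thinning is per-molecule binomial, an approximation
  to global without-replacement read sampling that is excellent at large
  read totals but not an emulation of any specific sampler's bitstream.
- The one-sample binomial form of the assignment-bias test is
  anti-conservative for two equally shallow platforms (see above).
- Consensus-NMF recovery of planted programs degrades when programs
  overlap densely or counts are shallow; the log transform compresses
  loading magnitudes, which caps attainable loading correlations.
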