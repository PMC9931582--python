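# mnsbs

Tools for running droplet scRNA-seq on single-end reads from open-fluidics,
mostly-natural sequencing-by-synthesis (mnSBS) instruments — and for the
downstream comparisons such data requires.

A single-end mnSBS read carries the whole droplet construct in one
sequence: cell barcode (CBC, 16 bases), UMI (12 bases for 3' v3.1
chemistry, 10 for 5'), an anchor — a poly(T) run (3') or the
template-switch oligo (5') — and the cDNA insert. Standard droplet
pre-processors expect paired-end input, so the core operation here
restructures each read into a *simulated pair*: R1 = CBC+UMI (with the
quality-degraded terminal UMI bases masked to `A` at Q40 in 3' chemistry),
R2 = the reverse complement of the cDNA after quality trimming at Q30,
anchor detection (≥8 Ts, or the TSO within 2 mismatches), a 5-base (3') or
3-base (5') post-anchor clip, a <50-base discard rule, and a 90-base cap.

Around this conversion the package implements the analyses needed to
compare platforms on equal footing:

- **UMI diagnostics** — collision/merge statistics when UMIs are shortened,
  per-cell and per-gene trimmed/full count ratios, UMI base-quality
  filtering.
- **Depth matching** — coupled-seed molecule-table thinning and the
  two-step (5% coarse / 1% refined) search for the sampling proportion
  matching a target UMI total; disjoint split-half resampling.
- **Gene-model bias** — collapsed-exon gene models, length/GC, positional
  profiles of read ends along the gene body, featureCounts-style read
  categorisation, assignment rates over the gene body ±100 bp, a
  count/assignment-rate bias classifier, and pseudobulk logFC
  (`ln(TPM+10)` differences, DE at `|logFC| > ln 2`).
- **Annotation extension** — new exon records inferred from uniquely
  assigned reads that overflow annotated gene boundaries (stranded
  single-linkage clustering, per-(cluster, gene) envelopes), appended to
  the GTF with original records preserved verbatim.
- **Perturb-Seq guide effects** — per-gene elastic nets
  (`l1_ratio=0.5, alpha=5e-4`) on scaled-UMI + one-hot guide/hash/cluster
  covariates, a margin-preserving permutation null (guides shuffled within
  hash strata, 100 permutations), expression-binned empirical p-values
  (20 bins), and guide-similarity matrices.
- **NMF program transfer** — logTPM normalisation, seeded NMF (K=15),
  NNLS projection, cross-dataset transfer MSE against a within-gene
  permuted null over 10 repeats, and consensus NMF over 100 restarts.
- **Synthetic fixtures** — deterministic generators for every input above,
  with machine-readable planted truth (including the mnSBS-specific
  quality drop flanking the poly(T)).

See `docs/methods.md` for the models, conventions and limitations.

## Worked example

```python
from mnsbs import THREE_PRIME
from mnsbs.simulate import simulate_reads, simulate_molecule_table
from mnsbs.restructure import convert_stream
from mnsbs.umi import collapse_table
from mnsbs.depth import match_depth

reads, truth = simulate_reads(THREE_PRIME, n_reads=10_000, seed=7,
                              frac_no_anchor=0.05, frac_short_cdna=0.05)
pairs, report = convert_stream(reads, THREE_PRIME)
print(report.to_dict())
```

```
{'n_input': 10000, 'n_too_short_after_trim': 0, 'n_no_anchor': 496,
 'n_short_cdna': 506, 'n_emitted': 8998}
```

Reads with a defective anchor (the planted 5% with only 7 Ts) or a
post-clip cDNA under 50 bases are discarded with explicit reasons; the
counters always sum to the input. The first emitted pair:

```python
pairs[0].r1.bases   # 'GGCGAGTTCCGCGAAAACTTGTCAAAAA'  (16-base CBC + 12-base UMI,
                    #  last 3 bases masked to 'A' at Q40)
pairs[0].r2.bases   # 'GTCGAGTGGGGTGTCGACAATTCGGCAT...' (90-base antisense cDNA)
```

UMI shortening and depth matching on a simulated molecule table:

```python
table = simulate_molecule_table(n_cells=8, n_genes=40,
                                molecules_per_cell=500, seed=5)
_, stats9 = collapse_table(table, 9)      # shorten 12-base UMIs to 9
# n_in=4000, n_out=4000, n_merged_within_gene=0, n_multi_gene_keys=3

res = match_depth(table, target_umis=2500, seed=100)
res.chosen_p                               # 0.37
res.umis_at(res.chosen_p)                  # 2497  (< 2500 <= UMIs at 0.38)
```

At 4000 molecules with random 12-mer UMIs, 9-base prefixes almost never
collide within a cell (3 multi-gene keys); the depth search returns the
largest sampling proportion whose UMI count stays below the target, and
the next 1% step crosses it.

The same operations are available from the shell:

```sh
mnsbs simulate reads --seed 7 --out-dir fixtures --n 10000
mnsbs convert --chem 3p --in fixtures/reads.fastq \
      --out-r1 R1.fastq --out-r2 R2.fastq --report report.json
mnsbs umi-stats --table mol.tsv --lens 12,11,10,9,8
mnsbs match-depth --table mol.tsv --target 2500 --seed 100
mnsbs extend-ref --gtf in.gtf --alignments aln.tsv --out extended.gtf
mnsbs perturb-fit --expr expr.tsv --meta meta.tsv --n-perm 100 --seed 1 \
      --out-effects effects.tsv --out-pvals pvals.tsv --out-sim sim.tsv
```

All commands are deterministic for a fixed seed.

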