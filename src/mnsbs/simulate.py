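"""Synthetic data generators with machine-readable ground truth.

Every input consumed elsewhere in the package can be generated here:
single-end reads with planted CBC/UMI/anchor/cDNA structure and the
characteristic quality drop flanking the poly(T) run, genomes with GTF
annotations, aligned-read tables (including planted boundary-overflow,
gapped and multimapping reads), molecule tables, Perturb-Seq expression
with planted guide effects, and paired count matrices sharing ground-truth
gene programs.  All generators are deterministic under a fixed seed and
return truth tables sufficient to verify the consuming module.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chemistry import (
    AnchorKind,
    ChemistryProfile,
    PhredRead,
    reverse_complement,
)
from .genemodel import AlignedRead, GeneModel

BASES = np.array(list("ACGT"))


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASE_BYTES[rng.integers(0, 4, size=n)].tobytes().decode()


# ---------------------------------------------------------------------------
# genome + annotation

def simulate_genome(
    n_genes: int,
    exons_per_gene: int = 3,
    overlap_fraction: float = 0.0,
    seed: int = 0,
    exon_len: Tuple[int, int] = (150, 400),
    intron_len: Tuple[int, int] = (50, 200),
    spacer: int = 500,
    genes_per_contig: int = 25,
) -> Tuple[Dict[str, str], List[str], List[GeneModel]]:
    """Random contigs with multi-exon genes on both strands.

    A fraction ``overlap_fraction`` of genes is planted overlapping the 3'
    end of the previous gene on the same strand, to exercise ambiguous
    assignment.  Returns (genome dict, GTF lines, collapsed GeneModels).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    genome: Dict[str, str] = {}
    gtf: List[str] = []
    models: List[GeneModel] = []

    contig_idx = 0
    pos = spacer
    contig_name = f"chr{contig_idx + 1}"
    contig_parts: List[Tuple[int, int]] = []  # gene spans for sizing
    prev: Optional[GeneModel] = None

    for gi in range(n_genes):
        if gi and gi % genes_per_contig == 0:
            contig_idx += 1
            contig_name = f"chr{contig_idx + 1}"
            pos = spacer
            prev = None
        gene_id = f"G{gi+1:04d}"
        overlap = prev is not None and rng.random() < overlap_fraction
        if overlap:
            strand = prev.strand
            start = prev.exons[-1][0] + max(
                1, (prev.exons[-1][1] - prev.exons[-1][0]) // 2
            )
        else:
            strand = "+" if rng.random() < 0.5 else "-"
            start = pos
        exons = []
        cur = start
        for _ in range(exons_per_gene):
            el = int(rng.integers(*exon_len))
            exons.append((cur, cur + el))
            cur += el + int(rng.integers(*intron_len))
        model = GeneModel(
            gene_id=gene_id, chrom=contig_name, strand=strand,
            exons=exons, gene_name=gene_id,
        )
        models.append(model)
        prev = model
        pos = max(pos, exons[-1][1]) + spacer

        tid = f"{gene_id}.t1"
        span = (exons[0][0] + 1, exons[-1][1])
        attrs = f'gene_id "{gene_id}"; gene_name "{gene_id}";'
        gtf.append(
            f"{contig_name}\tsim\tgene\t{span[0]}\t{span[1]}\t.\t{strand}\t.\t{attrs}"
        )
        tattrs = f'gene_id "{gene_id}"; transcript_id "{tid}"; gene_name "{gene_id}";'
        gtf.append(
            f"{contig_name}\tsim\ttranscript\t{span[0]}\t{span[1]}\t.\t{strand}\t.\t{tattrs}"
        )
        for s, e in exons:
            gtf.append(
                f"{contig_name}\tsim\texon\t{s+1}\t{e}\t.\t{strand}\t.\t{tattrs}"
            )

    # materialise contigs long enough for every gene plus trailing spacer
    ends: Dict[str, int] = {}
    for m in models:
        ends[m.chrom] = max(ends.get(m.chrom, 0), m.end + spacer)
    for name, ln in ends.items():
        genome[name] = _random_seq(rng, ln)
    return genome, gtf, models


# ---------------------------------------------------------------------------
# reads

@dataclass
class QualityProfile:
    """Per-cycle baseline quality with a drop flanking the poly(T) anchor."""

    baseline_q: int = 37
    flank_width: int = 0
    flank_depth: int = 0

    def build(
        self, read_len: int, anchor_span: Optional[Tuple[int, int]]
    ) -> List[int]:
        q = [self.baseline_q] * read_len
        if anchor_span is not None and self.flank_width > 0:
            s, e = anchor_span
            for i in range(max(0, s - self.flank_width), s):
                q[i] = max(0, q[i] - self.flank_depth)
            for i in range(e, min(read_len, e + self.flank_width)):
                q[i] = max(0, q[i] - self.flank_depth)
        return q


def simulate_reads(
    chem: ChemistryProfile,
    n_reads: int = 1000,
    seed: int = 0,
    quality_profile: Optional[QualityProfile] = None,
    error_rate: float = 0.0,
    cdna_len: Tuple[int, int] = (80, 140),
    poly_t_len: Tuple[int, int] = (10, 16),
    frac_no_anchor: float = 0.0,
    frac_short_cdna: float = 0.0,
    n_cells: int = 32,
) -> Tuple[List[PhredRead], pd.DataFrame]:
    """Reads with planted CBC+UMI+anchor+cDNA structure and a truth table.

    ``frac_no_anchor`` reads carry a defective anchor (poly(T) one base
    below threshold, or a heavily mutated TSO); ``frac_short_cdna`` reads
    carry a cDNA that falls below the minimum after the post-anchor clip.
    The truth table records, per read, the planted CBC, UMI, cDNA segment
    expected in R2 (after clip and 90-base cap, as it appears in the read),
    and the expected conversion outcome.
    """
    if quality_profile is None:
        quality_profile = QualityProfile()
    rng = np.random.default_rng(seed)
    cbcs = [_random_seq(rng, chem.cbc_len) for _ in range(n_cells)]
    reads: List[PhredRead] = []
    truth_rows = []
    for i in range(n_reads):
        rid = f"read{i:06d}"
        cbc = cbcs[int(rng.integers(len(cbcs)))]
        umi = _random_seq(rng, chem.umi_len)
        u = rng.random()
        if u < frac_no_anchor:
            outcome = "no_anchor"
        elif u < frac_no_anchor + frac_short_cdna:
            outcome = "short_cdna"
        else:
            outcome = "emitted"

        if chem.anchor_kind is AnchorKind.POLY_T:
            if outcome == "no_anchor":
                t_run = chem.anchor_min_t - 1
            else:
                t_run = int(rng.integers(*poly_t_len))
            # followed by a non-T base via cDNA below
            anchor = "T" * t_run
        else:
            if outcome == "no_anchor":
                tso = list(chem.tso_seq)
                pos = rng.choice(len(tso), size=chem.tso_max_mismatch + 1,
                                 replace=False)
                for p in pos:
                    tso[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tso[p]]
                anchor = "".join(tso)
            else:
                anchor = chem.tso_seq
            t_run = len(anchor)

        if outcome == "short_cdna":
            clen = chem.clip_after_anchor + chem.min_cdna_len - 1
        else:
            clen = int(rng.integers(*cdna_len))
        cdna = _random_seq(rng, clen)
        if cdna and chem.anchor_kind is AnchorKind.POLY_T and cdna[0] == "T":
            cdna = "A" + cdna[1:]  # keep the anchor run length exact

        bases = cbc + umi + anchor + cdna
        anchor_span = (chem.prefix_len, chem.prefix_len + t_run)
        quals = quality_profile.build(len(bases), anchor_span)
        if error_rate > 0:
            errs = np.flatnonzero(rng.random(len(bases)) < error_rate)
            blist = list(bases)
            for p in errs:
                blist[p] = {"A": "C", "C": "G", "G": "T", "T": "A", "N": "A"}[
                    blist[p]
                ]
            bases = "".join(blist)
        else:
            errs = np.array([], dtype=int)

        clip_start = chem.clip_after_anchor
        kept = cdna[clip_start : clip_start + chem.max_cdna_len]
        truth_rows.append(
            {
                "read_id": rid,
                "cbc": cbc,
                "umi": umi,
                "anchor_kind": chem.anchor_kind.value,
                "anchor_len": t_run,
                "cdna_kept": kept if outcome == "emitted" else "",
                "expected_outcome": outcome,
                "n_errors": len(errs),
            }
        )
        reads.append(PhredRead(rid, bases, quals))
    return reads, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# alignments

def simulate_alignments(
    models: Sequence[GeneModel],
    reads_per_gene: int = 20,
    read_len: int = 90,
    end_extension: int = 0,
    extend_fraction: float = 0.0,
    n_extend_reads: int = 3,
    gap_fraction: float = 0.0,
    multimap_fraction: float = 0.0,
    seed: int = 0,
) -> Tuple[List[AlignedRead], pd.DataFrame]:
    """Reads placed inside collapsed exons, plus planted special cases.

    For a fraction ``extend_fraction`` of genes, ``n_extend_reads`` extra
    reads start inside the 3'-most exon and extend ``end_extension`` bases
    past the annotated gene end; their envelope per gene is recorded in the
    truth table.  Fractions of interior reads carry >10-base N gaps or
    multiple hits.  Interior reads are placed within single exons.
    """
    rng = np.random.default_rng(seed)
    reads: List[AlignedRead] = []
    truth_rows = []
    rid = 0
    for m in models:
        sense_strand = m.strand
        extend = end_extension > 0 and rng.random() < extend_fraction
        for _ in range(reads_per_gene):
            exon_i = int(rng.integers(len(m.exons)))
            s, e = m.exons[exon_i]
            max_start = e - read_len
            if max_start <= s:
                continue
            start = int(rng.integers(s, max_start))
            gap = rng.random() < gap_fraction
            multi = rng.random() < multimap_fraction
            reads.append(
                AlignedRead(
                    id=f"aln{rid:06d}",
                    chrom=m.chrom,
                    strand=sense_strand,
                    blocks=[(start, start + read_len)],
                    gap_n_total=100 if gap else 0,
                    n_hits=3 if multi else 1,
                    assigned_gene=m.gene_id,
                )
            )
            truth_rows.append(
                {"read_id": f"aln{rid:06d}", "gene": m.gene_id,
                 "kind": "gap" if gap else "multi" if multi else "interior",
                 "env_start": -1, "env_end": -1}
            )
            rid += 1
        if extend:
            # overhang reads anchored 50 bp inside the gene's 3'-most exon
            # and extending exactly end_extension past the annotated gene
            # end; all planted reads share the span, so their envelope is
            # known in closed form
            overlap_in = 50
            if m.strand == "+":
                e = m.exons[-1][1]
                span = (e - overlap_in, e + end_extension)
            else:
                s = m.exons[0][0]
                span = (max(0, s - end_extension), s + overlap_in)
            for _ in range(n_extend_reads):
                reads.append(
                    AlignedRead(
                        id=f"aln{rid:06d}", chrom=m.chrom, strand=sense_strand,
                        blocks=[span], assigned_gene=m.gene_id,
                    )
                )
                rid += 1
            truth_rows.append(
                {"read_id": "", "gene": m.gene_id, "kind": "extension",
                 "env_start": span[0], "env_end": span[1]}
            )
    return reads, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# molecule tables

def simulate_molecule_table(
    n_cells: int = 10,
    n_genes: int = 50,
    molecules_per_cell: int = 100,
    umi_len: int = 12,
    depth_law: str = "geometric",
    mean_reads: float = 3.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Molecule table with uniform random UMIs and a read-depth law.

    ``depth_law``: 'const1' (every molecule one read) or 'geometric'
    (Geometric with mean ``mean_reads``).  Duplicate (cbc, umi, gene) draws
    are dropped, so row counts can fall slightly below the nominal total.
    """
    if umi_len < 1:
        raise ValueError("umi_len must be >= 1")
    rng = np.random.default_rng(seed)
    cbcs = [_random_seq(rng, 16) for _ in range(n_cells)]
    genes = [f"G{j+1:04d}" for j in range(n_genes)]
    n = n_cells * molecules_per_cell
    rows = {
        "cbc": rng.choice(cbcs, size=n),
        "umi": [
            row.tobytes().decode()
            for row in _BASE_BYTES[rng.integers(0, 4, size=(n, umi_len))]
        ],
        "gene": rng.choice(genes, size=n),
    }
    if depth_law == "const1":
        reads = np.ones(n, dtype=int)
    elif depth_law == "geometric":
        reads = rng.geometric(1.0 / mean_reads, size=n)
    else:
        raise ValueError(f"unknown depth_law {depth_law!r}")
    df = pd.DataFrame({**rows, "reads": reads})
    df = df.drop_duplicates(subset=["cbc", "umi", "gene"]).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# perturbation fixtures

@dataclass
class PerturbTruth:
    effects: pd.DataFrame  # guides x genes
    hash_effects: pd.DataFrame  # hashes x genes
    noise_sd: float
    affected_genes: Dict[str, List[str]]


def simulate_perturb(
    n_cells: int = 400,
    n_genes: int = 100,
    n_guides: int = 8,
    n_hashes: int = 4,
    n_clusters: int = 3,
    effect_magnitude: float = 1.0,
    noise_sd: float = 0.3,
    frac_affected: float = 0.1,
    shared_pairs: int = 0,
    control_guides: Sequence[str] = (),
    frac_multi: float = 0.0,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, PerturbTruth]:
    """logTPM expression with planted additive guide effects.

    Expression = gene baseline + guide effect + hash effect + noise,
    clipped at zero.  Each non-control guide perturbs a random
    ``frac_affected`` subset of genes by +/- ``effect_magnitude``; the
    first ``shared_pairs`` pairs of targeting guides share their effect
    rows exactly (for similarity checks).  ``frac_multi`` cells are given a
    'multiple' guide label to exercise filtering.  Control guides get zero
    effect rows.
    """
    if n_cells < n_guides * 11:
        raise ValueError("need at least 11 cells per guide on average")
    rng = np.random.default_rng(seed)
    genes = [f"gene{j+1:04d}" for j in range(n_genes)]
    guides = [f"guide{g+1:02d}" for g in range(n_guides)] + list(control_guides)
    hashes = [f"hash{h+1}" for h in range(n_hashes)]
    clusters = [f"c{c}" for c in range(n_clusters)]

    B = pd.DataFrame(0.0, index=guides, columns=genes)
    affected: Dict[str, List[str]] = {}
    targeting = [g for g in guides if g not in set(control_guides)]
    n_aff = max(1, int(frac_affected * n_genes))
    for g in targeting:
        sel = list(rng.choice(genes, size=n_aff, replace=False))
        signs = rng.choice([-1.0, 1.0], size=n_aff)
        B.loc[g, sel] = signs * effect_magnitude
        affected[g] = sel
    for p in range(shared_pairs):
        a, b = targeting[2 * p], targeting[2 * p + 1]
        B.loc[b] = B.loc[a].to_numpy()
        affected[b] = affected[a]

    Hfx = pd.DataFrame(
        rng.normal(0, 0.2, size=(n_hashes, n_genes)), index=hashes, columns=genes
    )
    baseline = rng.uniform(1.0, 5.0, size=n_genes)

    cell_guide = rng.choice(guides, size=n_cells)
    cell_hash = rng.choice(hashes, size=n_cells)
    cell_cluster = rng.choice(clusters, size=n_cells)
    n_umis = rng.integers(2000, 20000, size=n_cells)

    expr = (
        baseline[None, :]
        + B.loc[cell_guide].to_numpy()
        + Hfx.loc[cell_hash].to_numpy()
        + rng.normal(0, noise_sd, size=(n_cells, n_genes))
    )
    np.clip(expr, 0, None, out=expr)
    cells = [f"cell{i+1:05d}" for i in range(n_cells)]
    expr_df = pd.DataFrame(expr, index=cells, columns=genes)

    labels = cell_guide.astype(object)
    if frac_multi > 0:
        multi = rng.random(n_cells) < frac_multi
        labels[multi] = "multiple"
    meta = pd.DataFrame(
        {"guide": labels, "hash": cell_hash, "cluster": cell_cluster,
         "n_umis": n_umis},
        index=cells,
    )
    truth = PerturbTruth(
        effects=B, hash_effects=Hfx, noise_sd=noise_sd, affected_genes=affected
    )
    return expr_df, meta, truth


# ---------------------------------------------------------------------------
# program fixtures

@dataclass
class ProgramTruth:
    W: pd.DataFrame  # genes x K
    H_a: pd.DataFrame  # cells x K
    H_b: pd.DataFrame
    scale: float


def simulate_programs(
    K: int = 15,
    n_cells: int = 600,
    n_genes: int = 200,
    scale: float = 20.0,
    sparsity: float = 0.8,
    mode: str = "dense",
    platform_sigma: float = 0.1,
    seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, ProgramTruth]:
    """Two Poisson count matrices sharing ground-truth gene programs.

    W* (genes x K) is non-negative and shared; cell activities H* are drawn
    independently per dataset; counts ~ Poisson(scale * H* W_d^T / mean)
    where W_d multiplies W* by a dataset-specific log-normal per-gene
    factor (sd ``platform_sigma``), emulating platform-specific gene
    capture biases: each dataset's own model fits it slightly better than
    the other dataset's, while the shared programs keep transfer close.
    ``mode='dense'`` draws sparse random gene loadings with overlapping
    supports; ``mode='separated'`` plants well-separated programs — disjoint
    gene modules and cells dominated by a single program — the regime in
    which consensus factorisation is expected to recover the truth.
    """
    if K > min(n_cells, n_genes):
        raise ValueError("K exceeds matrix dimensions")
    rng = np.random.default_rng(seed)
    if mode == "separated":
        # disjoint gene modules with near-constant loadings; deep counts
        scale = max(scale, 50.0)
        W = np.full((n_genes, K), 0.02)
        module = np.arange(n_genes) % K
        W[np.arange(n_genes), module] = rng.gamma(60.0, 8.0 / 60.0, size=n_genes)
    elif mode == "dense":
        W = rng.gamma(2.0, 1.0, size=(n_genes, K))
        W[rng.random((n_genes, K)) < sparsity] = 0.0
        # every gene participates in at least one program
        empty = W.sum(axis=1) == 0
        W[empty, rng.integers(0, K, size=int(empty.sum()))] = rng.gamma(
            2.0, 1.0, size=int(empty.sum())
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    genes = [f"gene{j+1:04d}" for j in range(n_genes)]
    out = []
    Hs = []
    for d in range(2):
        if mode == "separated":
            H = np.full((n_cells, K), 0.02)
            dom = rng.integers(0, K, size=n_cells)
            H[np.arange(n_cells), dom] = rng.gamma(30.0, 10.0 / 30.0, size=n_cells)
        else:
            H = rng.gamma(1.5, 1.0, size=(n_cells, K))
        gene_bias = np.exp(rng.normal(0.0, platform_sigma, size=n_genes))
        rate = (H @ W.T) * gene_bias[None, :]
        rate = scale * rate / rate.mean()
        counts = rng.poisson(rate)
        cells = [f"ds{d}_cell{i+1:05d}" for i in range(n_cells)]
        out.append(pd.DataFrame(counts, index=cells, columns=genes))
        Hs.append(
            pd.DataFrame(H, index=cells, columns=[f"factor_{i+1}" for i in range(K)])
        )
    truth = ProgramTruth(
        W=pd.DataFrame(W, index=genes, columns=[f"factor_{i+1}" for i in range(K)]),
        H_a=Hs[0],
        H_b=Hs[1],
        scale=scale,
    )
    return out[0], out[1], truth
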