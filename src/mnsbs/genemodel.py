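"""Collapsed-exon gene models and platform-bias analyses.

A gene model is the strand-aware union of a gene's exons ("collapsed"
exons): the basis for exonic length and GC content, for positional
profiles of read ends along the gene body, for exon-overlap read
categorisation (the featureCounts-style sense/antisense assignment), and
for the count/assignment-rate bias classifier comparing two platforms.

Coordinates are 0-based half-open internally; GTF I/O converts from the
1-based inclusive convention at the boundary.
"""
from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

__all__ = [
    "GeneModel",
    "AlignedRead",
    "PositionalProfile",
    "ReadCategoryCounts",
    "GeneBiasRecord",
    "parse_gtf",
    "collapse_exons",
    "gene_length_gc",
    "exonic_offset",
    "positional_profile",
    "categorize_reads",
    "assignment_rate",
    "gene_flank_counts",
    "classify_gene_bias",
    "pseudobulk_logfc",
    "read_alignment_tsv",
    "write_alignment_tsv",
    "read_alignments_sam",
]


# ---------------------------------------------------------------------------
# gene models

@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]  # sorted, disjoint, half-open
    gc: Optional[float] = None
    gene_name: Optional[str] = None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def parse_gtf_attributes(attr: str) -> Dict[str, str]:
    return dict(_ATTR_RE.findall(attr))


def parse_gtf(path) -> pd.DataFrame:
    """Read a GTF into a frame of exon records (0-based half-open).

    Returns columns gene_id, gene_name, chrom, strand, start, end plus the
    raw line, one row per exon feature.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ValueError(f"bad GTF line: {line!r}")
            if f[2] != "exon":
                continue
            attrs = parse_gtf_attributes(f[8])
            rows.append(
                (
                    attrs.get("gene_id", ""),
                    attrs.get("gene_name", attrs.get("gene_id", "")),
                    f[0],
                    f[6],
                    int(f[3]) - 1,
                    int(f[4]),
                )
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "gene_name", "chrom", "strand", "start", "end"]
    )


def _union(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[Tuple[int, int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def collapse_exons(entries: pd.DataFrame) -> List[GeneModel]:
    """Collapse overlapping exons of each gene into disjoint intervals.

    ``entries`` needs columns gene_id, chrom, strand, start, end (0-based
    half-open), e.g. from :func:`parse_gtf`.  Genes whose exons sit on
    multiple chromosomes or strands are skipped with a warning.  Idempotent.
    """
    models: List[GeneModel] = []
    for gene_id, grp in entries.groupby("gene_id", sort=True):
        if grp["chrom"].nunique() > 1 or grp["strand"].nunique() > 1:
            warnings.warn(
                f"gene {gene_id}: exons on multiple chromosomes/strands; skipped"
            )
            continue
        name = grp["gene_name"].iloc[0] if "gene_name" in grp else None
        models.append(
            GeneModel(
                gene_id=gene_id,
                chrom=grp["chrom"].iloc[0],
                strand=grp["strand"].iloc[0],
                exons=_union(zip(grp["start"], grp["end"])),
                gene_name=name,
            )
        )
    return models


def gene_length_gc(model: GeneModel, genome: Dict[str, str]) -> Tuple[int, float]:
    """Exonic length and GC fraction over the collapsed exonic sequence.

    GC = (G+C)/(A+C+G+T); ambiguous bases are excluded from the denominator.
    """
    contig = genome.get(model.chrom)
    if contig is None:
        raise KeyError(f"chromosome {model.chrom} absent from genome")
    gc = at = 0
    for s, e in model.exons:
        if e > len(contig):
            raise ValueError(
                f"gene {model.gene_id}: exon [{s},{e}) beyond contig end"
            )
        seq = contig[s:e].upper()
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    denom = gc + at
    return model.length, gc / denom if denom else float("nan")


def exonic_cum(model: GeneModel, genomic_pos: int) -> int:
    """Exonic bases preceding ``genomic_pos`` counted from the gene's 5' end.

    Strand-aware integer in [0, length).  Raises ValueError for intronic or
    outside positions (callers skip such read ends).
    """
    cum = 0
    for s, e in model.exons:
        if s <= genomic_pos < e:
            plus_cum = cum + (genomic_pos - s)
            if model.strand == "+":
                return plus_cum
            return model.length - 1 - plus_cum
        cum += e - s
    raise ValueError(
        f"position {genomic_pos} not exonic in gene {model.gene_id}"
    )


def exonic_offset(model: GeneModel, genomic_pos: int) -> float:
    """Fractional position along the collapsed exons from the gene's 5' end."""
    return exonic_cum(model, genomic_pos) / model.length


# ---------------------------------------------------------------------------
# aligned reads

@dataclass
class AlignedRead:
    id: str
    chrom: Optional[str]
    strand: str
    blocks: List[Tuple[int, int]]
    gap_n_total: int = 0
    n_hits: int = 1
    assigned_gene: Optional[str] = None
    has_cbc: bool = True
    has_umi: bool = True

    @property
    def mapped(self) -> bool:
        return self.chrom is not None and bool(self.blocks)

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


_ALN_COLS = [
    "id", "chrom", "strand", "blocks", "gap_n_total", "n_hits",
    "assigned_gene", "has_cbc", "has_umi",
]


def write_alignment_tsv(reads: Sequence[AlignedRead], path) -> None:
    """Write the plain-text alignment dialect (blocks as s-e;s-e)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_ALN_COLS) + "\n")
        for r in reads:
            blocks = ";".join(f"{s}-{e}" for s, e in r.blocks)
            fh.write(
                "\t".join(
                    [
                        r.id,
                        r.chrom or "*",
                        r.strand,
                        blocks or "*",
                        str(r.gap_n_total),
                        str(r.n_hits),
                        r.assigned_gene or "*",
                        "1" if r.has_cbc else "0",
                        "1" if r.has_umi else "0",
                    ]
                )
                + "\n"
            )


def read_alignment_tsv(path) -> List[AlignedRead]:
    reads = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _ALN_COLS:
            raise ValueError(f"unexpected alignment TSV header: {header}")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            blocks = (
                []
                if f[3] == "*"
                else [tuple(map(int, b.split("-"))) for b in f[3].split(";")]
            )
            reads.append(
                AlignedRead(
                    id=f[0],
                    chrom=None if f[1] == "*" else f[1],
                    strand=f[2],
                    blocks=blocks,
                    gap_n_total=int(f[4]),
                    n_hits=int(f[5]),
                    assigned_gene=None if f[6] == "*" else f[6],
                    has_cbc=f[7] == "1",
                    has_umi=f[8] == "1",
                )
            )
    return reads


def read_alignments_sam(path) -> List[AlignedRead]:
    """Load AlignedRead records from SAM/BAM via pysam.

    Uses NH for hit counts, CB/UB (or CR/UR) for barcode presence, GX/GN for
    gene assignment; N-gap total from the CIGAR.
    """
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                reads.append(
                    AlignedRead(aln.query_name, None, "+", [], 0, 1, None,
                                aln.has_tag("CB"), aln.has_tag("UB"))
                )
                continue
            gap_n = sum(l for op, l in (aln.cigartuples or []) if op == 3)
            gene = None
            for tag in ("GX", "GN"):
                if aln.has_tag(tag):
                    gene = aln.get_tag(tag)
                    break
            reads.append(
                AlignedRead(
                    id=aln.query_name,
                    chrom=aln.reference_name,
                    strand="-" if aln.is_reverse else "+",
                    blocks=[tuple(b) for b in aln.get_blocks()],
                    gap_n_total=gap_n,
                    n_hits=aln.get_tag("NH") if aln.has_tag("NH") else 1,
                    assigned_gene=gene,
                    has_cbc=aln.has_tag("CB") or aln.has_tag("CR"),
                    has_umi=aln.has_tag("UB") or aln.has_tag("UR"),
                )
            )
    return reads


# ---------------------------------------------------------------------------
# read categorisation

class GeneIndex:
    """Interval index of collapsed exons for overlap queries."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models: Dict[str, GeneModel] = {m.gene_id: m for m in models}
        self._trees: Dict[str, IntervalTree] = {}
        for m in models:
            tree = self._trees.setdefault(m.chrom, IntervalTree())
            for s, e in m.exons:
                tree.addi(s, e, m.gene_id)

    def overlapping_genes(self, read: AlignedRead, sense: str) -> List[str]:
        tree = self._trees.get(read.chrom)
        if tree is None:
            return []
        hits = set()
        for s, e in read.blocks:
            for iv in tree.overlap(s, e):
                hits.add(iv.data)
        out = []
        for g in hits:
            gs = self.models[g].strand
            if sense == "sense" and gs == read.strand:
                out.append(g)
            elif sense == "antisense" and gs != read.strand:
                out.append(g)
        return sorted(out)


@dataclass
class ReadCategoryCounts:
    assigned: int = 0
    no_feature: int = 0
    ambiguous: int = 0
    multimapping: int = 0
    unmapped: int = 0
    per_gene: Dict[str, int] = field(default_factory=dict)
    per_gene_multi: Dict[str, int] = field(default_factory=dict)
    per_gene_ambig: Dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return (self.assigned + self.no_feature + self.ambiguous
                + self.multimapping + self.unmapped)


def assign_read(
    read: AlignedRead, index: GeneIndex, sense: str
) -> Tuple[str, List[str]]:
    """Categorise one read; returns (category, overlapped compatible genes).

    Precedence: unmapped, then multimapping, then exon overlap — exactly one
    strand-compatible gene is 'assigned', two or more 'ambiguous', none
    'no_feature'.  Any >=1 bp overlap of any alignment block counts.
    """
    if not read.mapped:
        return "unmapped", []
    genes = index.overlapping_genes(read, sense)
    if read.n_hits > 1:
        return "multimapping", genes
    if len(genes) == 1:
        return "assigned", genes
    if len(genes) >= 2:
        return "ambiguous", genes
    return "no_feature", []


def categorize_reads(
    reads: Sequence[AlignedRead], models: Sequence[GeneModel], sense: str = "sense"
) -> ReadCategoryCounts:
    """Tally reads into assigned/no_feature/ambiguous/multimapping/unmapped.

    Per-gene tallies: ``per_gene`` counts uniquely assigned reads;
    ``per_gene_multi`` additionally credits multimapping reads to every
    overlapped gene (the count-multimappers mode); ``per_gene_ambig`` does
    the same for ambiguous reads (the count-ambiguous mode).
    """
    index = GeneIndex(models)
    out = ReadCategoryCounts()
    for g in index.models:
        out.per_gene[g] = 0
        out.per_gene_multi[g] = 0
        out.per_gene_ambig[g] = 0
    for read in reads:
        cat, genes = assign_read(read, index, sense)
        setattr(out, cat, getattr(out, cat) + 1)
        if cat == "assigned":
            g = genes[0]
            out.per_gene[g] += 1
            out.per_gene_multi[g] += 1
            out.per_gene_ambig[g] += 1
        elif cat == "multimapping":
            for g in genes:
                out.per_gene_multi[g] += 1
        elif cat == "ambiguous":
            for g in genes:
                out.per_gene_ambig[g] += 1
    return out


# ---------------------------------------------------------------------------
# positional profiles

@dataclass
class PositionalProfile:
    end_kind: str  # 'read_5p' | 'read_3p'
    bins: np.ndarray  # 101 weights
    n_genes: int

    def normalized(self) -> np.ndarray:
        total = self.bins.sum()
        return self.bins / total if total else self.bins


def positional_profile(
    reads: Sequence[AlignedRead],
    models: Sequence[GeneModel],
    sample_fraction: float = 0.01,
    seed: int = 0,
) -> Tuple[PositionalProfile, PositionalProfile]:
    """Distribution of read 5' and 3' ends along the gene body.

    A random ``sample_fraction`` of alignments is drawn (seeded); reads
    without an assigned gene, CBC or UMI, and multimappers, are excluded.
    Each retained read contributes the exonic offsets of its two ends
    (strand-aware; the 3' end uses one-past-the-last-base, so a read ending
    at the gene's 3' terminus lands exactly on offset 1.0).  Offsets fall
    into 101 bins labelled 0..100, bin b covering [b/100, (b+1)/100) and bin
    100 holding exactly 1.0; contributions are weighted 1/(reads retained
    for that gene), so each gene carries total weight 1 per profile.
    Intronic read ends are skipped.
    """
    rng = np.random.default_rng(seed)
    if sample_fraction < 1.0:
        keep = rng.random(len(reads)) < sample_fraction
        sampled = [r for r, k in zip(reads, keep) if k]
    else:
        sampled = list(reads)

    by_gene: Dict[str, GeneModel] = {m.gene_id: m for m in models}
    retained = [
        r
        for r in sampled
        if r.mapped
        and r.assigned_gene in by_gene
        and r.has_cbc
        and r.has_umi
        and r.n_hits == 1
    ]
    per_gene = {}
    for r in retained:
        per_gene[r.assigned_gene] = per_gene.get(r.assigned_gene, 0) + 1

    bins5 = np.zeros(101)
    bins3 = np.zeros(101)
    for r in retained:
        model = by_gene[r.assigned_gene]
        w = 1.0 / per_gene[r.assigned_gene]
        left = r.start
        right = r.end - 1  # last aligned base
        if model.strand == "+":
            five_pos, three_pos = left, right
        else:
            five_pos, three_pos = right, left
        L = model.length
        try:
            cum5 = exonic_cum(model, five_pos)  # offset cum5/L in [0, 1)
            bins5[(100 * cum5) // L] += w
        except ValueError:
            pass
        try:
            cum3 = exonic_cum(model, three_pos) + 1  # one-past: (cum3)/L in (0, 1]
            bins3[min((100 * cum3) // L, 100)] += w
        except ValueError:
            pass
    n_genes = len(per_gene)
    return (
        PositionalProfile("read_5p", bins5, n_genes),
        PositionalProfile("read_3p", bins3, n_genes),
    )


# ---------------------------------------------------------------------------
# assignment rate and bias classification

def assignment_rate(assigned: int, mapped_in_flank: int) -> float:
    """Fraction of reads in the flanked gene body that were gene-assigned."""
    if mapped_in_flank == 0:
        raise ZeroDivisionError("no reads mapped in flank; gene excluded")
    if assigned > mapped_in_flank:
        raise ValueError("assigned exceeds reads mapped in flank")
    return assigned / mapped_in_flank


def gene_flank_counts(
    reads: Sequence[AlignedRead], models: Sequence[GeneModel], flank: int = 100
) -> Dict[str, int]:
    """Mapped reads overlapping each gene's span extended by ``flank`` bp."""
    trees: Dict[str, IntervalTree] = {}
    for m in models:
        tree = trees.setdefault(m.chrom, IntervalTree())
        tree.addi(max(0, m.start - flank), m.end + flank, m.gene_id)
    counts = {m.gene_id: 0 for m in models}
    for r in reads:
        if not r.mapped:
            continue
        hit = set()
        for s, e in r.blocks:
            for iv in trees.get(r.chrom, IntervalTree()).overlap(s, e):
                hit.add(iv.data)
        for g in hit:
            counts[g] += 1
    return counts


@dataclass
class GeneBiasRecord:
    gene_id: str
    count_a: int
    count_b: int
    norm_logfc: float
    assign_rate_a: Optional[float]
    assign_rate_b: Optional[float]
    assign_p_a: Optional[float]  # two-sided binomial p: assigned_a vs rate_b
    assign_p_b: Optional[float]  # two-sided binomial p: assigned_b vs rate_a
    count_class: str  # higher_a | higher_b | similar
    assign_class: str  # higher_a | higher_b | none


def classify_gene_bias(
    per_gene: pd.DataFrame,
    fold: float = 5.0,
    assign_fold: float = 3.0,
    alpha: float = 0.01,
    min_total: int = 100,
) -> List[GeneBiasRecord]:
    """Classify genes by count bias and assignment-rate bias between platforms.

    ``per_gene`` columns: gene_id, count_a, count_b, assigned_a,
    flank_a, assigned_b, flank_b (flank = reads mapped to gene body +100 bp).
    Genes kept when max(count_a, count_b) > min_total.  norm_logfc =
    ln(count_a+1) - ln(count_b+1) minus the median over kept genes; count
    class is 'higher' when |norm_logfc| > ln(fold).  Assignment class
    requires a rate ratio > assign_fold AND a two-sided binomial test
    p < alpha of assigned_a ~ Binom(flank_a, rate_b) (and symmetrically).
    """
    df = per_gene[per_gene[["count_a", "count_b"]].max(axis=1) > min_total].copy()
    if df.empty:
        return []
    logfc = np.log(df["count_a"] + 1) - np.log(df["count_b"] + 1)
    logfc = logfc - np.median(logfc)
    records: List[GeneBiasRecord] = []
    lf = np.log(fold)
    for (_, row), nl in zip(df.iterrows(), logfc):
        count_class = (
            "higher_a" if nl > lf else "higher_b" if nl < -lf else "similar"
        )
        ra = rb = p_a = p_b = None
        assign_class = "none"
        if row["flank_a"] > 0 and row["flank_b"] > 0:
            ra = row["assigned_a"] / row["flank_a"]
            rb = row["assigned_b"] / row["flank_b"]
            p_a = stats.binomtest(
                int(row["assigned_a"]), int(row["flank_a"]), rb
            ).pvalue
            p_b = stats.binomtest(
                int(row["assigned_b"]), int(row["flank_b"]), ra
            ).pvalue
            if rb > 0 and ra / rb > assign_fold and p_a < alpha:
                assign_class = "higher_a"
            elif ra > 0 and rb / ra > assign_fold and p_b < alpha:
                assign_class = "higher_b"
        records.append(
            GeneBiasRecord(
                gene_id=row["gene_id"],
                count_a=int(row["count_a"]),
                count_b=int(row["count_b"]),
                norm_logfc=float(nl),
                assign_rate_a=ra,
                assign_rate_b=rb,
                assign_p_a=p_a,
                assign_p_b=p_b,
                count_class=count_class,
                assign_class=assign_class,
            )
        )
    return records


def pseudobulk_logfc(
    counts_a: pd.DataFrame, counts_b: pd.DataFrame, pseudocount: float = 10.0
) -> pd.DataFrame:
    """Pseudobulk log fold change between two cell x gene count matrices.

    Gene sums per platform are scaled to counts per million; logFC =
    ln(tpm_a + pseudocount) - ln(tpm_b + pseudocount) (natural log).  The
    DE flag marks |logFC| strictly greater than ln 2.
    """
    if counts_a.empty or counts_b.empty:
        raise ValueError("empty count matrix")
    genes = counts_a.columns
    if not genes.equals(counts_b.columns):
        raise ValueError("matrices must share the gene universe")
    sums_a = counts_a.sum(axis=0).astype(float)
    sums_b = counts_b.sum(axis=0).astype(float)
    tpm_a = sums_a / sums_a.sum() * 1e6
    tpm_b = sums_b / sums_b.sum() * 1e6
    logfc = np.log(tpm_a + pseudocount) - np.log(tpm_b + pseudocount)
    # strict inequality: values at the threshold (up to float error) not flagged
    return pd.DataFrame(
        {
            "tpm_a": tpm_a,
            "tpm_b": tpm_b,
            "logfc": logfc,
            "de": np.abs(logfc) - np.log(2) > 1e-9,
        }
    )
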