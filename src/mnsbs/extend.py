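"""Data-driven extension of a gene annotation from aligned reads.

Reads that overlap a gene's exons but spill past its annotated boundaries
are evidence of unannotated transcribed sequence (typically 3' UTR).  The
pipeline: keep uniquely assigned reads without large N gaps, record each as
a stranded interval tagged with its gene, single-linkage cluster intervals
(same chromosome and strand, >=1 bp overlap), merge each (cluster, gene)
group into its envelope, and append the envelopes as new exon records to
the standard GTF.  Original GTF records are preserved byte-verbatim.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .genemodel import (
    AlignedRead,
    GeneIndex,
    GeneModel,
    assign_read,
    parse_gtf_attributes,
)

__all__ = [
    "AssignedInterval",
    "IntervalCluster",
    "ExtensionExon",
    "reads_to_intervals",
    "cluster_intervals",
    "merge_cluster_gene",
    "build_extended_gtf",
    "extend_annotation",
]

MAX_N_GAP = 10


@dataclass
class AssignedInterval:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("interval start must be < end")


@dataclass
class IntervalCluster:
    cluster_id: int
    chrom: str
    strand: str
    members: List[AssignedInterval]


@dataclass
class ExtensionExon:
    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    source: str = "mnsbs_extend"


def reads_to_intervals(
    reads: Sequence[AlignedRead],
    models: Sequence[GeneModel],
    sense: str = "sense",
    max_n_gap: int = MAX_N_GAP,
    fragment_span: bool = False,
) -> List[AssignedInterval]:
    """One stranded interval per uniquely assigned read.

    Reads that are unmapped, multimapping, ambiguous, unassigned, or carry
    more than ``max_n_gap`` N-gap bases are dropped.  The interval spans
    alignment start to end (per read; ``fragment_span`` is accepted for
    paired input where mate spans were merged upstream — intervals are
    emitted identically).
    """
    index = GeneIndex(models)
    out: List[AssignedInterval] = []
    for r in reads:
        if not r.mapped or r.gap_n_total > max_n_gap:
            continue
        cat, genes = assign_read(r, index, sense)
        if cat != "assigned":
            continue
        out.append(
            AssignedInterval(
                chrom=r.chrom, start=r.start, end=r.end,
                strand=r.strand, gene_id=genes[0],
            )
        )
    return out


def cluster_intervals(intervals: Sequence[AssignedInterval]) -> List[IntervalCluster]:
    """Single-linkage stranded clustering of intervals.

    Two intervals chain into one cluster iff they share chromosome and
    strand and overlap by at least one base (half-open coordinates:
    book-ended intervals do not cluster).  Cluster ids follow sweep order.
    """
    ordered = sorted(intervals, key=lambda iv: (iv.chrom, iv.strand, iv.start, iv.end))
    clusters: List[IntervalCluster] = []
    current: Optional[IntervalCluster] = None
    reach = 0
    for iv in ordered:
        if (
            current is not None
            and iv.chrom == current.chrom
            and iv.strand == current.strand
            and iv.start < reach
        ):
            current.members.append(iv)
            reach = max(reach, iv.end)
        else:
            current = IntervalCluster(len(clusters), iv.chrom, iv.strand, [iv])
            clusters.append(current)
            reach = iv.end
    return clusters


def merge_cluster_gene(clusters: Sequence[IntervalCluster]) -> List[ExtensionExon]:
    """Envelope [min start, max end) per (cluster, gene) group."""
    out: List[ExtensionExon] = []
    for cl in clusters:
        by_gene: Dict[str, List[AssignedInterval]] = {}
        for iv in cl.members:
            by_gene.setdefault(iv.gene_id, []).append(iv)
        for gene_id in sorted(by_gene):
            ivs = by_gene[gene_id]
            out.append(
                ExtensionExon(
                    chrom=cl.chrom,
                    start=min(iv.start for iv in ivs),
                    end=max(iv.end for iv in ivs),
                    strand=cl.strand,
                    gene_id=gene_id,
                )
            )
    return out


def build_extended_gtf(
    gtf_path, exons: Sequence[ExtensionExon], out_path
) -> int:
    """Append extension exons to a GTF, preserving original lines verbatim.

    Each extension exon becomes one exon record with the gene's gene_id and
    gene_name and a synthetic transcript id "<gene_id>.ext.<n>".  The output
    is coordinate-sorted (chromosome, start); original lines keep their text
    byte-for-byte.  Unknown gene_ids raise ValueError listing offenders.
    """
    originals: List[Tuple[str, int, str]] = []  # (chrom, start0, raw line)
    gene_names: Dict[str, str] = {}
    header: List[str] = []
    with open(gtf_path) as fh:
        for line in fh:
            raw = line.rstrip("\n")
            if not raw.strip():
                continue
            if raw.startswith("#"):
                header.append(raw)
                continue
            f = raw.split("\t")
            if len(f) < 9:
                raise ValueError(f"bad GTF line: {raw!r}")
            attrs = parse_gtf_attributes(f[8])
            gid = attrs.get("gene_id")
            if gid and gid not in gene_names:
                gene_names[gid] = attrs.get("gene_name", gid)
            originals.append((f[0], int(f[3]) - 1, raw))

    unknown = sorted({e.gene_id for e in exons} - set(gene_names))
    if unknown:
        raise ValueError(f"extension exons reference unknown gene_ids: {unknown}")

    counters: Dict[str, int] = {}
    new_lines: List[Tuple[str, int, str]] = []
    for e in exons:
        counters[e.gene_id] = counters.get(e.gene_id, 0) + 1
        tid = f"{e.gene_id}.ext.{counters[e.gene_id]}"
        attrs = (
            f'gene_id "{e.gene_id}"; transcript_id "{tid}"; '
            f'gene_name "{gene_names[e.gene_id]}";'
        )
        line = "\t".join(
            [e.chrom, e.source, "exon", str(e.start + 1), str(e.end), ".",
             e.strand, ".", attrs]
        )
        new_lines.append((e.chrom, e.start, line))

    merged = sorted(originals + new_lines, key=lambda t: (t[0], t[1]))
    with open(out_path, "w") as fh:
        for h in header:
            fh.write(h + "\n")
        for _, _, line in merged:
            fh.write(line + "\n")
    return len(new_lines)


def extend_annotation(
    reads: Sequence[AlignedRead],
    models: Sequence[GeneModel],
    gtf_path,
    out_path,
    sense: str = "sense",
    max_n_gap: int = MAX_N_GAP,
) -> List[ExtensionExon]:
    """Full pipeline: reads -> intervals -> clusters -> envelopes -> GTF."""
    intervals = reads_to_intervals(reads, models, sense=sense, max_n_gap=max_n_gap)
    exons = merge_cluster_gene(cluster_intervals(intervals))
    build_extended_gtf(gtf_path, exons, out_path)
    return exons
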