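"""Restructure single-end barcode+anchor+cDNA reads into simulated read pairs.

Open-fluidics sequencers emit one read per molecule in which the cell
barcode, UMI, anchor (poly(T) or TSO) and cDNA are concatenated.  Standard
droplet pre-processors expect paired-end input: R1 = CBC+UMI, R2 = cDNA in
antisense orientation.  The conversion here is:

1. 3' quality trimming with the partial-sum rule at a Phred threshold
   (default 30);
2. anchor detection at the fixed offset cbc_len+umi_len — at least eight
   consecutive Ts for 3' chemistry, the TSO within a mismatch budget for 5';
3. split into R1 (CBC+UMI, with the terminal UMI bases optionally masked to
   'A' at a fixed quality) and cDNA (anchor end + clip offset to read end);
4. discard if the cDNA is shorter than 50 bases, else keep the
   anchor-proximal 90 bases and emit their reverse complement (with
   reversed qualities) as R2.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Tuple, Union

import numpy as np

from .chemistry import (
    AnchorKind,
    ChemistryProfile,
    DiscardReason,
    PhredRead,
    hamming,
    reverse_complement,
)

__all__ = [
    "SimulatedPair",
    "ConversionReport",
    "quality_trim_3prime",
    "locate_anchor",
    "restructure_read",
    "convert_stream",
]


@dataclass
class SimulatedPair:
    """Restructured (barcode read, antisense cDNA read) pair."""

    r1: PhredRead
    r2: PhredRead
    source_id: str
    anchor_span: Tuple[int, int]  # half-open, on the quality-trimmed source


@dataclass
class ConversionReport:
    n_input: int = 0
    n_too_short_after_trim: int = 0
    n_no_anchor: int = 0
    n_short_cdna: int = 0
    n_emitted: int = 0

    def check(self) -> None:
        total = (
            self.n_too_short_after_trim
            + self.n_no_anchor
            + self.n_short_cdna
            + self.n_emitted
        )
        if total != self.n_input:
            raise AssertionError(f"counter mismatch: {self} ")

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_too_short_after_trim": self.n_too_short_after_trim,
            "n_no_anchor": self.n_no_anchor,
            "n_short_cdna": self.n_short_cdna,
            "n_emitted": self.n_emitted,
        }


def quality_trim_3prime(read: PhredRead, threshold: int) -> PhredRead:
    """Trim the 3' end by the partial-sum rule.

    For each cut point i, S_i = sum_{j>=i}(qual_j - threshold).  The read is
    cut at the i minimising S_i; if the minimum is non-negative the read is
    unchanged.  Among tied minima the longest prefix is kept.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    n = len(read)
    if n == 0:
        return read
    d = np.asarray(read.quals, dtype=np.int64) - threshold
    # suffix[i] = S_i computed from the 3' end
    suffix = np.cumsum(d[::-1])[::-1]
    m = suffix.min()
    if m >= 0:
        return read
    # last index attaining the minimum -> longest surviving prefix
    cut = n - 1 - int(np.argmin(suffix[::-1]))
    return read.slice(0, cut)


def locate_anchor(
    read: PhredRead, chem: ChemistryProfile
) -> Optional[Tuple[int, int]]:
    """Locate the anchor at the fixed offset cbc_len+umi_len.

    Poly(T): requires >= anchor_min_t consecutive Ts starting at the offset;
    the span covers the maximal contiguous T run.  TSO: requires Hamming
    distance <= tso_max_mismatch over the TSO-length window.  Returns the
    half-open span, or None.
    """
    off = chem.prefix_len
    if chem.anchor_kind is AnchorKind.POLY_T:
        if len(read) < off + chem.anchor_min_t:
            return None
        end = off
        n = len(read)
        while end < n and read.bases[end] == "T":
            end += 1
        if end - off < chem.anchor_min_t:
            return None
        return (off, end)
    window = read.bases[off : off + len(chem.tso_seq)]
    if len(window) < len(chem.tso_seq):
        return None
    if hamming(window, chem.tso_seq) > chem.tso_max_mismatch:
        return None
    return (off, off + len(chem.tso_seq))


def restructure_read(
    read: PhredRead, chem: ChemistryProfile, mask_mode: str = "substitute"
) -> Union[SimulatedPair, DiscardReason]:
    """Convert one single-end read into a simulated pair, or a discard reason.

    mask_mode: 'substitute' replaces the terminal umi_mask_len UMI bases with
    mask_base at mask_qual (the default); 'trim' drops them from R1 instead.
    """
    trimmed = quality_trim_3prime(read, chem.qtrim_threshold)
    if len(trimmed) < chem.prefix_len + chem.min_anchor_len:
        return DiscardReason.TOO_SHORT
    span = locate_anchor(trimmed, chem)
    if span is None:
        return DiscardReason.NO_ANCHOR
    cdna_start = span[1] + chem.clip_after_anchor
    cdna = trimmed.slice(cdna_start, len(trimmed))
    if len(cdna) < chem.min_cdna_len:
        return DiscardReason.SHORT_CDNA
    cdna = cdna.slice(0, chem.max_cdna_len)

    r1_bases = trimmed.bases[: chem.prefix_len]
    r1_quals = list(trimmed.quals[: chem.prefix_len])
    k = chem.umi_mask_len
    if k > 0:
        if mask_mode == "substitute":
            r1_bases = r1_bases[:-k] + chem.mask_base * k
            r1_quals[-k:] = [chem.mask_qual] * k
        elif mask_mode == "trim":
            r1_bases = r1_bases[:-k]
            r1_quals = r1_quals[:-k]
        else:
            raise ValueError(f"unknown mask_mode {mask_mode!r}")
    r1 = PhredRead(read.id, r1_bases, r1_quals)
    r2 = PhredRead(read.id, reverse_complement(cdna.bases), cdna.quals[::-1])
    return SimulatedPair(r1=r1, r2=r2, source_id=read.id, anchor_span=span)


def convert_stream(
    reads: Iterable[PhredRead], chem: ChemistryProfile, mask_mode: str = "substitute"
) -> Tuple[List[SimulatedPair], ConversionReport]:
    """Convert a read stream, preserving order, with discard accounting."""
    report = ConversionReport()
    pairs: List[SimulatedPair] = []
    for read in reads:
        report.n_input += 1
        out = restructure_read(read, chem, mask_mode=mask_mode)
        if isinstance(out, SimulatedPair):
            report.n_emitted += 1
            pairs.append(out)
        elif out is DiscardReason.TOO_SHORT:
            report.n_too_short_after_trim += 1
        elif out is DiscardReason.NO_ANCHOR:
            report.n_no_anchor += 1
        else:
            report.n_short_cdna += 1
    report.check()
    return pairs, report
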