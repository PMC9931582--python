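"""Read layout descriptions for single-end droplet scRNA-seq chemistries.

A single-end read from an open-fluidics (mostly natural SBS) sequencer
carries, in order: cell barcode (CBC), unique molecular identifier (UMI),
an anchor separating barcode from insert — a poly(T) run for 3' gene
expression libraries, the template-switch oligo (TSO) for 5' libraries —
and finally the cDNA insert.  A :class:`ChemistryProfile` captures the
segment lengths and the trimming/masking rules applied when such a read is
restructured into a simulated (R1, R2) pair.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import List, Sequence

MAX_PHRED = 93

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement; 'N' maps to 'N'."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnchorKind(str, Enum):
    POLY_T = "poly_t"
    TSO = "tso"


class DiscardReason(str, Enum):
    TOO_SHORT = "too_short_after_trim"
    NO_ANCHOR = "no_anchor"
    SHORT_CDNA = "short_cdna"


@dataclass
class PhredRead:
    """A read with per-base Phred quality scores (Phred+33 on disk)."""

    id: str
    bases: str
    quals: List[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.id!r}: {len(self.bases)} bases but {len(self.quals)} quals"
            )
        if self.quals and (min(self.quals) < 0 or max(self.quals) > MAX_PHRED):
            raise ValueError(f"read {self.id!r}: quality outside [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, stop: int) -> "PhredRead":
        return PhredRead(self.id, self.bases[start:stop], self.quals[start:stop])


# 13-base template-switch sequence present after the UMI in 10x 5' reads.
DEFAULT_TSO = "TTTCTTATATGGG"


@dataclass(frozen=True)
class ChemistryProfile:
    """Segment lengths and restructuring rules for one library chemistry.

    Defaults follow the 10x 3' v3.1 (16+12, poly(T) anchor) and 5' v2
    (16+10, TSO anchor) constructs; every rule is configurable.
    """

    name: str
    cbc_len: int = 16
    umi_len: int = 12
    anchor_kind: AnchorKind = AnchorKind.POLY_T
    anchor_min_t: int = 8
    tso_seq: str = DEFAULT_TSO
    tso_max_mismatch: int = 2
    clip_after_anchor: int = 5
    umi_mask_len: int = 3
    mask_base: str = "A"
    mask_qual: int = 40
    min_cdna_len: int = 50
    max_cdna_len: int = 90
    qtrim_threshold: int = 30

    def __post_init__(self) -> None:
        if self.cbc_len <= 0:
            raise ValueError("cbc_len must be positive")
        if self.umi_mask_len > self.umi_len:
            raise ValueError("umi_mask_len exceeds umi_len")
        if self.min_cdna_len > self.max_cdna_len:
            raise ValueError("min_cdna_len exceeds max_cdna_len")
        if self.anchor_kind is AnchorKind.POLY_T and self.anchor_min_t < 1:
            raise ValueError("anchor_min_t must be >= 1 for poly(T) chemistry")

    @property
    def prefix_len(self) -> int:
        """Bases before the anchor: CBC followed by UMI."""
        return self.cbc_len + self.umi_len

    @property
    def min_anchor_len(self) -> int:
        if self.anchor_kind is AnchorKind.POLY_T:
            return self.anchor_min_t
        return len(self.tso_seq)

    def with_(self, **kw) -> "ChemistryProfile":
        return replace(self, **kw)


THREE_PRIME = ChemistryProfile(name="3p")
FIVE_PRIME = ChemistryProfile(
    name="5p",
    umi_len=10,
    anchor_kind=AnchorKind.TSO,
    clip_after_anchor=3,
    umi_mask_len=0,
)

PROFILES = {"3p": THREE_PRIME, "5p": FIVE_PRIME}


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
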