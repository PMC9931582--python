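"""UMI-shortening diagnostics on molecule tables.

A molecule table has one row per unique (cell barcode, UMI, gene) with the
number of supporting reads — the text form of a droplet pipeline's
molecule-info output.  Shortening the UMI (keeping its prefix) merges
molecules whose keys collide; the statistics here quantify that loss:
within-gene merges, keys shared across genes, and per-cell / per-gene
trimmed-to-full UMI count ratios.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import pandas as pd

from .chemistry import ChemistryProfile
from .restructure import SimulatedPair

COLUMNS = ["cbc", "umi", "gene", "reads"]


def read_molecule_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cbc": str, "umi": str, "gene": str})
    missing = set(COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"molecule table missing columns: {sorted(missing)}")
    return df[COLUMNS]


def write_molecule_table(df: pd.DataFrame, path) -> None:
    df[COLUMNS].to_csv(path, sep="\t", index=False)


@dataclass
class CollapseStats:
    umi_len_out: int
    n_in: int
    n_out: int
    n_merged_within_gene: int
    n_multi_gene_keys: int
    fraction_single_gene: float


def collapse_table(
    table: pd.DataFrame, target_len: int, keep: str = "prefix"
) -> Tuple[pd.DataFrame, CollapseStats]:
    """Shorten UMIs to ``target_len`` and merge molecules sharing a key.

    Output rows are keyed by (cbc, shortened umi, gene) with read counts
    summed.  ``keep='prefix'`` drops terminal UMI bases (the poly(T)-adjacent
    ones); ``keep='suffix'`` drops leading bases instead.
    """
    if target_len <= 0:
        raise ValueError("target_len must be positive")
    umi_len = table["umi"].str.len()
    if (umi_len < target_len).any():
        raise ValueError("target_len exceeds UMI length in table")
    if keep == "prefix":
        short = table["umi"].str.slice(0, target_len)
    elif keep == "suffix":
        short = table["umi"].str.slice(-target_len)
    else:
        raise ValueError(f"unknown keep mode {keep!r}")

    work = table.assign(umi=short)
    out = (
        work.groupby(["cbc", "umi", "gene"], sort=False, as_index=False)["reads"]
        .sum()
    )
    n_in, n_out = len(table), len(out)
    genes_per_key = out.groupby(["cbc", "umi"], sort=False)["gene"].nunique()
    n_multi = int((genes_per_key > 1).sum())
    n_keys = len(genes_per_key)
    stats = CollapseStats(
        umi_len_out=target_len,
        n_in=n_in,
        n_out=n_out,
        n_merged_within_gene=n_in - n_out,
        n_multi_gene_keys=n_multi,
        fraction_single_gene=1.0 - n_multi / n_keys if n_keys else 1.0,
    )
    return out, stats


@dataclass
class TrimRatio:
    entity_id: str
    n_full: int
    n_trim: int
    ratio: float


def trim_ratio(
    table: pd.DataFrame, full_len: int, trim_len: int, by: str = "cell"
) -> List[TrimRatio]:
    """Per-cell or per-gene ratio of trimmed-UMI to full-UMI molecule counts.

    A ratio of 1.0 means trimming merged nothing for that entity; 0.8 means a
    20% loss of distinguishable molecules, etc.
    """
    if not trim_len < full_len:
        raise ValueError("require trim_len < full_len")
    if (table["umi"].str.len() < full_len).any():
        raise ValueError("full_len exceeds UMI length in table")
    if by == "cell":
        entity = "cbc"
        other = "gene"
    elif by == "gene":
        entity = "gene"
        other = "cbc"
    else:
        raise ValueError(f"by must be 'cell' or 'gene', got {by!r}")

    short = table["umi"].str.slice(0, trim_len)
    work = pd.DataFrame(
        {entity: table[entity], "key": table[other] + "\x00" + short}
    )
    full = table.groupby(entity, sort=False).size()
    trim = work.groupby(entity, sort=False)["key"].nunique()
    return [
        TrimRatio(entity_id=e, n_full=int(full[e]), n_trim=int(trim[e]),
                  ratio=trim[e] / full[e])
        for e in full.index
    ]


def filter_umi_quality(
    pairs: Sequence[SimulatedPair], min_q: int, chem: ChemistryProfile
) -> Tuple[List[SimulatedPair], int]:
    """Drop pairs whose UMI segment contains any base below ``min_q``.

    The UMI occupies R1 positions [cbc_len, cbc_len+umi_len); masked bases
    carry the mask quality and therefore pass.
    """
    kept: List[SimulatedPair] = []
    removed = 0
    lo, hi = chem.cbc_len, chem.cbc_len + chem.umi_len
    for p in pairs:
        if len(p.r1) < hi:
            raise ValueError(f"pair {p.source_id!r}: R1 shorter than CBC+UMI")
        if all(q >= min_q for q in p.r1.quals[lo:hi]):
            kept.append(p)
        else:
            removed += 1
    return kept, removed
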