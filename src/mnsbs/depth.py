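"""Depth normalisation between sequencing platforms.

To compare platforms at equal depth, reads are downsampled so the UMI
totals match: a coarse scan over sampling proportions in 5% increments
picks the largest proportion yielding fewer UMIs than the target, then a
1% refinement over the next 5% window picks the final proportion.  Thinning
operates on molecule tables: each molecule with r supporting reads survives
sampling at proportion p with probability 1-(1-p)^r.  Sampling draws are
coupled across proportions (one minimum-uniform per molecule), so UMI
survival is exactly monotone in p and the search brackets the target.

Split-half resampling partitions individual reads into two disjoint halves
of equal size (up to rounding) and rebuilds a molecule table per half.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple, TypeVar

import numpy as np
import pandas as pd

T = TypeVar("T")


def sample_read_stream(reads: Sequence[T], p: float, seed: int) -> List[T]:
    """Keep each read independently with probability p; seed-deterministic."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if p == 1:
        return list(reads)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < p
    return [r for r, k in zip(reads, keep) if k]


def thin_molecule_table(table: pd.DataFrame, p: float, seed: int) -> pd.DataFrame:
    """Binomially thin read counts at proportion p; drop empty molecules."""
    if not 0 < p <= 1:
        raise ValueError("p must be in (0, 1]")
    if p == 1:
        return table.copy()
    rng = np.random.default_rng(seed)
    new = rng.binomial(table["reads"].to_numpy(), p)
    out = table.assign(reads=new)
    return out[out["reads"] > 0].reset_index(drop=True)


@dataclass
class DepthMatchResult:
    coarse_evals: List[Tuple[float, int]]
    refined_evals: List[Tuple[float, int]]
    chosen_p: float
    target_umis: int

    def umis_at(self, p: float) -> int:
        for q, n in self.coarse_evals + self.refined_evals:
            if abs(q - p) < 1e-9:
                return n
        raise KeyError(f"proportion {p} was not evaluated")


def _min_uniforms(read_counts: np.ndarray, seed: int) -> np.ndarray:
    # minimum of r iid uniforms ~ Beta(1, r): the sampling proportion at
    # which the molecule first survives.  One draw per molecule couples
    # every proportion on the grid.
    rng = np.random.default_rng(seed)
    return rng.beta(1.0, read_counts.astype(float))


def match_depth(table: pd.DataFrame, target_umis: int, seed: int) -> DepthMatchResult:
    """Two-step search for the largest proportion with fewer UMIs than target.

    Coarse pass: p in {0.05, 0.10, ..., 1.00}.  Refinement: 1% steps over
    (estimate, estimate+5%].  If even the full table has fewer UMIs than the
    target, no sampling is needed and chosen_p is 1.0.
    """
    if target_umis <= 0:
        raise ValueError("target_umis must be positive")
    m = _min_uniforms(table["reads"].to_numpy(), seed)
    m.sort()

    def umis(p: float) -> int:
        return int(np.searchsorted(m, p, side="left"))

    coarse_grid = [round(0.05 * i, 2) for i in range(1, 21)]
    coarse = [(p, umis(p)) for p in coarse_grid]
    total = umis(1.0)
    if total < target_umis:
        return DepthMatchResult(coarse, [], 1.0, target_umis)

    under = [p for p, n in coarse if n < target_umis]
    estimate = max(under) if under else 0.0
    if not under:
        warnings.warn(
            "target below UMI count at the smallest coarse proportion; "
            "refining from 0"
        )
    refined_grid = [round(estimate + 0.01 * i, 2) for i in range(1, 6)]
    refined_grid = [p for p in refined_grid if p <= 1.0]
    refined = [(p, umis(p)) for p in refined_grid]

    candidates = [p for p, n in coarse + refined if n < target_umis]
    if not candidates:
        chosen = min(p for p, _ in coarse + refined)
        warnings.warn("no evaluated proportion yields fewer UMIs than target")
    else:
        chosen = max(candidates)
    return DepthMatchResult(coarse, refined, chosen, target_umis)


@dataclass
class SplitHalves:
    half_a: np.ndarray  # read indices (into the expanded read list)
    half_b: np.ndarray
    table_a: pd.DataFrame
    table_b: pd.DataFrame


def split_halves(table: pd.DataFrame, seed: int) -> SplitHalves:
    """Partition individual reads into two disjoint halves and rebuild tables.

    Reads are enumerated molecule by molecule; a uniform random half (sizes
    differing by at most one) goes to A, the rest to B.  A molecule appears
    in a half's table with the count of its reads landing there; single-read
    molecules therefore appear in exactly one half.
    """
    counts = table["reads"].to_numpy()
    total = int(counts.sum())
    if total < 2:
        raise ValueError("need at least 2 reads to split")
    rng = np.random.default_rng(seed)
    n_a = (total + 1) // 2
    assign = np.zeros(total, dtype=bool)
    assign[:n_a] = True
    rng.shuffle(assign)

    mol_of_read = np.repeat(np.arange(len(table)), counts)
    reads_a = np.bincount(mol_of_read[assign], minlength=len(table))
    reads_b = counts - reads_a

    def build(per_mol: np.ndarray) -> pd.DataFrame:
        out = table.assign(reads=per_mol)
        return out[out["reads"] > 0].reset_index(drop=True)

    return SplitHalves(
        half_a=np.flatnonzero(assign),
        half_b=np.flatnonzero(~assign),
        table_a=build(reads_a),
        table_b=build(reads_b),
    )
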