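"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's sweep/searchsorted implementations:
interval questions are answered per base on explicit coverage arrays, and
rank statistics are recomputed from first principles.
"""

from __future__ import annotations

import numpy as np


def perbase_consensus(source_pairs: list[list[tuple[int, int]]],
                      min_sources: int, chrom_len: int) -> list[tuple[int, int]]:
    """Per-base oracle for multi-source consensus on one chromosome:
    contiguous union-covered runs containing >=1 base covered by
    >= min_sources distinct sources."""
    depth = np.zeros(chrom_len, dtype=int)
    union = np.zeros(chrom_len, dtype=bool)
    for pairs in source_pairs:
        cov = np.zeros(chrom_len, dtype=bool)
        for s, e in pairs:
            cov[s:e] = True
        union |= cov
        depth += cov
    runs = bool_runs(union)
    return [(s, e) for s, e in runs if (depth[s:e] >= min_sources).any()]


def bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True in a boolean array, as half-open intervals."""
    out = []
    in_run = False
    start = 0
    for i, v in enumerate(mask):
        if v and not in_run:
            in_run, start = True, i
        elif not v and in_run:
            out.append((start, i))
            in_run = False
    if in_run:
        out.append((start, len(mask)))
    return out


def perbase_mask(contributions: list[tuple[int, int]],
                 chrom_len: int) -> np.ndarray:
    cov = np.zeros(chrom_len, dtype=bool)
    for s, e in contributions:
        cov[max(0, s):min(chrom_len, e)] = True
    return cov


def perbase_overlaps(start: int, end: int, cov: np.ndarray) -> bool:
    return bool(cov[start:end].any())


def bruteforce_counts(reads: list[tuple[str, int, int, str]],
                      regions: list[tuple[str, str, int, int]],
                      samples: list[str]) -> dict[tuple[str, str], int]:
    """O(n*m) overlap counts: reads are (chrom, start, end, sample);
    regions are (id, chrom, start, end)."""
    counts = {(rid, s): 0 for rid, *_ in regions for s in samples}
    for chrom, rs, re_, sample in reads:
        for rid, rchrom, s, e in regions:
            if chrom == rchrom and rs < e and s < re_:
                counts[(rid, sample)] += 1
    return counts


def spearman_oracle(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-then-Pearson with explicit mid-ranks computed by sorting."""

    def midrank(v: np.ndarray) -> np.ndarray:
        order = np.argsort(v, kind="mergesort")
        ranks = np.empty(len(v), dtype=float)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midrank(np.asarray(x, float)), midrank(np.asarray(y, float))
    dx, dy = rx - rx.mean(), ry - ry.mean()
    return float((dx * dy).sum() / np.sqrt((dx ** 2).sum() * (dy ** 2).sum()))


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up from the definition: q_(i) =
    min_{j>=i} ( m * p_(j) / j ), capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(1.0, running)
    q = np.empty(m)
    q[order] = q_sorted
    return q
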