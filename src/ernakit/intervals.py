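"""Genomic interval primitives.

All coordinates are BED-style: 0-based, half-open ``[start, end)``. Strand is
carried on every interval but deliberately ignored by the overlap machinery
(exclusion masking and read counting are strand-agnostic); it only matters
when placing the upstream-antisense (uaRNA) window relative to a TSS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")
ROLES = ("enhancer", "gene", "lncRNA", "blacklist", "read")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid coordinates {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple[str, int, int]:
        return (self.chrom, self.start, self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneRecord(GenomicInterval):
    """A gene or lncRNA span with TSS, TES and exon structure.

    ``tss``/``tes`` are single base positions inside ``[start, end)``;
    ``exons`` are half-open sub-intervals of the gene span, non-overlapping
    once sorted. Introns are the gaps between consecutive exons.
    """

    tss: int = -1
    tes: int = -1
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        super().__post_init__()
        for name, pos in (("tss", self.tss), ("tes", self.tes)):
            if not (self.start <= pos < self.end):
                raise ValueError(
                    f"{name}={pos} outside gene span "
                    f"{self.chrom}:{self.start}-{self.end}"
                )
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for (s, e) in exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"exon [{s},{e}) not nested in gene span")
            if prev_end is not None and s < prev_end:
                raise ValueError("exons overlap after sorting")
            prev_end = e

    def introns(self) -> list[tuple[int, int]]:
        gaps = []
        for (s0, e0), (s1, _e1) in zip(self.exons, self.exons[1:]):
            if s1 > e0:
                gaps.append((e0, s1))
        return gaps


@dataclass
class AnnotationSet:
    """A collection of intervals sharing one role, tagged with a source label."""

    role: str
    source: str
    intervals: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}; expected one of {ROLES}")
        if self.role in ("gene", "lncRNA"):
            for iv in self.intervals:
                if not isinstance(iv, GeneRecord):
                    raise ValueError(f"role {self.role!r} requires GeneRecord entries")
        # canonical order so downstream output never depends on input ordering
        self.intervals = sorted(self.intervals, key=lambda iv: iv.sort_key())

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def chroms(self) -> list[str]:
        return sorted({iv.chrom for iv in self.intervals})

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out


# ---------------------------------------------------------------------------
# interval arithmetic on (start, end) arrays, per chromosome
# ---------------------------------------------------------------------------

def merge_pairs(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open intervals into maximal runs.

    Touching intervals ([a,b) and [b,c)) merge because the covered bases form
    one contiguous run.
    """
    pairs = sorted(pairs)
    merged: list[tuple[int, int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            if e > merged[-1][1]:
                merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


class IntervalIndex:
    """Sorted, merged intervals of one chromosome supporting overlap queries."""

    def __init__(self, pairs: Iterable[tuple[int, int]]):
        merged = merge_pairs(pairs)
        self.starts = np.array([s for s, _ in merged], dtype=np.int64)
        self.ends = np.array([e for _, e in merged], dtype=np.int64)

    def overlaps_any(self, start: int | np.ndarray, end: int | np.ndarray):
        """True where the query [start, end) shares >=1 bp with any interval."""
        start = np.asarray(start, dtype=np.int64)
        end = np.asarray(end, dtype=np.int64)
        if self.starts.size == 0:
            return np.zeros(start.shape, dtype=bool) if start.ndim else False
        # candidate: the last stored interval with starts < end
        idx = np.searchsorted(self.starts, end, side="left") - 1
        hit = (idx >= 0) & (np.where(idx >= 0, self.ends[np.maximum(idx, 0)], 0) > start)
        return hit if start.ndim else bool(hit)


def multisource_consensus(
    sets_by_chrom: dict[str, list[list[tuple[int, int]]]],
    min_sources: int,
) -> dict[str, list[tuple[int, int]]]:
    """Per-chromosome consensus runs from multiple interval sources.

    Returns the maximal contiguous runs of bases covered by the union of all
    sources, keeping only runs that contain >=1 base covered by at least
    ``min_sources`` distinct sources. Within one source, overlapping intervals
    count once (per-base source multiplicity is 0/1).
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for chrom, per_source in sets_by_chrom.items():
        # sweep events: +1/-1 per *merged-within-source* interval, so each
        # source contributes at most 1 to depth at any base
        events: list[tuple[int, int]] = []
        for pairs in per_source:
            for s, e in merge_pairs(pairs):
                events.append((s, 1))
                events.append((e, -1))
        if not events:
            continue
        events.sort()
        union_runs: list[tuple[int, int]] = []
        seed_runs: list[tuple[int, int]] = []
        depth = 0
        union_start = seed_start = None
        i, n = 0, len(events)
        while i < n:
            pos = events[i][0]
            while i < n and events[i][0] == pos:
                depth += events[i][1]
                i += 1
            if depth > 0 and union_start is None:
                union_start = pos
            elif depth == 0 and union_start is not None:
                union_runs.append((union_start, pos))
                union_start = None
            if depth >= min_sources and seed_start is None:
                seed_start = pos
            elif depth < min_sources and seed_start is not None:
                seed_runs.append((seed_start, pos))
                seed_start = None
        seeds = IntervalIndex(seed_runs)
        kept = [
            (s, e) for s, e in union_runs
            if seed_runs and seeds.overlaps_any(s, e)
        ]
        if kept:
            out[chrom] = kept
    return out
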