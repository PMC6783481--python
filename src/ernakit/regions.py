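"""Candidate eRNA region construction.

The pipeline starts from enhancer annotations collected from several sources.
An enhancer is trusted when it is annotated in at least ``min_sources``
distinct sources; the consensus operation returns maximal union-coverage runs
that contain at least one multi-source base. Each consensus enhancer yields
one candidate eRNA region: the +/- ``flank_bp`` window around its midpoint
(clamped at chromosome ends). A region is then dropped outright — not
trimmed — if it overlaps, by a single base, any exclusion interval: a gene or
lncRNA span extended ``gene_extension_bp`` on both ends, the
``uaRNA_window_bp`` upstream-antisense window beyond the extended TSS side,
or a blacklist interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .intervals import (
    AnnotationSet,
    GeneRecord,
    GenomicInterval,
    IntervalIndex,
    merge_pairs,
    multisource_consensus,
)


@dataclass(frozen=True)
class ERNARegion:
    id: str
    interval: GenomicInterval
    midpoint: int

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end


@dataclass
class ExclusionMask:
    """Merged exclusion intervals plus the tagged pre-merge contributions."""

    merged: dict[str, list[tuple[int, int]]]
    contributions: list[tuple[str, int, int, str]]  # (chrom, start, end, tag)

    def index(self) -> dict[str, IntervalIndex]:
        return {c: IntervalIndex(p) for c, p in self.merged.items()}


def consensus_enhancers(sources: list[AnnotationSet], min_sources: int) -> AnnotationSet:
    """Merge multi-source enhancer annotations into consensus enhancers.

    Keeps every maximal contiguous run of union coverage that contains at
    least one base annotated by >= ``min_sources`` distinct sources.
    """
    if len(sources) < min_sources:
        raise ValueError(
            f"{len(sources)} source sets provided but min_sources={min_sources}"
        )
    chroms: dict[str, list[list[tuple[int, int]]]] = {}
    all_chroms = sorted({iv.chrom for src in sources for iv in src})
    for chrom in all_chroms:
        chroms[chrom] = [
            [(iv.start, iv.end) for iv in src if iv.chrom == chrom]
            for src in sources
        ]
    runs = multisource_consensus(chroms, min_sources)
    intervals = [
        GenomicInterval(chrom=c, start=s, end=e, id=f"cons_{c}_{s}_{e}")
        for c in sorted(runs) for s, e in runs[c]
    ]
    return AnnotationSet(role="enhancer", source="consensus", intervals=intervals)


def define_regions(
    consensus: AnnotationSet,
    flank_bp: int,
    chrom_lengths: dict[str, int],
) -> list[ERNARegion]:
    """One +/- ``flank_bp`` region per consensus enhancer, clamped to the
    chromosome; the ID is deterministic from the midpoint coordinate."""
    regions: list[ERNARegion] = []
    for enh in consensus:
        if enh.chrom not in chrom_lengths:
            raise ValueError(f"enhancer on unknown chromosome {enh.chrom!r}")
        clen = chrom_lengths[enh.chrom]
        mid = (enh.start + enh.end) // 2
        start = max(0, mid - flank_bp)
        end = min(clen, mid + flank_bp)
        regions.append(ERNARegion(
            id=f"erna_{enh.chrom}_{mid}",
            interval=GenomicInterval(chrom=enh.chrom, start=start, end=end,
                                     id=f"erna_{enh.chrom}_{mid}"),
            midpoint=mid,
        ))
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return regions


def build_exclusion_mask(
    genes: AnnotationSet,
    lncrnas: AnnotationSet,
    blacklist: AnnotationSet,
    gene_extension_bp: int,
    uaRNA_window_bp: int,
) -> ExclusionMask:
    """Exclusion geometry around annotated transcription units.

    Per gene/lncRNA: the span extended ``gene_extension_bp`` on both ends,
    plus a ``uaRNA_window_bp`` window immediately beyond the extended
    upstream (TSS) end — strand-aware, so lower coordinates for ``+`` genes
    and higher for ``-`` genes. Blacklist intervals enter unchanged.
    """
    contributions: list[tuple[str, int, int, str]] = []
    for annset, tag in ((genes, "gene"), (lncrnas, "lncRNA")):
        for g in annset:
            assert isinstance(g, GeneRecord)
            s = max(0, g.start - gene_extension_bp)
            e = g.end + gene_extension_bp
            contributions.append((g.chrom, s, e, f"{tag}±{gene_extension_bp}"))
            if uaRNA_window_bp > 0:
                if g.strand == "-":
                    us = g.tss + 1 + gene_extension_bp
                    ue = us + uaRNA_window_bp
                else:
                    ue = g.tss - gene_extension_bp
                    us = ue - uaRNA_window_bp
                us, ue = max(0, us), max(0, ue)
                if us < ue:
                    contributions.append((g.chrom, us, ue, "uaRNA"))
    for b in blacklist:
        contributions.append((b.chrom, b.start, b.end, "blacklist"))

    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom in sorted({c for c, *_ in contributions}):
        merged[chrom] = merge_pairs(
            [(s, e) for c, s, e, _ in contributions if c == chrom]
        )
    return ExclusionMask(merged=merged, contributions=sorted(contributions))


def filter_regions(
    regions: list[ERNARegion],
    mask: ExclusionMask,
) -> tuple[list[ERNARegion], pd.DataFrame]:
    """Drop every region overlapping the mask by >= 1 bp.

    Returns the surviving regions (sorted) and an audit table of dropped
    regions with the exclusion tags they hit.
    """
    index = mask.index()
    kept: list[ERNARegion] = []
    dropped: list[dict] = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start, r.end)):
        idx = index.get(r.chrom)
        if idx is not None and idx.overlaps_any(r.start, r.end):
            tags = sorted({
                tag for c, s, e, tag in mask.contributions
                if c == r.chrom and s < r.end and r.start < e
            })
            dropped.append({
                "erna_id": r.id, "chrom": r.chrom, "start": r.start,
                "end": r.end, "reason": ";".join(tags),
            })
        else:
            kept.append(r)
    audit = pd.DataFrame(dropped, columns=["erna_id", "chrom", "start", "end", "reason"])
    return kept, audit


def merge_overlapping_regions(regions: list[ERNARegion]) -> list[ERNARegion]:
    """Optionally collapse overlapping surviving regions into one region per
    merged span (off by default: the analysis counts one eRNA per consensus
    enhancer)."""
    by_chrom: dict[str, list[ERNARegion]] = {}
    for r in regions:
        by_chrom.setdefault(r.chrom, []).append(r)
    merged: list[ERNARegion] = []
    for chrom in sorted(by_chrom):
        for s, e in merge_pairs([(r.start, r.end) for r in by_chrom[chrom]]):
            mid = (s + e) // 2
            merged.append(ERNARegion(
                id=f"erna_{chrom}_{mid}",
                interval=GenomicInterval(chrom=chrom, start=s, end=e,
                                         id=f"erna_{chrom}_{mid}"),
                midpoint=mid))
    return merged


def regions_to_annotation(regions: list[ERNARegion]) -> AnnotationSet:
    return AnnotationSet(
        role="enhancer", source="erna_regions",
        intervals=[r.interval for r in regions],
    )
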