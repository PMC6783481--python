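"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats:

* BED (3-6 columns) for enhancers, blacklist regions and reads-as-intervals.
  Coordinates stay 0-based half-open exactly as in the file.
* "GTF-lite": a 12-column TSV gene table documented in the README
  (chrom, start, end, id, score, strand, tss, tes, n_exons,
  exon_starts, exon_ends, role). Comma-separated exon coordinate lists,
  all 0-based half-open. GTF-style 1-based inputs must be converted by the
  caller; the package keeps a single internal convention.
* TSV matrices: header row of sample IDs, first column of feature IDs; "NA"
  or empty cells are missing values handled pairwise-complete downstream.
* Hi-C contacts: TSV with columns tissue, chrom, bin_a, bin_b, oe
  (intra-chromosomal contacts; bins are bin-start coordinates; keys are
  unordered because contact maps are symmetric).
* Sample metadata: TSV with columns sample, patient, cohort, condition,
  subtype, stage, grade, smoking, time, event.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import AnnotationSet, GeneRecord, GenomicInterval

FLOAT_FORMAT = "%.10g"

METADATA_COLUMNS = [
    "sample", "patient", "cohort", "condition",
    "subtype", "stage", "grade", "smoking", "time", "event",
]


def read_bed(path: str | Path, role: str, source: str) -> AnnotationSet:
    """Read a 3-6 column BED file into an :class:`AnnotationSet`."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start >= end ({start} >= {end})"
                )
            name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else None
            strand = fields[5] if len(fields) > 5 and fields[5] in ("+", "-") else "."
            try:
                intervals.append(
                    GenomicInterval(chrom=chrom, start=start, end=end,
                                    strand=strand, id=name)
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return AnnotationSet(role=role, source=source, intervals=intervals)


def write_bed(annset: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in annset:
            name = iv.id if iv.id is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_gene_table(path: str | Path, role: str = "gene",
                    source: str = "genes") -> AnnotationSet:
    """Read the 12-column GTF-lite gene table."""
    records: list[GeneRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 columns, got {len(f)}")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                gene_id, strand = f[3], f[5]
                tss, tes, n_exons = int(f[6]), int(f[7]), int(f[8])
                exon_starts = [int(x) for x in f[9].split(",") if x]
                exon_ends = [int(x) for x in f[10].split(",") if x]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed field") from exc
            if len(exon_starts) != n_exons or len(exon_ends) != n_exons:
                raise ValueError(f"{path}:{lineno}: exon count mismatch")
            try:
                records.append(GeneRecord(
                    chrom=chrom, start=start, end=end, strand=strand, id=gene_id,
                    tss=tss, tes=tes,
                    exons=tuple(zip(exon_starts, exon_ends)),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return AnnotationSet(role=role, source=source, intervals=records)


def write_gene_table(annset: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in annset:
            assert isinstance(g, GeneRecord)
            starts = ",".join(str(s) for s, _ in g.exons)
            ends = ",".join(str(e) for _, e in g.exons)
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.id}\t0\t{g.strand}"
                f"\t{g.tss}\t{g.tes}\t{len(g.exons)}\t{starts}\t{ends}\t{annset.role}\n"
            )


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a feature x sample TSV matrix; 'NA'/empty cells become NaN."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({c for c in header if header.count(c) > 1})[:3]
        raise ValueError(f"{path}: duplicate column IDs, e.g. {dup}")
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][:3].tolist()
        raise ValueError(f"{path}: duplicate row IDs, e.g. {dup}")
    # canonical row/column order: output must not depend on file ordering
    return df.sort_index().sort_index(axis=1)


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "id") -> None:
    df.sort_index().sort_index(axis=1).to_csv(path, sep="\t",
                                              index_label=index_label,
                                              float_format=FLOAT_FORMAT)


def read_hic(path: str | Path) -> pd.DataFrame:
    """Read Hi-C O/E records (tissue, chrom, bin_a, bin_b, oe)."""
    df = pd.read_csv(path, sep="\t",
                     dtype={"tissue": str, "chrom": str, "bin_a": np.int64,
                            "bin_b": np.int64, "oe": float})
    required = {"tissue", "chrom", "bin_a", "bin_b", "oe"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df


def write_hic(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_metadata(path: str | Path) -> pd.DataFrame:
    md = pd.read_csv(path, sep="\t", dtype={"sample": str, "patient": str})
    missing = [c for c in METADATA_COLUMNS if c not in md.columns]
    if missing:
        raise ValueError(f"{path}: metadata missing columns {missing}")
    if md["sample"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample IDs in metadata")
    return md.set_index("sample").sort_index()


def write_metadata(md: pd.DataFrame, path: str | Path) -> None:
    md.sort_index().to_csv(path, sep="\t", index_label="sample",
                           float_format=FLOAT_FORMAT)


def read_id_list(path: str | Path) -> list[str]:
    """Read a one-column ID list (e.g. the TF list)."""
    out = []
    with open(path) as fh:
        for line in fh:
            tok = line.strip()
            if tok and not tok.startswith("#"):
                out.append(tok)
    return out


def read_gene_sets(path: str | Path) -> pd.DataFrame:
    """Read two-column (set_name, gene) TSV used for pathways/CAGs/ICs and
    the drug->pathway map."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["set", "member"], dtype=str)
    return df


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, length = line.split("\t")[:2]
            out[chrom] = int(length)
    return out


def write_chrom_lengths(lengths: dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(lengths):
            fh.write(f"{chrom}\t{lengths[chrom]}\n")


def file_checksum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
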