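"""eRNA expression quantification and specificity classification.

Reads falling in an eRNA region (>=1 bp overlap; a read spanning k regions
counts toward all k) are summed per sample and normalised to reads per
million mapped reads (RPM). An eRNA is *detectable* in a cohort when its
mean RPM over the cohort's tumor samples reaches the detection threshold
(default 1; 5 as the stringent robustness cutoff). Detectable eRNAs are
classified by how many cohorts detect them: ubiquitous (>=10), intermediately
specific (2-9) or cohort-specific (exactly 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import AnnotationSet
from .regions import ERNARegion
from .stats import _midranks


@dataclass
class ExpressionMatrix:
    """Feature x sample expression with per-sample metadata.

    ``values`` may hold raw counts or RPM; ``library_sizes`` is total mapped
    reads per sample. ``metadata`` is indexed by sample and carries cohort,
    condition (tumor/normal), patient pairing and the clinical fields.
    """

    values: pd.DataFrame
    library_sizes: pd.Series | None = None
    metadata: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.values = self.values.sort_index()
        if (self.values.to_numpy(dtype=float) < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.metadata is not None:
            missing = self.values.columns.difference(self.metadata.index)
            if len(missing):
                raise ValueError(f"metadata missing samples: {list(missing)[:5]}")

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def features(self) -> pd.Index:
        return self.values.index

    def subset_samples(self, samples) -> "ExpressionMatrix":
        lib = self.library_sizes.loc[samples] if self.library_sizes is not None else None
        md = self.metadata.loc[samples] if self.metadata is not None else None
        return ExpressionMatrix(self.values[list(samples)], lib, md)

    def tumor_samples(self, cohort: str | None = None) -> list[str]:
        if self.metadata is None:
            raise ValueError("no metadata attached")
        md = self.metadata
        mask = md["condition"] == "tumor"
        if cohort is not None:
            mask &= md["cohort"] == cohort
        return [s for s in self.samples if mask.get(s, False)]


@dataclass
class DetectabilityTable:
    per_cohort: pd.DataFrame   # columns: erna_id, cohort, mean_rpm, detectable
    per_erna: pd.DataFrame     # index erna_id; n_cohorts_detected, erna_class

    cohorts: list[str] = field(default_factory=list)

    def detectable_ids(self, cohort: str) -> list[str]:
        pc = self.per_cohort
        sel = pc[(pc["cohort"] == cohort) & pc["detectable"]]
        return sorted(sel["erna_id"])


def count_overlaps(reads: AnnotationSet, regions: list[ERNARegion]) -> pd.DataFrame:
    """Count reads per (region, sample); >=1 bp overlap, no fractional
    assignment. Read sample IDs ride in the interval ``id`` field."""
    if not regions:
        raise ValueError("no regions to count against")
    samples = sorted({iv.id for iv in reads if iv.id is not None})
    s_index = {s: j for j, s in enumerate(samples)}
    region_ids = [r.id for r in regions]
    counts = np.zeros((len(regions), len(samples)), dtype=np.int64)

    by_chrom: dict[str, list[tuple[int, int, int]]] = {}
    for iv in reads:
        if iv.id is None:
            raise ValueError("read interval without sample ID")
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end, s_index[iv.id]))

    for i, reg in enumerate(regions):
        rows = by_chrom.get(reg.chrom)
        if not rows:
            continue
        arr = np.asarray(rows, dtype=np.int64)
        hit = (arr[:, 0] < reg.end) & (arr[:, 1] > reg.start)
        if hit.any():
            np.add.at(counts[i], arr[hit, 2], 1)
    return pd.DataFrame(counts, index=region_ids, columns=samples)


def rpm(counts: pd.DataFrame, library_sizes: pd.Series,
        metadata: pd.DataFrame | None = None) -> ExpressionMatrix:
    """RPM = count * 1e6 / library size."""
    lib = library_sizes.reindex(counts.columns)
    if lib.isna().any():
        raise ValueError("library size missing for some samples")
    if (lib <= 0).any():
        raise ValueError("library sizes must be strictly positive")
    # divide before scaling: the quotient count/library is identical (as a
    # real number) under joint scaling, so correctly-rounded division keeps
    # RPM bit-for-bit invariant when counts and library sizes scale together
    values = counts.div(lib, axis=1) * 1e6
    return ExpressionMatrix(values=values, library_sizes=lib, metadata=metadata)


def detectability(expr: ExpressionMatrix, threshold: float) -> DetectabilityTable:
    """Per-cohort detectability from tumor-sample mean RPM (inclusive >=)."""
    if expr.metadata is None:
        raise ValueError("detectability requires sample metadata")
    cohorts = sorted(expr.metadata.loc[list(expr.samples), "cohort"].unique())
    rows = []
    for cohort in cohorts:
        tumor = expr.tumor_samples(cohort)
        if not tumor:
            raise ValueError(f"cohort {cohort!r} has no tumor samples")
        means = expr.values[tumor].mean(axis=1)
        for erna_id, m in means.items():
            rows.append({"erna_id": erna_id, "cohort": cohort,
                         "mean_rpm": float(m), "detectable": bool(m >= threshold)})
    per_cohort = pd.DataFrame(rows).sort_values(["erna_id", "cohort"],
                                                ignore_index=True)
    n_det = (per_cohort[per_cohort["detectable"]]
             .groupby("erna_id").size()
             .reindex(expr.features, fill_value=0))
    per_erna = pd.DataFrame({
        "n_cohorts_detected": n_det.astype(int),
        "erna_class": classify_specificity(n_det),
    })
    return DetectabilityTable(per_cohort=per_cohort, per_erna=per_erna,
                              cohorts=list(cohorts))


def classify_specificity(n_cohorts_detected: pd.Series) -> pd.Series:
    """ubiquitous (>=10 cohorts), intermediate (2-9), specific (1),
    undetected (0)."""
    n = n_cohorts_detected.astype(int)
    out = pd.Series("undetected", index=n.index, dtype=object)
    out[n == 1] = "specific"
    out[(n >= 2) & (n <= 9)] = "intermediate"
    out[n >= 10] = "ubiquitous"
    return out


def sample_similarity(expr: ExpressionMatrix,
                      detectable_ids: list[str] | None = None) -> pd.DataFrame:
    """Pairwise Spearman similarity between samples over detectable eRNAs.

    A constant-expression sample gets NaN against every other sample; the
    diagonal is 1 by convention.
    """
    values = expr.values
    if detectable_ids is not None:
        values = values.loc[sorted(set(detectable_ids) & set(values.index))]
    if values.shape[1] < 2:
        raise ValueError("need >=2 samples for a similarity matrix")
    arr = values.to_numpy(dtype=float)
    ranks = np.apply_along_axis(_midranks, 0, arr)
    sd = ranks.std(axis=0)
    const = sd == 0
    sd_safe = np.where(const, 1.0, sd)
    z = (ranks - ranks.mean(axis=0)) / sd_safe
    sim = z.T @ z / arr.shape[0]
    np.clip(sim, -1.0, 1.0, out=sim)
    sim[const, :] = np.nan
    sim[:, const] = np.nan
    np.fill_diagonal(sim, 1.0)
    return pd.DataFrame(sim, index=values.columns, columns=values.columns)
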