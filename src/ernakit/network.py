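"""eRNA -> putative target gene network with Hi-C support.

A candidate pair is an eRNA region and a gene TSS on the same chromosome at
most ``max_link_distance_bp`` apart (inclusive), excluding eRNAs that lie
entirely inside an intron of that gene. Candidates become links when their
co-expression passes Rs >= ``rs_min`` at BH-FDR < ``fdr_max`` (BH over all
candidate pairs within the cohort). Each link is then looked up in per-tissue
Hi-C observed/expected (O/E) maps at the (region-midpoint bin, TSS bin) key;
O/E >= ``hic_oe_min`` counts as support in that tissue. The overall supported
fraction is compared against random region-gene pairs by a seeded permutation
test with the add-one empirical p-value ``(b + 1) / (n_permutations + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import AnnotationSet, GeneRecord
from .regions import ERNARegion
from .stats import bh_fdr, fisher_combine, spearman_matrix  # noqa: F401  (fisher_combine re-exported)

LINK_COLUMNS = ["erna_id", "gene_id", "cohort", "distance_bp", "n", "rs", "p", "q"]


@dataclass
class PermutationResult:
    observed_fraction: float
    n_permutations: int
    exceedances: int
    p_empirical: float


def candidate_pairs(
    regions: list[ERNARegion],
    genes: AnnotationSet,
    max_link_distance_bp: int,
) -> pd.DataFrame:
    """Distance-eligible (eRNA, gene) pairs with intronic eRNAs removed.

    Distance is |region midpoint - gene TSS|, same chromosome, inclusive
    threshold. A pair is dropped when the region lies entirely within one
    intron of that gene.
    """
    rows = []
    gene_list: list[GeneRecord] = []
    for g in genes:
        if not isinstance(g, GeneRecord) or g.tss < 0:
            raise ValueError(f"gene {g.id!r} lacks a TSS")
        gene_list.append(g)
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in gene_list:
        by_chrom.setdefault(g.chrom, []).append(g)
    for r in regions:
        for g in by_chrom.get(r.chrom, ()):
            dist = abs(r.midpoint - g.tss)
            if dist > max_link_distance_bp:
                continue
            intronic = any(
                s <= r.start and r.end <= e for s, e in g.introns()
            )
            if intronic:
                continue
            rows.append({"erna_id": r.id, "gene_id": g.id,
                         "distance_bp": int(dist)})
    return (pd.DataFrame(rows, columns=["erna_id", "gene_id", "distance_bp"])
            .sort_values(["erna_id", "gene_id"], ignore_index=True))


def correlate_links(
    pairs: pd.DataFrame,
    expr_erna: pd.DataFrame,
    expr_gene: pd.DataFrame,
    cohort: str,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Keep candidate pairs whose co-expression passes the edge thresholds."""
    pairs = pairs[pairs["erna_id"].isin(expr_erna.index)
                  & pairs["gene_id"].isin(expr_gene.index)]
    if pairs.empty:
        return pd.DataFrame(columns=LINK_COLUMNS)
    ernas = sorted(pairs["erna_id"].unique())
    gene_ids = sorted(pairs["gene_id"].unique())
    rs, p, n = spearman_matrix(expr_erna.loc[ernas], expr_gene.loc[gene_ids],
                               min_n=config.min_pairs_complete)
    ei = pairs["erna_id"].map({e: i for i, e in enumerate(ernas)}).to_numpy()
    gi = pairs["gene_id"].map({g: i for i, g in enumerate(gene_ids)}).to_numpy()
    out = pairs.copy()
    out["n"] = n.to_numpy()[ei, gi]
    out["rs"] = rs.to_numpy()[ei, gi]
    out["p"] = p.to_numpy()[ei, gi]
    out = out[np.isfinite(out["p"])].reset_index(drop=True)
    if out.empty:
        return pd.DataFrame(columns=LINK_COLUMNS)
    out["q"] = bh_fdr(out["p"])
    out["cohort"] = cohort
    sig = out["rs"].abs() >= config.rs_min if config.rs_absolute \
        else out["rs"] >= config.rs_min
    links = out[sig & (out["q"] < config.fdr_max)]
    return (links[LINK_COLUMNS]
            .sort_values(["erna_id", "gene_id"], ignore_index=True))


class HiCIndex:
    """Per-tissue O/E lookup keyed by unordered (chrom, bin, bin) pairs."""

    def __init__(self, triples: pd.DataFrame, bin_bp: int):
        self.bin_bp = int(bin_bp)
        self.tissues = sorted(triples["tissue"].unique())
        self.maps: dict[str, dict[tuple[str, int, int], float]] = {
            t: {} for t in self.tissues}
        ba = triples["bin_a"].to_numpy()
        bb = triples["bin_b"].to_numpy()
        lo, hi = np.minimum(ba, bb), np.maximum(ba, bb)
        for tissue, chrom, l, h, oe in zip(triples["tissue"],
                                           triples["chrom"], lo, hi,
                                           triples["oe"]):
            self.maps[tissue][(chrom, int(l), int(h))] = float(oe)

    def bin_of(self, pos: int) -> int:
        return (int(pos) // self.bin_bp) * self.bin_bp

    def oe(self, tissue: str, chrom: str, pos_a: int, pos_b: int) -> float:
        a, b = self.bin_of(pos_a), self.bin_of(pos_b)
        key = (chrom, a, b) if a <= b else (chrom, b, a)
        return self.maps[tissue].get(key, np.nan)


def hic_support(
    links: pd.DataFrame,
    hic: HiCIndex,
    region_midpoints: dict[str, tuple[str, int]],
    gene_tss: dict[str, tuple[str, int]],
    hic_oe_min: float,
) -> pd.DataFrame:
    """Per-link, per-tissue O/E values and support counts.

    ``region_midpoints``/``gene_tss`` map IDs to (chrom, position). A missing
    bin pair (or a cross-chromosome pair) is a missing value and counts as
    unsupported in that tissue.
    """
    rows = []
    for erna_id, gene_id in zip(links["erna_id"], links["gene_id"]):
        r_chrom, r_pos = region_midpoints[erna_id]
        g_chrom, g_pos = gene_tss[gene_id]
        row: dict = {"erna_id": erna_id, "gene_id": gene_id}
        n_sup = 0
        for tissue in hic.tissues:
            oe = hic.oe(tissue, r_chrom, r_pos, g_pos) \
                if r_chrom == g_chrom else np.nan
            row[f"oe_{tissue}"] = oe
            if np.isfinite(oe) and oe >= hic_oe_min:
                n_sup += 1
        row["supported_tissues"] = n_sup
        row["supported_any"] = n_sup >= 1
        rows.append(row)
    cols = (["erna_id", "gene_id"] + [f"oe_{t}" for t in hic.tissues]
            + ["supported_tissues", "supported_any"])
    return pd.DataFrame(rows, columns=cols)


def permutation_enrichment(
    links: pd.DataFrame,
    all_regions: list[ERNARegion],
    all_genes: AnnotationSet,
    hic: HiCIndex,
    n_permutations: int,
    seed: int,
    hic_oe_min: float = 1.0,
    max_link_distance_bp: int | None = None,
) -> PermutationResult:
    """Permutation test of the Hi-C-supported fraction against random pairs.

    Each permutation draws ``len(links)`` random (region, gene) pairs
    genome-wide without replacement within the permutation (pass
    ``max_link_distance_bp`` for the distance-matched background variant) and
    records its supported-in-any-tissue fraction; ``b`` counts permutations
    with fraction >= observed and ``p = (b + 1) / (n_permutations + 1)``.
    """
    m = len(links)
    if m == 0:
        raise ValueError("no links to test")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    genes = [g for g in all_genes]
    region_mid = {r.id: (r.chrom, r.midpoint) for r in all_regions}
    tss = {g.id: (g.chrom, g.tss) for g in genes}  # type: ignore[attr-defined]

    # precompute supported_any over the full region x gene universe once
    n_r, n_g = len(all_regions), len(genes)
    support = np.zeros((n_r, n_g), dtype=bool)
    eligible = np.ones((n_r, n_g), dtype=bool)
    for i, r in enumerate(all_regions):
        for j, g in enumerate(genes):
            if r.chrom != g.chrom:
                if max_link_distance_bp is not None:
                    eligible[i, j] = False
                continue
            dist = abs(r.midpoint - g.tss)  # type: ignore[attr-defined]
            if max_link_distance_bp is not None and dist > max_link_distance_bp:
                eligible[i, j] = False
                continue
            for tissue in hic.tissues:
                oe = hic.oe(tissue, r.chrom, r.midpoint, g.tss)  # type: ignore[attr-defined]
                if np.isfinite(oe) and oe >= hic_oe_min:
                    support[i, j] = True
                    break

    r_index = {r.id: i for i, r in enumerate(all_regions)}
    g_index = {g.id: j for j, g in enumerate(genes)}
    obs_idx = [
        (r_index[e], g_index[g]) for e, g in zip(links["erna_id"], links["gene_id"])
    ]
    observed = float(np.mean([support[i, j] for i, j in obs_idx]))

    flat_support = support.ravel()
    flat_pool = np.flatnonzero(eligible.ravel())
    if len(flat_pool) < m:
        raise ValueError("background pool smaller than the number of links")
    rng = np.random.default_rng(seed)
    fractions = np.empty(n_permutations)
    for b_i in range(n_permutations):
        idx = rng.choice(flat_pool, size=m, replace=False)
        fractions[b_i] = flat_support[idx].mean()
    b = int(np.sum(fractions >= observed))
    p = (b + 1) / (n_permutations + 1)
    return PermutationResult(observed_fraction=observed,
                             n_permutations=n_permutations,
                             exceedances=b, p_empirical=p)


def annotate_pathways(
    links: pd.DataFrame,
    pathway_sets: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pathway labels per link (via the target gene) and per-eRNA membership.

    ``pathway_sets`` has columns (set, member); a gene in several pathways
    yields one labelled row per pathway.
    """
    labelled = links.merge(pathway_sets.rename(
        columns={"set": "pathway", "member": "gene_id"}), on="gene_id", how="inner")
    labelled = labelled.sort_values(["erna_id", "gene_id", "pathway"],
                                    ignore_index=True)
    per_erna = (labelled.groupby("erna_id")["pathway"]
                .agg(lambda s: sorted(set(s)))
                .rename("pathways").reset_index())
    return labelled, per_erna
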