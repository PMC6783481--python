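"""Synthetic multi-cohort data generator with planted, recoverable effects.

Everything the pipeline consumes can be generated from one seed: a toy
genome (genes with exon structure, lncRNAs, blacklist), three enhancer
annotation sources with controllable cross-source overlap, negative-binomial
count matrices whose rank-correlation structure is planted through a latent
Gaussian copula, per-tissue Hi-C O/E triples with elevated contacts at true
eRNA-gene links, drug-response AUC matrices with planted correlations, and
exponential survival times with planted log-hazard effects.

The copula device: two latent standard normals correlated at ``rho`` map
through a monotone transform to negative-binomial means, so the Spearman
correlation of the resulting counts approaches the analytic Gaussian-copula
value ``(6 / pi) * asin(rho / 2)`` — which makes planted correlations
quantitatively recoverable, not just directionally.

Every planted effect is written to a truth ledger keyed by the IDs that
appear in the generated files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .intervals import AnnotationSet, GeneRecord, GenomicInterval, IntervalIndex
from .regions import (
    ERNARegion,
    build_exclusion_mask,
    consensus_enhancers,
    define_regions,
    filter_regions,
)


def copula_spearman(rho: float) -> float:
    """Analytic Spearman correlation of a bivariate Gaussian copula."""
    return 6.0 / math.pi * math.asin(rho / 2.0)


@dataclass
class CohortSpec:
    name: str
    n_tumor: int
    n_paired_normal: int


@dataclass
class SimulationDesign:
    """Study-design parameters of the synthetic cohort.

    Defaults describe the conditions the pipeline is exercised under:
    three tumor cohorts of 60 tumors with 30 paired normals each, a
    100-line cell-line panel with 30 drugs, three enhancer sources with 60%
    cross-source overlap, 20 Hi-C tissues, and planted effects sized like
    the signals the method is meant to detect (master TF driving 40% of
    eRNAs at copula rho 0.6; eRNA-gene links at rho 0.5; tumor/normal fold
    change 4; drug correlations at |rho| 0.6; hazard ratio 2 per SD).
    """

    # genome
    n_chroms: int = 4
    chrom_length_bp: int = 3_000_000
    n_genes: int = 120
    n_lncRNAs: int = 25
    gene_length_bp: tuple[int, int] = (3_000, 8_000)
    lnc_length_bp: tuple[int, int] = (1_000, 4_000)
    exons_per_gene: tuple[int, int] = (2, 5)
    n_blacklist: int = 16
    blacklist_length_bp: tuple[int, int] = (500, 2_000)
    # enhancers
    n_enhancers: int = 110
    enhancer_length_bp: tuple[int, int] = (400, 1_000)
    cross_source_overlap_frac: float = 0.6
    enhancer_jitter_bp: int = 200
    masked_enhancer_frac: float = 0.12
    # cohorts
    cohorts: list[CohortSpec] = field(default_factory=lambda: [
        CohortSpec("C1", 60, 30),
        CohortSpec("C2", 60, 30),
        CohortSpec("C3", 60, 30),
    ])
    n_cell_lines: int = 100
    n_drugs: int = 30
    n_TFs: int = 12
    # expression model
    nb_dispersion: float = 0.05       # NB variance = mu + dispersion * mu^2
    mean_library_size: float = 2e6
    library_size_sigma: float = 0.1
    latent_sigma: float = 1.2         # log-scale spread of expression
    pairing_weight: float = 0.3       # shared patient-latent variance fraction
    erna_active_rpm: tuple[float, float] = (3.0, 30.0)
    erna_inactive_rpm: float = 0.05
    gene_base_rpm: tuple[float, float] = (5.0, 100.0)
    # planted effects (counts; identities are drawn from the seed and
    # recorded in the truth ledger)
    master_tf: bool = True
    master_driven_fraction: float = 0.4
    master_rho: float = 0.6
    n_planted_links: int = 20
    link_rho: float = 0.5
    n_planted_de: int = 15
    de_fold_change: float = 4.0
    n_planted_drug: int = 10
    drug_rho: float = 0.6
    n_planted_hazard: int = 3
    hazard_log_hr: float = math.log(2.0)
    n_planted_subtype: int = 5
    subtype_shift_sd: float = 2.0     # shift in latent-SD units
    baseline_median_survival: float = 24.0
    censoring_rate_factor: float = 0.43   # ~30% independent censoring
    # Hi-C
    n_tissues: int = 20
    hic_coverage: float = 0.1
    hic_background_sigma: float = 0.5
    hic_enrichment_factor: float = 10.0
    hic_enriched_tissue_count: int = 20
    # pathways
    n_pathways: int = 10
    pathway_size: tuple[int, int] = (3, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rho in (("master_rho", self.master_rho),
                          ("link_rho", self.link_rho),
                          ("drug_rho", self.drug_rho)):
            if not -1.0 < rho < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")
        if not 0.0 <= self.cross_source_overlap_frac <= 1.0:
            raise ValueError("cross_source_overlap_frac must lie in [0, 1]")
        for name in ("n_chroms", "chrom_length_bp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticTruth:
    """Ledger of every planted effect, keyed by generated IDs."""

    tables: dict[str, pd.DataFrame] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in sorted(self.tables.items()):
            df.to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False,
                      float_format="%.10g")


@dataclass
class SyntheticBundle:
    design: SimulationDesign
    chrom_lengths: dict[str, int]
    genes: AnnotationSet
    lncrnas: AnnotationSet
    blacklist: AnnotationSet
    enhancer_sources: list[AnnotationSet]
    regions: list[ERNARegion]
    counts: pd.DataFrame            # feature x sample (tumor/normal cohorts)
    library_sizes: pd.Series
    metadata: pd.DataFrame          # indexed by sample
    cell_counts: pd.DataFrame       # feature x cell line
    cell_library_sizes: pd.Series
    auc: pd.DataFrame               # drug x cell line
    hic: pd.DataFrame               # tissue, bin_a, bin_b, oe
    tf_ids: list[str]
    pathway_sets: pd.DataFrame      # set, member (pathway -> gene)
    drug_pathways: pd.DataFrame     # set, member (pathway -> drug)
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------

def _place_nonoverlapping(rng, n: int, lengths: np.ndarray, chrom_len: int,
                          occupied: list[tuple[int, int]],
                          max_tries: int = 2000) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = []
    occ = list(occupied)
    for L in lengths:
        ok = False
        for _ in range(max_tries):
            s = int(rng.integers(0, max(1, chrom_len - L)))
            e = s + int(L)
            if all(e <= a or b <= s for a, b in occ):
                occ.append((s, e))
                placed.append((s, e))
                ok = True
                break
        if not ok:
            raise RuntimeError(
                "could not place features without overlap; "
                "increase chrom_length_bp or reduce feature counts"
            )
    return placed


def simulate_genome(design: SimulationDesign,
                    rng: np.random.Generator | None = None
                    ) -> tuple[AnnotationSet, AnnotationSet, AnnotationSet,
                               dict[str, int]]:
    """Place non-overlapping genes, lncRNAs and a blacklist on toy
    chromosomes by rejection sampling; each gene gets 2-5 exons."""
    rng = rng if rng is not None else np.random.default_rng(design.seed)
    chrom_lengths = {f"chr{i + 1}": design.chrom_length_bp
                     for i in range(design.n_chroms)}
    chroms = sorted(chrom_lengths)

    def _make_records(n, length_range, prefix, with_exons):
        records = []
        per_chrom = np.array_split(np.arange(n), len(chroms))
        for chrom, idxs in zip(chroms, per_chrom):
            if len(idxs) == 0:
                continue
            lens = rng.integers(length_range[0], length_range[1] + 1,
                                size=len(idxs))
            occupied = occupied_by_chrom.get(chrom, [])
            spans = _place_nonoverlapping(rng, len(idxs), lens,
                                          chrom_lengths[chrom], occupied)
            occupied_by_chrom.setdefault(chrom, []).extend(spans)
            for k, (s, e) in zip(idxs, spans):
                strand = "+" if rng.random() < 0.5 else "-"
                tss, tes = (s, e - 1) if strand == "+" else (e - 1, s)
                if with_exons:
                    n_ex = int(rng.integers(design.exons_per_gene[0],
                                            design.exons_per_gene[1] + 1))
                    cuts = np.sort(rng.choice(
                        np.arange(s + 1, e), size=2 * n_ex - 2, replace=False))
                    bounds = [s, *cuts.tolist(), e]
                    exons = tuple(
                        (bounds[2 * i], bounds[2 * i + 1]) for i in range(n_ex)
                    )
                else:
                    exons = ((s, e),)
                records.append(GeneRecord(
                    chrom=chrom, start=int(s), end=int(e), strand=strand,
                    id=f"{prefix}{k:04d}", tss=int(tss), tes=int(tes),
                    exons=exons))
        return records

    occupied_by_chrom: dict[str, list[tuple[int, int]]] = {}
    genes = _make_records(design.n_genes, design.gene_length_bp, "g", True)
    lncs = _make_records(design.n_lncRNAs, design.lnc_length_bp, "lnc", False)

    bl: list[GenomicInterval] = []
    per_chrom = np.array_split(np.arange(design.n_blacklist), len(chroms))
    for chrom, idxs in zip(chroms, per_chrom):
        if len(idxs) == 0:
            continue
        lens = rng.integers(design.blacklist_length_bp[0],
                            design.blacklist_length_bp[1] + 1, size=len(idxs))
        for k, L in zip(idxs, lens):
            s = int(rng.integers(0, chrom_lengths[chrom] - int(L)))
            bl.append(GenomicInterval(chrom=chrom, start=s, end=s + int(L),
                                      id=f"bl{k:03d}"))

    return (
        AnnotationSet(role="gene", source="synthetic", intervals=genes),
        AnnotationSet(role="lncRNA", source="synthetic", intervals=lncs),
        AnnotationSet(role="blacklist", source="synthetic", intervals=bl),
        chrom_lengths,
    )


# ---------------------------------------------------------------------------
# enhancers
# ---------------------------------------------------------------------------

def simulate_enhancers(
    design: SimulationDesign,
    mask_index: dict[str, IntervalIndex],
    chrom_lengths: dict[str, int],
    config: PipelineConfig,
    rng: np.random.Generator,
) -> tuple[list[AnnotationSet], pd.DataFrame]:
    """Three enhancer sources with known multi-source ground truth.

    A fraction ``cross_source_overlap_frac`` of base enhancers is duplicated
    (with +/- jitter) into one or two additional sources, so which enhancers
    survive the >=2-source consensus is known in advance. Base enhancer
    midpoints are separated by more than 2x the region flank so each base
    enhancer yields exactly one consensus run, and a ``masked_enhancer_frac``
    fraction is deliberately placed inside the exclusion mask to exercise
    region filtering.
    """
    chroms = sorted(chrom_lengths)
    flank = config.flank_bp
    min_sep = 2 * flank + 2 * design.enhancer_jitter_bp + design.enhancer_length_bp[1]
    rows = []
    sources: dict[str, list[GenomicInterval]] = {"s1": [], "s2": [], "s3": []}
    placed_mids: dict[str, list[int]] = {c: [] for c in chroms}
    per_chrom = np.array_split(np.arange(design.n_enhancers), len(chroms))
    for chrom, idxs in zip(chroms, per_chrom):
        idx_mask = mask_index.get(chrom)
        clen = chrom_lengths[chrom]
        for k in idxs:
            L = int(rng.integers(design.enhancer_length_bp[0],
                                 design.enhancer_length_bp[1] + 1))
            want_masked = rng.random() < design.masked_enhancer_frac
            mid = None
            for _ in range(5000):
                cand = int(rng.integers(flank + L, clen - flank - L))
                if any(abs(cand - m) < min_sep for m in placed_mids[chrom]):
                    continue
                reg_s, reg_e = cand - flank, cand + flank
                in_mask = bool(idx_mask.overlaps_any(reg_s, reg_e)) \
                    if idx_mask is not None else False
                if in_mask == want_masked:
                    mid = cand
                    break
            if mid is None:
                # fall back to any clear placement
                for _ in range(5000):
                    cand = int(rng.integers(flank + L, clen - flank - L))
                    if all(abs(cand - m) >= min_sep for m in placed_mids[chrom]):
                        mid = cand
                        want_masked = bool(
                            idx_mask.overlaps_any(cand - flank, cand + flank)
                        ) if idx_mask is not None else False
                        break
            if mid is None:
                raise RuntimeError("could not place enhancers; "
                                   "increase chrom_length_bp")
            placed_mids[chrom].append(mid)
            s, e = mid - L // 2, mid + (L - L // 2)
            enh_id = f"enh{k:04d}"
            dup = rng.random() < design.cross_source_overlap_frac
            srcs = ["s1"]
            if dup:
                extra = ["s2", "s3"] if rng.random() < 0.5 else ["s2"]
                srcs += extra
            spans = []
            for src in srcs:
                if src == "s1":
                    js, je = s, e
                else:
                    j = int(rng.integers(-design.enhancer_jitter_bp,
                                         design.enhancer_jitter_bp + 1))
                    js, je = s + j, e + j
                spans.append((js, je))
                sources[src].append(GenomicInterval(
                    chrom=chrom, start=js, end=je, id=f"{enh_id}_{src}"))
            # the consensus run is the union span of the base enhancer and
            # its jittered copies; the region follows its midpoint
            u_s = min(js for js, _ in spans)
            u_e = max(je for _, je in spans)
            region_mid = (u_s + u_e) // 2
            reg_s = max(0, region_mid - flank)
            reg_e = min(clen, region_mid + flank)
            in_mask = bool(idx_mask.overlaps_any(reg_s, reg_e)) \
                if idx_mask is not None else False
            rows.append({
                "enhancer_id": enh_id, "chrom": chrom, "start": s, "end": e,
                "midpoint": region_mid,
                "sources": ",".join(srcs), "n_sources": len(srcs),
                "multi_source": len(srcs) >= config.min_sources,
                "in_mask": in_mask,
                "expected_region_id": f"erna_{chrom}_{region_mid}",
                "expected_survives": len(srcs) >= config.min_sources
                                     and not in_mask,
            })
    annsets = [AnnotationSet(role="enhancer", source=name, intervals=ivs)
               for name, ivs in sorted(sources.items())]
    return annsets, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """NB draws with variance mu + dispersion * mu^2 (gamma-Poisson)."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam)


def simulate_all(design: SimulationDesign,
                 config: PipelineConfig | None = None,
                 outdir: str | Path | None = None) -> SyntheticBundle:
    """Generate the full synthetic bundle; optionally write it to disk in
    the exact formats the pipeline readers consume."""
    config = config or PipelineConfig(seed=design.seed)
    rng = np.random.default_rng(design.seed)
    truth = SyntheticTruth()

    genes, lncs, blacklist, chrom_lengths = simulate_genome(design, rng)
    mask = build_exclusion_mask(genes, lncs, blacklist,
                                config.gene_extension_bp,
                                config.uaRNA_window_bp)
    enhancer_sources, enh_truth = simulate_enhancers(
        design, mask.index(), chrom_lengths, config, rng)
    truth.tables["enhancers"] = enh_truth

    consensus = consensus_enhancers(enhancer_sources, config.min_sources)
    regions_all = define_regions(consensus, config.flank_bp, chrom_lengths)
    regions, _audit = filter_regions(regions_all, mask)

    gene_ids = sorted(g.id for g in genes)
    tf_ids = gene_ids[:design.n_TFs]
    erna_ids = [r.id for r in regions]
    features = gene_ids + erna_ids
    n_genes, n_ernas = len(gene_ids), len(erna_ids)
    n_feat = len(features)
    f_index = {f: i for i, f in enumerate(features)}

    cohort_names = [c.name for c in design.cohorts]

    # base RPM: genes expressed everywhere; each eRNA active in a random
    # non-empty cohort subset (this is what makes specificity classes and
    # cohort-distinct expression programs exist)
    gene_base = np.exp(rng.uniform(np.log(design.gene_base_rpm[0]),
                                   np.log(design.gene_base_rpm[1]),
                                   size=n_genes))
    erna_active_base = np.exp(rng.uniform(np.log(design.erna_active_rpm[0]),
                                          np.log(design.erna_active_rpm[1]),
                                          size=n_ernas))
    active = np.zeros((n_ernas, len(cohort_names)), dtype=bool)
    for i in range(n_ernas):
        k = int(rng.integers(1, len(cohort_names) + 1))
        cols = rng.choice(len(cohort_names), size=k, replace=False)
        active[i, cols] = True

    master_tf_id = tf_ids[0] if design.master_tf else None
    n_driven = int(round(design.master_driven_fraction * n_ernas))
    driven_idx = np.sort(rng.choice(n_ernas, size=n_driven, replace=False)) \
        if master_tf_id else np.array([], dtype=int)
    # master-driven eRNAs must be detectable to enter the master fraction
    active[driven_idx, :] = True
    if master_tf_id:
        truth.tables["planted_master"] = pd.DataFrame({
            "tf_id": [master_tf_id] * len(driven_idx),
            "erna_id": [erna_ids[i] for i in driven_idx],
            "rho": [design.master_rho] * len(driven_idx),
            "expected_spearman":
                [copula_spearman(design.master_rho)] * len(driven_idx),
        })

    # eRNA-gene links: eligible pairs <= 1 Mb, non-intronic, gene not a TF
    eligible_pairs = []
    gene_by_id = {g.id: g for g in genes}
    for ri, r in enumerate(regions):
        for gid in gene_ids[design.n_TFs:]:
            g = gene_by_id[gid]
            if g.chrom != r.chrom:
                continue
            if abs(r.midpoint - g.tss) > config.max_link_distance_bp:
                continue
            if any(s <= r.start and r.end <= e for s, e in g.introns()):
                continue
            eligible_pairs.append((ri, gid))
    rng.shuffle(eligible_pairs)
    used_genes: set[str] = set()
    link_list: list[tuple[int, str]] = []
    for ri, gid in eligible_pairs:
        if gid in used_genes:
            continue
        link_list.append((ri, gid))
        used_genes.add(gid)
        if len(link_list) >= design.n_planted_links:
            break
    for ri, _ in link_list:
        active[ri, :] = True
    truth.tables["planted_links"] = pd.DataFrame({
        "erna_id": [erna_ids[ri] for ri, _ in link_list],
        "gene_id": [gid for _, gid in link_list],
        "rho": [design.link_rho] * len(link_list),
        "expected_spearman":
            [copula_spearman(design.link_rho)] * len(link_list),
    })

    def _pick_ernas(n: int, exclude: set[int] = frozenset()) -> list[int]:
        pool = [i for i in np.flatnonzero(active.all(axis=1))
                if i not in exclude]
        n = min(n, len(pool))
        return sorted(rng.choice(pool, size=n, replace=False).tolist())

    de_idx = _pick_ernas(design.n_planted_de)
    truth.tables["planted_de"] = pd.DataFrame({
        "erna_id": [erna_ids[i] for i in de_idx],
        "fold_change": [design.de_fold_change] * len(de_idx),
    })
    hazard_idx = _pick_ernas(design.n_planted_hazard, set(de_idx))
    truth.tables["planted_hazard"] = pd.DataFrame({
        "erna_id": [erna_ids[i] for i in hazard_idx],
        "log_hr_per_sd": [design.hazard_log_hr] * len(hazard_idx),
    })
    subtype_idx = _pick_ernas(design.n_planted_subtype,
                              set(de_idx) | set(hazard_idx))
    truth.tables["planted_subtype"] = pd.DataFrame({
        "erna_id": [erna_ids[i] for i in subtype_idx],
        "shift_sd": [design.subtype_shift_sd] * len(subtype_idx),
    })
    truth.tables["erna_activity"] = pd.DataFrame({
        "erna_id": erna_ids,
        "active_cohorts": [",".join(c for c, a in zip(cohort_names, row) if a)
                           for row in active],
        "base_rpm": erna_active_base,
    })
    drug_idx = _pick_ernas(design.n_planted_drug)
    drug_ids = [f"drug{j:03d}" for j in range(design.n_drugs)]
    planted_drugs = rng.choice(design.n_drugs,
                               size=min(design.n_planted_drug, design.n_drugs),
                               replace=False)
    drug_rows = []
    for t, (ei, dj) in enumerate(zip(drug_idx, planted_drugs)):
        rho = design.drug_rho if t % 2 else -design.drug_rho
        drug_rows.append({"erna_id": erna_ids[ei], "drug_id": drug_ids[dj],
                          "rho": rho,
                          "expected_direction":
                              "resistant" if rho > 0 else "sensitive"})
    truth.tables["planted_drug"] = pd.DataFrame(
        drug_rows, columns=["erna_id", "drug_id", "rho", "expected_direction"])

    # ------------------------------------------------------------------
    # per-cohort latent draws -> NB counts
    # ------------------------------------------------------------------
    master_i = f_index[master_tf_id] if master_tf_id else None
    sigma = design.latent_sigma

    def _mix(z_driver: np.ndarray, z_own: np.ndarray, rho: float) -> np.ndarray:
        return rho * z_driver + math.sqrt(1.0 - rho * rho) * z_own

    def _latents(n_samples: int) -> np.ndarray:
        z = rng.standard_normal((n_feat, n_samples))
        if master_i is not None:
            for ri in driven_idx:
                fi = f_index[erna_ids[ri]]
                z[fi] = _mix(z[master_i], z[fi], design.master_rho)
        for ri, gid in link_list:
            fe, fg = f_index[erna_ids[ri]], f_index[gid]
            z[fg] = _mix(z[fe], z[fg], design.link_rho)
        return z

    def _base_rpm(cohort_col: int | None) -> np.ndarray:
        base = np.empty(n_feat)
        base[:n_genes] = gene_base
        if cohort_col is None:
            base[n_genes:] = erna_active_base   # cell lines: all active
        else:
            on = active[:, cohort_col]
            base[n_genes:] = np.where(on, erna_active_base,
                                      design.erna_inactive_rpm)
        return base

    def _counts_from_latents(z: np.ndarray, base: np.ndarray,
                             lib: np.ndarray,
                             mult: np.ndarray | None = None) -> np.ndarray:
        mu_rpm = base[:, None] * np.exp(sigma * z - 0.5 * sigma * sigma)
        if mult is not None:
            mu_rpm = mu_rpm * mult
        mu_counts = mu_rpm * (lib[None, :] / 1e6)
        return _nb_counts(rng, mu_counts, design.nb_dispersion)

    all_counts: list[pd.DataFrame] = []
    lib_sizes: dict[str, float] = {}
    meta_rows: list[dict] = []
    rate0 = math.log(2.0) / design.baseline_median_survival
    subtype_levels = ["su1", "su2", "su3"]
    stage_levels = ["st1", "st2", "st3", "st4"]
    grade_levels = ["g1", "g2", "g3"]
    smoking_levels = ["never", "ever"]

    for ci, spec in enumerate(design.cohorts):
        nt, nn = spec.n_tumor, spec.n_paired_normal
        if nn > nt:
            raise ValueError(f"cohort {spec.name}: more normals than tumors")
        t_samples = [f"{spec.name}_T{i:03d}" for i in range(nt)]
        n_samples_ids = [f"{spec.name}_N{i:03d}" for i in range(nn)]
        patients = [f"{spec.name}_P{i:03d}" for i in range(nt)]

        subtype = rng.choice(subtype_levels, size=nt)
        stage = rng.choice(stage_levels, size=nt)
        grade = rng.choice(grade_levels, size=nt)
        smoking = rng.choice(smoking_levels, size=nt)

        z_t = _latents(nt)
        w = design.pairing_weight
        z_n = (math.sqrt(w) * z_t[:, :nn]
               + math.sqrt(1.0 - w) * rng.standard_normal((n_feat, nn)))

        base = _base_rpm(ci)
        lib_t = np.exp(rng.normal(math.log(design.mean_library_size),
                                  design.library_size_sigma, size=nt))
        lib_n = np.exp(rng.normal(math.log(design.mean_library_size),
                                  design.library_size_sigma, size=nn))

        mult_t = np.ones((n_feat, nt))
        for i in de_idx:
            mult_t[f_index[erna_ids[i]], :] *= design.de_fold_change
        shift = math.exp(design.subtype_shift_sd * sigma)
        sub0 = subtype == subtype_levels[0]
        for i in subtype_idx:
            mult_t[f_index[erna_ids[i]], sub0] *= shift

        c_t = _counts_from_latents(z_t, base, lib_t, mult_t)
        c_n = _counts_from_latents(z_n, base, lib_n)

        rpm_t = c_t * (1e6 / lib_t[None, :])
        log_rate = np.full(nt, math.log(rate0))
        for i in hazard_idx:
            xr = rpm_t[f_index[erna_ids[i]]]
            sd = xr.std()
            zts = (xr - xr.mean()) / sd if sd > 0 else np.zeros(nt)
            log_rate += design.hazard_log_hr * zts
        t_event = rng.exponential(1.0 / np.exp(log_rate))
        t_cens = rng.exponential(
            1.0 / (design.censoring_rate_factor * rate0), size=nt)
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)

        for j, s in enumerate(t_samples):
            lib_sizes[s] = float(lib_t[j])
            meta_rows.append({
                "sample": s, "patient": patients[j], "cohort": spec.name,
                "condition": "tumor", "subtype": subtype[j],
                "stage": stage[j], "grade": grade[j], "smoking": smoking[j],
                "time": float(time[j]), "event": int(event[j]),
            })
        for j, s in enumerate(n_samples_ids):
            lib_sizes[s] = float(lib_n[j])
            meta_rows.append({
                "sample": s, "patient": patients[j], "cohort": spec.name,
                "condition": "normal", "subtype": "", "stage": "",
                "grade": "", "smoking": "", "time": np.nan, "event": np.nan,
            })
        all_counts.append(pd.DataFrame(
            np.concatenate([c_t, c_n], axis=1), index=features,
            columns=t_samples + n_samples_ids))

    counts = pd.concat(all_counts, axis=1)
    library_sizes = pd.Series(lib_sizes, name="library_size")
    metadata = pd.DataFrame(meta_rows).set_index("sample").sort_index()

    # ------------------------------------------------------------------
    # cell lines + drug AUC
    # ------------------------------------------------------------------
    lines = [f"cl{j:03d}" for j in range(design.n_cell_lines)]
    z_cl = _latents(design.n_cell_lines)
    lib_cl = np.exp(rng.normal(math.log(design.mean_library_size),
                               design.library_size_sigma,
                               size=design.n_cell_lines))
    c_cl = _counts_from_latents(z_cl, _base_rpm(None), lib_cl)
    cell_counts = pd.DataFrame(c_cl, index=features, columns=lines)
    cell_library_sizes = pd.Series(lib_cl, index=lines, name="library_size")

    z_drug = rng.standard_normal((design.n_drugs, design.n_cell_lines))
    for row in drug_rows:
        dj = drug_ids.index(row["drug_id"])
        fe = f_index[row["erna_id"]]
        z_drug[dj] = _mix(z_cl[fe], z_drug[dj], row["rho"])
    from scipy.stats import norm as _norm
    auc = pd.DataFrame(0.2 + 0.6 * _norm.cdf(z_drug),
                       index=drug_ids, columns=lines)

    # ------------------------------------------------------------------
    # Hi-C O/E triples
    # ------------------------------------------------------------------
    tissues = [f"tissue{t:02d}" for t in range(design.n_tissues)]
    bin_bp = config.hic_bin_bp
    enriched_tissues = tissues[:design.hic_enriched_tissue_count]
    link_bins = set()
    for ri, gid in link_list:
        r, g = regions[ri], gene_by_id[gid]
        a = (r.midpoint // bin_bp) * bin_bp
        b = (g.tss // bin_bp) * bin_bp
        link_bins.add((r.chrom, min(a, b), max(a, b)))
    hic_rows = []
    for r in regions:
        a = (r.midpoint // bin_bp) * bin_bp
        for g in genes:
            if g.chrom != r.chrom:
                continue
            b = (g.tss // bin_bp) * bin_bp
            key = (r.chrom, min(a, b), max(a, b))
            planted = key in link_bins
            for tissue in tissues:
                enriched = planted and tissue in enriched_tissues
                if not enriched and rng.random() >= design.hic_coverage:
                    continue
                oe = float(np.exp(rng.normal(0.0, design.hic_background_sigma)))
                if enriched:
                    oe *= design.hic_enrichment_factor
                hic_rows.append({"tissue": tissue, "chrom": key[0],
                                 "bin_a": key[1], "bin_b": key[2], "oe": oe})
    hic = (pd.DataFrame(hic_rows,
                        columns=["tissue", "chrom", "bin_a", "bin_b", "oe"])
           .drop_duplicates(subset=["tissue", "chrom", "bin_a", "bin_b"])
           .sort_values(["tissue", "chrom", "bin_a", "bin_b"],
                        ignore_index=True))
    truth.tables["planted_hic"] = pd.DataFrame({
        "erna_id": [erna_ids[ri] for ri, _ in link_list],
        "gene_id": [gid for _, gid in link_list],
        "enrichment_factor":
            [design.hic_enrichment_factor] * len(link_list),
        "enriched_tissues": [",".join(enriched_tissues)] * len(link_list),
    })

    # ------------------------------------------------------------------
    # pathway gene sets + drug -> pathway map
    # ------------------------------------------------------------------
    pw_rows = []
    non_tf_genes = gene_ids[design.n_TFs:]
    for pwi in range(design.n_pathways):
        size = int(rng.integers(design.pathway_size[0],
                                design.pathway_size[1] + 1))
        members = rng.choice(non_tf_genes, size=min(size, len(non_tf_genes)),
                             replace=False)
        for m in sorted(members):
            pw_rows.append({"set": f"pathway{pwi:02d}", "member": m})
    pathway_sets = pd.DataFrame(pw_rows, columns=["set", "member"])
    dp_rows = []
    for dj, d in enumerate(drug_ids):
        if rng.random() < 0.8:
            pw = f"pathway{int(rng.integers(design.n_pathways)):02d}"
            dp_rows.append({"set": pw, "member": d})
    drug_pathways = pd.DataFrame(dp_rows, columns=["set", "member"])

    bundle = SyntheticBundle(
        design=design, chrom_lengths=chrom_lengths, genes=genes,
        lncrnas=lncs, blacklist=blacklist,
        enhancer_sources=enhancer_sources, regions=regions,
        counts=counts, library_sizes=library_sizes, metadata=metadata,
        cell_counts=cell_counts, cell_library_sizes=cell_library_sizes,
        auc=auc, hic=hic, tf_ids=tf_ids, pathway_sets=pathway_sets,
        drug_pathways=drug_pathways, truth=truth,
    )
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, Path]:
    """Write the bundle in the pipeline's input formats; returns a manifest
    of file paths."""
    from . import io as kio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    kio.write_chrom_lengths(bundle.chrom_lengths, outdir / "chrom_lengths.tsv")
    paths["chrom_lengths"] = outdir / "chrom_lengths.tsv"
    kio.write_gene_table(bundle.genes, outdir / "genes.tsv")
    paths["genes"] = outdir / "genes.tsv"
    kio.write_gene_table(bundle.lncrnas, outdir / "lncrnas.tsv")
    paths["lncrnas"] = outdir / "lncrnas.tsv"
    kio.write_bed(bundle.blacklist, outdir / "blacklist.bed")
    paths["blacklist"] = outdir / "blacklist.bed"
    for i, src in enumerate(bundle.enhancer_sources, start=1):
        p = outdir / f"enhancers_s{i}.bed"
        kio.write_bed(src, p)
        paths[f"enhancers_{i}"] = p
    kio.write_matrix(bundle.counts, outdir / "counts.tsv")
    paths["counts"] = outdir / "counts.tsv"
    bundle.library_sizes.sort_index().to_frame().to_csv(
        outdir / "library_sizes.tsv", sep="\t", index_label="sample",
        float_format="%.10g")
    paths["library_sizes"] = outdir / "library_sizes.tsv"
    kio.write_metadata(bundle.metadata, outdir / "metadata.tsv")
    paths["metadata"] = outdir / "metadata.tsv"
    kio.write_matrix(bundle.cell_counts, outdir / "cell_counts.tsv")
    paths["cell_counts"] = outdir / "cell_counts.tsv"
    bundle.cell_library_sizes.sort_index().to_frame().to_csv(
        outdir / "cell_library_sizes.tsv", sep="\t", index_label="sample",
        float_format="%.10g")
    paths["cell_library_sizes"] = outdir / "cell_library_sizes.tsv"
    kio.write_matrix(bundle.auc, outdir / "auc.tsv")
    paths["auc"] = outdir / "auc.tsv"
    kio.write_hic(bundle.hic, outdir / "hic.tsv")
    paths["hic"] = outdir / "hic.tsv"
    with open(outdir / "tf_list.tsv", "w") as fh:
        for tf in bundle.tf_ids:
            fh.write(tf + "\n")
    paths["tf_list"] = outdir / "tf_list.tsv"
    bundle.pathway_sets.to_csv(outdir / "pathways.tsv", sep="\t",
                               index=False, header=False)
    paths["pathways"] = outdir / "pathways.tsv"
    bundle.drug_pathways.to_csv(outdir / "drug_pathways.tsv", sep="\t",
                                index=False, header=False)
    paths["drug_pathways"] = outdir / "drug_pathways.tsv"
    bundle.truth.write(outdir / "truth")
    return paths
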