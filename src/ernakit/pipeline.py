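"""Stage orchestration: run the whole analysis from a manifest of input
files, writing one TSV per stage plus a run log (config, seed, input
checksums). Stages are rerunnable independently from intermediate files;
every output is sorted and written with a fixed float format so reruns with
the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import clinical as clin
from . import io as kio
from . import network as net
from . import pharmaco as ph
from . import quantify as qt
from . import regulators as reg
from .config import PipelineConfig
from .regions import (
    build_exclusion_mask,
    consensus_enhancers,
    define_regions,
    filter_regions,
    merge_overlapping_regions,
    regions_to_annotation,
)

log = logging.getLogger("ernakit")

ALL_STAGES = ("regions", "quantify", "classify", "regulators", "network",
              "hic-test", "pharmaco", "clinical", "report")

STAGE_INPUTS: dict[str, list[str]] = {
    "regions": ["enhancers", "genes", "lncrnas", "blacklist", "chrom_lengths"],
    "quantify": ["library_sizes", "metadata"],   # plus counts OR reads
    "classify": [],
    "regulators": ["tf_list"],
    "network": ["pathways"],
    "hic-test": ["hic"],
    "pharmaco": ["cell_counts", "cell_library_sizes", "auc", "drug_pathways"],
    "clinical": [],
    "report": [],
}


STAGE_DEPS: dict[str, list[str]] = {
    "regions": [],
    "quantify": [],
    "classify": ["quantify"],
    "regulators": ["quantify", "classify"],
    "network": ["regions", "quantify", "classify"],
    "hic-test": ["network"],
    "pharmaco": ["network"],
    "clinical": ["quantify", "classify"],
    "report": [],
}


def expand_stages(stages: list[str]) -> list[str]:
    """Close the requested stage list under dependencies, in run order."""
    wanted: set[str] = set()

    def _add(s: str) -> None:
        if s in wanted:
            return
        for d in STAGE_DEPS.get(s, []):
            _add(d)
        wanted.add(s)

    for s in stages:
        if s not in ALL_STAGES:
            raise ValueError(f"unknown stage {s!r}")
        _add(s)
    return [s for s in ALL_STAGES if s in wanted]


def check_manifest(manifest: dict[str, Path], stages: list[str]) -> None:
    missing = []
    for stage in stages:
        for key in STAGE_INPUTS.get(stage, []):
            if key == "enhancers":
                if not any(k.startswith("enhancers") for k in manifest):
                    missing.append((stage, key))
            elif key not in manifest:
                missing.append((stage, key))
        if stage == "quantify" and "counts" not in manifest \
                and "reads" not in manifest:
            missing.append((stage, "counts|reads"))
    if missing:
        raise FileNotFoundError(
            "manifest lacks inputs: "
            + ", ".join(f"{k} (stage {s})" for s, k in missing)
        )
    for key, path in manifest.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"manifest entry {key!r}: {path} not found")


def run_pipeline(
    config: PipelineConfig,
    manifest: dict[str, Path],
    outdir: str | Path,
    stages: list[str] | None = None,
) -> dict[str, Path]:
    """Run the requested stages (default: all) and write per-stage outputs.

    Returns a dict of output paths. Raises before any computation if a
    requested stage's inputs are missing from the manifest.
    """
    stages = expand_stages(list(stages) if stages else list(ALL_STAGES))
    manifest = {k: Path(v) for k, v in manifest.items()}
    if "quantify" in stages and "counts" not in manifest:
        # counting from a reads BED needs the eRNA regions
        stages = expand_stages(stages + ["regions"])
    check_manifest(manifest, stages)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}

    run_log = {
        "config": {k: (v if not isinstance(v, Path) else str(v))
                   for k, v in vars(config).items()},
        "seed": config.seed,
        "inputs": {k: {"path": str(p), "md5": kio.file_checksum(p)}
                   for k, p in sorted(manifest.items())},
        "stages": stages,
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)

    def _write(df: pd.DataFrame, name: str, index: bool = False) -> Path:
        path = outdir / name
        df.to_csv(path, sep="\t", index=index, float_format=kio.FLOAT_FORMAT)
        outputs[name] = path
        return path

    # ---------------- regions ----------------
    regions = None
    genes = lncs = None
    if "regions" in stages:
        log.info("stage regions")
        sources = [
            kio.read_bed(manifest[k], role="enhancer", source=k)
            for k in sorted(manifest) if k.startswith("enhancers")
        ]
        genes = kio.read_gene_table(manifest["genes"], role="gene")
        lncs = kio.read_gene_table(manifest["lncrnas"], role="lncRNA")
        blacklist = kio.read_bed(manifest["blacklist"], role="blacklist",
                                 source="blacklist")
        chrom_lengths = kio.read_chrom_lengths(manifest["chrom_lengths"])
        consensus = consensus_enhancers(sources, config.min_sources)
        mask = build_exclusion_mask(genes, lncs, blacklist,
                                    config.gene_extension_bp,
                                    config.uaRNA_window_bp)
        all_regions = define_regions(consensus, config.flank_bp, chrom_lengths)
        regions, audit = filter_regions(all_regions, mask)
        if config.merge_surviving_regions:
            regions = merge_overlapping_regions(regions)
        kio.write_bed(regions_to_annotation(regions), outdir / "erna_regions.bed")
        outputs["erna_regions.bed"] = outdir / "erna_regions.bed"
        _write(audit, "region_drop_audit.tsv")

    # ---------------- quantify ----------------
    expr = None
    if "quantify" in stages:
        log.info("stage quantify")
        lib = kio.read_matrix(manifest["library_sizes"]).iloc[:, 0]
        metadata = kio.read_metadata(manifest["metadata"])
        if "counts" in manifest:
            counts = kio.read_matrix(manifest["counts"])
        else:
            # reads-as-BED path: the BED name column carries the sample ID
            if regions is None:
                raise ValueError("quantifying from reads requires the "
                                 "regions stage")
            reads = kio.read_bed(manifest["reads"], role="read",
                                 source="reads")
            counts = qt.count_overlaps(reads, regions)
            counts = counts.reindex(columns=sorted(lib.index), fill_value=0)
        expr = qt.rpm(counts, lib, metadata)
        kio.write_matrix(expr.values, outdir / "rpm.tsv")
        outputs["rpm.tsv"] = outdir / "rpm.tsv"

    # ---------------- classify ----------------
    detect = None
    erna_ids: list[str] = []
    if "classify" in stages and expr is not None:
        log.info("stage classify")
        if regions is not None:
            erna_ids = [r.id for r in regions]
        else:
            erna_ids = [f for f in expr.features if f.startswith("erna_")]
        erna_expr = qt.ExpressionMatrix(expr.values.loc[erna_ids],
                                        expr.library_sizes, expr.metadata)
        detect = qt.detectability(erna_expr, config.rpm_detect)
        _write(detect.per_cohort, "detectability.tsv")
        _write(detect.per_erna.reset_index(names="erna_id"), "erna_classes.tsv")
        det_any = sorted(detect.per_erna.index[
            detect.per_erna["n_cohorts_detected"] > 0])
        sim = qt.sample_similarity(erna_expr.subset_samples(
            [s for s in erna_expr.samples
             if expr.metadata.loc[s, "condition"] == "tumor"]), det_any)
        kio.write_matrix(sim, outdir / "sample_similarity.tsv")
        outputs["sample_similarity.tsv"] = outdir / "sample_similarity.tsv"

    # ---------------- regulators ----------------
    edges_all = profiles_all = None
    if "regulators" in stages and expr is not None and detect is not None:
        log.info("stage regulators")
        tf_ids = [t for t in kio.read_id_list(manifest["tf_list"])
                  if t in expr.features]
        edges_frames, profile_frames = [], []
        for cohort in detect.cohorts:
            tumor = expr.tumor_samples(cohort)
            det_ids = detect.detectable_ids(cohort)
            if not det_ids:
                continue
            e = reg.putative_regulators(
                expr.values.loc[tf_ids, tumor],
                expr.values.loc[det_ids, tumor], cohort, config)
            edges_frames.append(e)
            profile_frames.append(reg.master_regulators(
                e, len(det_ids), cohort, tf_ids, config))
        edges_all = pd.concat(edges_frames, ignore_index=True) \
            if edges_frames else pd.DataFrame(columns=reg.EDGE_COLUMNS)
        profiles_all = pd.concat(profile_frames, ignore_index=True)
        general = reg.general_master_regulators(profiles_all, config)
        _write(edges_all, "regulator_edges.tsv")
        _write(profiles_all, "regulator_profiles.tsv")
        _write(general, "general_masters.tsv")

    # ---------------- network ----------------
    links_all = None
    pathway_labels = erna_pathways = None
    if "network" in stages and expr is not None and detect is not None \
            and regions is not None:
        log.info("stage network")
        pairs = net.candidate_pairs(regions, genes, config.max_link_distance_bp)
        gene_ids = sorted({g.id for g in genes} & set(expr.features))
        link_frames = []
        for cohort in detect.cohorts:
            tumor = expr.tumor_samples(cohort)
            det_ids = detect.detectable_ids(cohort)
            link_frames.append(net.correlate_links(
                pairs, expr.values.loc[det_ids, tumor],
                expr.values.loc[gene_ids, tumor], cohort, config))
        links_all = pd.concat(link_frames, ignore_index=True) \
            if link_frames else pd.DataFrame(columns=net.LINK_COLUMNS)
        _write(links_all, "erna_gene_links.tsv")
        pathway_sets = kio.read_gene_sets(manifest["pathways"])
        pathway_labels, erna_pathways = net.annotate_pathways(
            links_all, pathway_sets)
        _write(pathway_labels, "link_pathways.tsv")
        ep = erna_pathways.copy()
        ep["pathways"] = ep["pathways"].apply(",".join)
        _write(ep, "erna_pathway_membership.tsv")

    # ---------------- hic-test ----------------
    if "hic-test" in stages and links_all is not None and regions is not None:
        log.info("stage hic-test")
        hic = net.HiCIndex(kio.read_hic(manifest["hic"]), config.hic_bin_bp)
        region_mid = {r.id: (r.chrom, r.midpoint) for r in regions}
        gene_tss = {g.id: (g.chrom, g.tss) for g in genes}
        uniq = links_all[["erna_id", "gene_id"]].drop_duplicates(
            ignore_index=True)
        support = net.hic_support(uniq, hic, region_mid, gene_tss,
                                  config.hic_oe_min)
        _write(support, "hic_support.tsv")
        if len(uniq):
            perm = net.permutation_enrichment(
                uniq, regions, genes, hic,
                config.n_permutations, config.seed,
                hic_oe_min=config.hic_oe_min,
                max_link_distance_bp=(config.max_link_distance_bp
                                      if config.distance_matched_background
                                      else None))
            with open(outdir / "hic_permutation.json", "w") as fh:
                json.dump({
                    "observed_fraction": perm.observed_fraction,
                    "n_permutations": perm.n_permutations,
                    "exceedances": perm.exceedances,
                    "p_empirical": perm.p_empirical,
                }, fh, indent=2, sort_keys=True)
            outputs["hic_permutation.json"] = outdir / "hic_permutation.json"

    # ---------------- pharmaco ----------------
    if "pharmaco" in stages and erna_pathways is not None:
        log.info("stage pharmaco")
        cell_counts = kio.read_matrix(manifest["cell_counts"])
        cell_lib = kio.read_matrix(manifest["cell_library_sizes"]).iloc[:, 0]
        cell_expr = qt.rpm(cell_counts, cell_lib)
        auc = kio.read_matrix(manifest["auc"])
        if erna_ids:
            cell_vals = cell_expr.values.loc[
                [e for e in erna_ids if e in cell_expr.features]]
        else:
            cell_vals = cell_expr.values
        assoc = ph.drug_associations(cell_vals, auc, config, source="screen")
        drug_pw = kio.read_gene_sets(manifest["drug_pathways"])
        assoc = ph.classify_pathway_relation(assoc, erna_pathways, drug_pw)
        _write(assoc, "drug_associations.tsv")

    # ---------------- clinical ----------------
    if "clinical" in stages and expr is not None and detect is not None:
        log.info("stage clinical")
        de_frames, assoc_frames = [], []
        for cohort in detect.cohorts:
            det_ids = detect.detectable_ids(cohort)
            cohort_samples = [
                s for s in expr.samples
                if expr.metadata.loc[s, "cohort"] == cohort]
            sub = qt.ExpressionMatrix(
                expr.values.loc[det_ids, cohort_samples],
                expr.library_sizes.loc[cohort_samples],
                expr.metadata.loc[cohort_samples])
            de_frames.append(clin.differential_expression(sub, cohort, config))
            for feature in clin.GROUP_FEATURES:
                assoc_frames.append(clin.group_tests(sub, cohort, feature,
                                                     config))
            assoc_frames.append(clin.survival_association(sub, cohort, config))
        de_all = pd.concat(de_frames, ignore_index=True) \
            if de_frames else pd.DataFrame(columns=clin.DE_COLUMNS)
        assoc_all = pd.concat(assoc_frames, ignore_index=True) \
            if assoc_frames else pd.DataFrame(columns=clin.ASSOC_COLUMNS)
        summary = clin.clinical_summary(assoc_all, de_all, config)
        summary = summary.copy()
        summary["categories"] = summary["categories"].apply(",".join)
        _write(de_all, "differential_expression.tsv")
        _write(assoc_all, "clinical_associations.tsv")
        _write(summary, "clinical_summary.tsv")

    # ---------------- report ----------------
    if "report" in stages:
        report: dict[str, float | int] = {}
        if regions is not None:
            report["n_erna_regions"] = len(regions)
        if detect is not None:
            cls = detect.per_erna["erna_class"].value_counts()
            report["n_detectable_ernas"] = int(
                (detect.per_erna["n_cohorts_detected"] > 0).sum())
            for c in ("ubiquitous", "intermediate", "specific"):
                report[f"n_{c}"] = int(cls.get(c, 0))
        if profiles_all is not None:
            report["n_master_regulator_flags"] = int(
                profiles_all["is_master"].sum())
        if links_all is not None:
            report["n_links"] = int(len(links_all))
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
        outputs["report.json"] = outdir / "report.json"

    return outputs
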