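"""Pipeline configuration.

Every numeric threshold the pipeline uses lives here, with the defaults the
analysis is defined by: eRNA regions are the +/-3 kb windows around consensus
enhancer midpoints; gene/lncRNA exclusions extend 1 kb past TSS and TES with a
500 bp upstream-antisense (uaRNA) window; detectability is mean RPM >= 1
(RPM >= 5 as the stringent robustness cutoff); co-expression edges require
Spearman Rs >= 0.3 at BH-FDR < 0.05; a master regulator correlates with
>= 25% of a cohort's detectable eRNAs and a general master is master in
>= 10 cohorts; eRNA-gene links span <= 1 Mb; differential expression calls
need |fold change| >= 1.5 at FDR < 0.05; clinical group tests require groups
of >= 5; Hi-C support means O/E >= 1 in a 10 kb-binned contact map, tested
against 10,000 random-pair permutations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    flank_bp: int = 3000
    gene_extension_bp: int = 1000
    uaRNA_window_bp: int = 500
    min_sources: int = 2
    rpm_detect: float = 1.0
    rpm_strict: float = 5.0
    rs_min: float = 0.3
    fdr_max: float = 0.05
    master_fraction: float = 0.25
    general_master_min_types: int = 10
    max_link_distance_bp: int = 1_000_000
    fc_min: float = 1.5
    min_group_size: int = 5
    n_permutations: int = 10_000
    hic_oe_min: float = 1.0
    hic_bin_bp: int = 10_000
    seed: int = 0
    # interpretation switches (defaults follow the Results wording)
    rs_absolute: bool = False          # True: |Rs| >= rs_min instead of Rs >= rs_min
    master_strict: bool = False        # True: fraction > master_fraction (Methods wording)
    general_master_strict: bool = False
    merge_surviving_regions: bool = False
    fc_boundary_inclusive: bool = True
    distance_matched_background: bool = False
    min_pairs_complete: int = 10       # pairwise-complete n below which a pair is skipped
    de_pseudocount: float = 0.1
    survival_mode: str = "cox"         # "cox" or "logrank"

    def __post_init__(self) -> None:
        for name in (
            "flank_bp", "gene_extension_bp", "uaRNA_window_bp", "min_sources",
            "rpm_detect", "rpm_strict", "rs_min", "fdr_max", "master_fraction",
            "general_master_min_types", "max_link_distance_bp", "fc_min",
            "min_group_size", "n_permutations", "hic_oe_min", "hic_bin_bp",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"config threshold {name!r} must be strictly positive")
        if not 0.0 < self.fdr_max < 1.0:
            raise ValueError("fdr_max must lie in (0, 1)")
        if not 0.0 < self.master_fraction <= 1.0:
            raise ValueError("master_fraction must lie in (0, 1]")
        if self.survival_mode not in ("cox", "logrank"):
            raise ValueError("survival_mode must be 'cox' or 'logrank'")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config from YAML; keyword overrides win over file values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    def replace(self, **changes) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)
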