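"""Putative TF regulators of eRNAs.

Per cohort, every TF x detectable-eRNA pair is screened by Spearman
correlation; an edge requires Rs >= ``rs_min`` (positive only by default —
the screen targets activating regulators; set ``rs_absolute`` for |Rs|) at
BH-FDR < ``fdr_max``, with BH applied jointly over all TF x eRNA tests
within the cohort. A TF correlated with at least ``master_fraction`` of the
cohort's detectable eRNAs is a putative master regulator; a TF that is a
master in at least ``general_master_min_types`` cohorts is a general master
regulator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .stats import bh_fdr, spearman_matrix

EDGE_COLUMNS = ["tf_id", "erna_id", "cohort", "n", "rs", "p", "q"]


def putative_regulators(
    expr_tf: pd.DataFrame,
    expr_erna: pd.DataFrame,
    cohort: str,
    config: PipelineConfig,
) -> pd.DataFrame:
    """TF -> eRNA edges for one cohort.

    ``expr_tf``/``expr_erna`` are feature x sample matrices restricted to the
    cohort's tumor samples and (for eRNAs) to detectable eRNAs.
    """
    if expr_tf.empty or expr_erna.empty:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    rs, p, n = spearman_matrix(expr_tf, expr_erna,
                               min_n=config.min_pairs_complete)
    long = pd.DataFrame({
        "tf_id": np.repeat(rs.index, len(rs.columns)),
        "erna_id": np.tile(rs.columns, len(rs.index)),
        "n": n.to_numpy().ravel(),
        "rs": rs.to_numpy().ravel(),
        "p": p.to_numpy().ravel(),
    })
    long = long[np.isfinite(long["p"])].reset_index(drop=True)
    if long.empty:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    long["q"] = bh_fdr(long["p"])
    long["cohort"] = cohort
    sig = long["rs"].abs() >= config.rs_min if config.rs_absolute \
        else long["rs"] >= config.rs_min
    edges = long[sig & (long["q"] < config.fdr_max)]
    return (edges[EDGE_COLUMNS]
            .sort_values(["tf_id", "erna_id"], ignore_index=True))


def master_regulators(
    edges: pd.DataFrame,
    n_detectable: int,
    cohort: str,
    tf_ids: list[str],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-TF regulator profile for one cohort."""
    if n_detectable <= 0:
        raise ValueError(f"cohort {cohort!r} has zero detectable eRNAs")
    counts = (edges[edges["cohort"] == cohort]
              .groupby("tf_id")["erna_id"].nunique())
    rows = []
    for tf in sorted(tf_ids):
        k = int(counts.get(tf, 0))
        frac = k / n_detectable
        is_master = frac > config.master_fraction if config.master_strict \
            else frac >= config.master_fraction
        rows.append({
            "tf_id": tf, "cohort": cohort,
            "n_ernas_correlated": k,
            "n_ernas_detectable": n_detectable,
            "fraction": frac,
            "is_master": bool(is_master),
        })
    return pd.DataFrame(rows)


def general_master_regulators(
    profiles: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Flag TFs that are master regulators in enough cohorts."""
    n_master = (profiles[profiles["is_master"]]
                .groupby("tf_id")["cohort"].nunique())
    tf_ids = sorted(profiles["tf_id"].unique())
    k = pd.Series([int(n_master.get(tf, 0)) for tf in tf_ids], index=tf_ids)
    thr = config.general_master_min_types
    is_general = k > thr if config.general_master_strict else k >= thr
    return pd.DataFrame({
        "tf_id": tf_ids,
        "n_cohorts_master": k.to_numpy(),
        "is_general_master": is_general.to_numpy(),
    })
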