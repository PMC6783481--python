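"""eRNA-drug associations across cell lines.

Drug response is summarised as the area under the dose-response curve (AUC),
where higher AUC means a *more resistant* line (CTRP/GDSC convention). Hence
a negative expression-AUC Spearman correlation — higher eRNA expression,
lower AUC — is labelled "sensitive" and a positive one "resistant", both at
BH-FDR < ``fdr_max`` over all (eRNA, drug) pairs within one response source.
Separate sources (e.g. CTRP-like and GDSC-like screens) are independent
association runs with separate FDR.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .stats import bh_fdr, spearman_matrix

ASSOC_COLUMNS = ["erna_id", "drug_id", "source", "n", "rs", "p", "q", "direction"]


def drug_associations(
    expr_cell_lines: pd.DataFrame,
    auc_matrix: pd.DataFrame,
    config: PipelineConfig,
    source: str = "screen",
) -> pd.DataFrame:
    """Spearman screen of eRNA expression (eRNA x line) against drug AUC
    (drug x line) over the shared cell lines."""
    shared = expr_cell_lines.columns.intersection(auc_matrix.columns)
    if len(shared) == 0:
        raise ValueError("no shared cell lines between expression and AUC")
    rs, p, n = spearman_matrix(expr_cell_lines[shared], auc_matrix[shared],
                               min_n=config.min_pairs_complete)
    long = pd.DataFrame({
        "erna_id": np.repeat(rs.index, len(rs.columns)),
        "drug_id": np.tile(rs.columns, len(rs.index)),
        "n": n.to_numpy().ravel(),
        "rs": rs.to_numpy().ravel(),
        "p": p.to_numpy().ravel(),
    })
    long = long[np.isfinite(long["p"])].reset_index(drop=True)
    if long.empty:
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    long["q"] = bh_fdr(long["p"])
    long["source"] = source
    sig = long["q"] < config.fdr_max
    long["direction"] = np.where(
        sig & (long["rs"] < 0), "sensitive",
        np.where(sig & (long["rs"] > 0), "resistant", "none"),
    )
    return long[ASSOC_COLUMNS].sort_values(["erna_id", "drug_id"],
                                           ignore_index=True)


def classify_pathway_relation(
    associations: pd.DataFrame,
    erna_pathways: pd.DataFrame,
    drug_pathways: pd.DataFrame,
) -> pd.DataFrame:
    """Label each association within- or cross-pathway.

    ``erna_pathways`` is the per-eRNA membership table from
    :func:`ernakit.network.annotate_pathways` (erna_id, pathways list);
    ``drug_pathways`` has columns (set, member) = (pathway, drug). An
    association is *within* when the eRNA has a putative target gene in the
    drug's target pathway, *cross* when the eRNA has pathway-annotated
    targets but none in that pathway, and *unassigned* otherwise (including
    drugs absent from the map).
    """
    erna_map = dict(zip(erna_pathways["erna_id"],
                        [set(p) for p in erna_pathways["pathways"]]))
    drug_map: dict[str, set[str]] = {}
    for pw, drug in zip(drug_pathways["set"], drug_pathways["member"]):
        drug_map.setdefault(drug, set()).add(pw)

    out = associations.copy()
    relations = []
    for erna_id, drug_id in zip(out["erna_id"], out["drug_id"]):
        epaths = erna_map.get(erna_id, set())
        dpaths = drug_map.get(drug_id, set())
        if not epaths or not dpaths:
            relations.append("unassigned")
        elif epaths & dpaths:
            relations.append("within")
        else:
            relations.append("cross")
    out["pathway_relation"] = relations
    return out
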