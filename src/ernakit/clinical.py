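"""Clinical associations of eRNA expression.

Four analyses per cohort:

* paired tumor/normal differential expression: paired two-sided t-test on
  log2(RPM + eps), fold change (mean_tumor + eps)/(mean_normal + eps), calls
  "up"/"down" at |FC| >= ``fc_min`` and BH-FDR < ``fdr_max`` over the
  cohort's eRNAs; cohorts with fewer than 5 tumor-normal pairs are skipped;
* group tests on subtype/stage/grade/smoking: Welch t-test for two groups,
  one-way ANOVA for more, after dropping groups smaller than
  ``min_group_size``; BH within (cohort, feature);
* survival: univariate Cox on z-scored expression (Wald p) or log-rank of
  the top vs bottom expression quartile; BH within cohort;
* the clinically-relevant summary: an eRNA is clinically relevant when at
  least one of survival/subtype/stage/grade/smoking is significant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps

from .config import PipelineConfig
from .quantify import ExpressionMatrix
from .stats import bh_fdr

DE_COLUMNS = ["erna_id", "cohort", "n_pairs", "mean_tumor_rpm",
              "mean_normal_rpm", "fold_change", "p", "q", "call"]
ASSOC_COLUMNS = ["erna_id", "cohort", "feature", "test", "statistic",
                 "p", "q", "effect"]
GROUP_FEATURES = ("subtype", "stage", "grade", "smoking")
CLINICAL_FEATURES = ("survival",) + GROUP_FEATURES


def _cohort_frame(expr: ExpressionMatrix, cohort: str,
                  condition: str | None = "tumor") -> tuple[pd.DataFrame, pd.DataFrame]:
    md = expr.metadata
    mask = md["cohort"] == cohort
    if condition is not None:
        mask &= md["condition"] == condition
    samples = [s for s in expr.samples if mask.get(s, False)]
    return expr.values[samples], md.loc[samples]


def differential_expression(
    expr: ExpressionMatrix,
    cohort: str,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Paired tumor vs normal DE for one cohort (empty frame if <5 pairs)."""
    md = expr.metadata
    if md is None:
        raise ValueError("differential expression requires metadata")
    sub = md[md["cohort"] == cohort]
    tum = sub[sub["condition"] == "tumor"]
    nor = sub[sub["condition"] == "normal"]
    if tum["patient"].duplicated().any() or nor["patient"].duplicated().any():
        raise ValueError(f"cohort {cohort!r}: a patient has duplicate samples "
                         "per condition; pairing is ambiguous")
    patients = sorted(set(tum["patient"]) & set(nor["patient"]))
    if len(patients) < config.min_group_size:
        return pd.DataFrame(columns=DE_COLUMNS)
    t_samples = tum.reset_index().set_index("patient").loc[patients, "sample"]
    n_samples = nor.reset_index().set_index("patient").loc[patients, "sample"]
    T = expr.values[list(t_samples)].to_numpy(dtype=float)
    N = expr.values[list(n_samples)].to_numpy(dtype=float)
    eps = config.de_pseudocount
    mt, mn = T.mean(axis=1), N.mean(axis=1)
    fc = (mt + eps) / (mn + eps)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tstat, p = sps.ttest_rel(np.log2(T + eps), np.log2(N + eps), axis=1)
    p = np.where(np.isfinite(p), p, 1.0)  # zero-variance pairs: no evidence
    q = bh_fdr(p)
    if config.fc_boundary_inclusive:
        up = (fc >= config.fc_min) & (q < config.fdr_max)
        down = (fc <= 1.0 / config.fc_min) & (q < config.fdr_max)
    else:
        up = (fc > config.fc_min) & (q < config.fdr_max)
        down = (fc < 1.0 / config.fc_min) & (q < config.fdr_max)
    call = np.where(up, "up", np.where(down, "down", "ns"))
    return pd.DataFrame({
        "erna_id": expr.features, "cohort": cohort, "n_pairs": len(patients),
        "mean_tumor_rpm": mt, "mean_normal_rpm": mn, "fold_change": fc,
        "p": p, "q": q, "call": call,
    }).sort_values("erna_id", ignore_index=True)


def group_tests(
    expr: ExpressionMatrix,
    cohort: str,
    feature: str,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Welch t (2 groups) / one-way ANOVA (>2) per eRNA for one clinical
    grouping feature, over the cohort's tumor samples."""
    if feature not in GROUP_FEATURES:
        raise ValueError(f"unknown grouping feature {feature!r}")
    values, md = _cohort_frame(expr, cohort)
    # group tests run on log2(RPM + eps): expression is log-scale noisy, and
    # mean shifts are planted (and interpreted) on that scale
    values = np.log2(values + config.de_pseudocount)
    labels = md[feature].astype(object)
    labels = labels[~pd.isna(labels)]
    sizes = labels.value_counts()
    groups = sorted(sizes[sizes >= config.min_group_size].index)
    if len(groups) < 2:
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    arrays = [values[labels.index[labels == g]].to_numpy(dtype=float)
              for g in groups]
    rows = []
    for i, erna in enumerate(values.index):
        xs = [a[i] for a in arrays]
        if all(np.ptp(x) == 0 for x in xs) and len({x[0] for x in xs}) == 1:
            stat, p = 0.0, 1.0
        elif len(groups) == 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = sps.ttest_ind(xs[0], xs[1], equal_var=False)
            test = "t"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p = sps.f_oneway(*xs)
        test = "t" if len(groups) == 2 else "anova"
        if not np.isfinite(p):
            stat, p = 0.0, 1.0
        effect = ";".join(f"{g}={np.mean(x):.6g}" for g, x in zip(groups, xs))
        rows.append({"erna_id": erna, "cohort": cohort, "feature": feature,
                     "test": test, "statistic": float(stat), "p": float(p),
                     "effect": effect})
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"])
    return out[ASSOC_COLUMNS].sort_values("erna_id", ignore_index=True)


def survival_association(
    expr: ExpressionMatrix,
    cohort: str,
    config: PipelineConfig,
    mode: str | None = None,
) -> pd.DataFrame:
    """Per-eRNA overall-survival association for one cohort.

    mode="cox": univariate Cox on z-scored expression (effect = log hazard
    ratio per SD). mode="logrank": top vs bottom expression quartile.
    Cohorts with <20 subjects or <10 events are skipped; constant-expression
    eRNAs are skipped.
    """
    mode = mode or config.survival_mode
    values, md = _cohort_frame(expr, cohort)
    ok = md["time"].notna() & md["event"].notna()
    values, md = values[md.index[ok]], md[ok]
    time = md["time"].astype(float)
    event = md["event"].astype(int)
    if len(md) < 20 or event.sum() < 10:
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    rows = []
    for erna in values.index:
        x = values.loc[erna].astype(float)
        if x.std() == 0:
            continue
        if mode == "cox":
            z = (x - x.mean()) / x.std()
            df = pd.DataFrame({"time": time, "event": event, "z": z})
            cph = CoxPHFitter()
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cph.fit(df, duration_col="time", event_col="event")
            except Exception:
                continue
            coef = float(cph.params_["z"])
            p = float(cph.summary.loc["z", "p"])
            stat = float(cph.summary.loc["z", "z"])
            rows.append({"erna_id": erna, "cohort": cohort,
                         "feature": "survival", "test": "cox",
                         "statistic": stat, "p": p,
                         "effect": f"log_hr_per_sd={coef:.6g}"})
        elif mode == "logrank":
            lo, hi = x.quantile(0.25), x.quantile(0.75)
            low_idx, high_idx = x.index[x <= lo], x.index[x >= hi]
            if len(low_idx) < 2 or len(high_idx) < 2:
                continue
            res = logrank_test(time[high_idx], time[low_idx],
                               event[high_idx], event[low_idx])
            direction = np.sign(
                float(time[low_idx].mean() - time[high_idx].mean())
            )
            rows.append({"erna_id": erna, "cohort": cohort,
                         "feature": "survival", "test": "logrank",
                         "statistic": float(res.test_statistic),
                         "p": float(res.p_value),
                         "effect": f"high_vs_low_worse={direction:+.0f}"})
        else:
            raise ValueError(f"unknown survival mode {mode!r}")
    if not rows:
        return pd.DataFrame(columns=ASSOC_COLUMNS)
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"])
    return out[ASSOC_COLUMNS].sort_values("erna_id", ignore_index=True)


def clinical_summary(
    associations: pd.DataFrame,
    differential: pd.DataFrame | None,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Per-(eRNA, cohort) clinically-relevant flag: significant in at least
    one of survival/subtype/stage/grade/smoking. DE calls are reported
    alongside but do not enter the relevance flag."""
    if associations.empty:
        base = pd.DataFrame(columns=["erna_id", "cohort"])
    else:
        sig = associations[associations["q"] < config.fdr_max]
        base = (sig.groupby(["erna_id", "cohort"])["feature"]
                .agg(lambda s: sorted(set(s)))
                .rename("categories").reset_index())
    if base.empty:
        base = pd.DataFrame(columns=["erna_id", "cohort", "categories"])
    base["clinically_relevant"] = True
    tested = associations[["erna_id", "cohort"]].drop_duplicates() \
        if not associations.empty else pd.DataFrame(columns=["erna_id", "cohort"])
    out = tested.merge(base, on=["erna_id", "cohort"], how="left")
    out["clinically_relevant"] = out["clinically_relevant"].eq(True)
    out["categories"] = out["categories"].apply(
        lambda v: v if isinstance(v, list) else [])
    if differential is not None and not differential.empty:
        de = differential[["erna_id", "cohort", "call"]].rename(
            columns={"call": "de_call"})
        out = out.merge(de, on=["erna_id", "cohort"], how="left")
        out["de_call"] = out["de_call"].fillna("untested")
    else:
        out["de_call"] = "untested"
    return out.sort_values(["erna_id", "cohort"], ignore_index=True)
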