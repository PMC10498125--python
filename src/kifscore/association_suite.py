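"""Downstream statistics of the score: prognosis, adjusted linear models,
Spearman feature panels, group tests, and the differential-expression filter.

All results are returned as association records — one named target per row
with the statistic kind, estimate, p-value and (where a family is declared)
its Benjamini–Hochberg adjusted p.  Kaplan–Meier estimation and the log-rank
test come from lifelines; plain hypothesis tests from scipy; the adjusted
linear model from statsmodels OLS.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from statsmodels.api import OLS
from statsmodels.stats.multitest import multipletests

from .risk_partition import CoxResult, fit_univariate_cox

logger = logging.getLogger("kifscore")

__all__ = [
    "AssociationRecord",
    "bh_adjust",
    "score_prognosis",
    "km_logrank",
    "adjusted_linear_assoc",
    "spearman_panel",
    "group_tests",
    "differential_filter",
]


@dataclasses.dataclass
class AssociationRecord:
    target: str
    kind: str  # spearman_rho | linear_coef | HR | log_rank | wilcoxon | kruskal | fisher_or | t_stat | paired_wilcoxon
    estimate: float
    p: float
    padj: float | None = None


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (one family per call)."""
    arr = np.asarray(pvalues, dtype=float)
    mask = np.isfinite(arr)
    out = np.full(arr.shape, np.nan)
    if mask.sum():
        out[mask] = multipletests(arr[mask], method="fdr_bh")[1]
    return out


def score_prognosis(
    scores: pd.DataFrame,
    clinical: pd.DataFrame,
    endpoint: str = "OS",
    per_cohort: bool = True,
) -> pd.DataFrame:
    """Univariate Cox of the continuous score on a survival endpoint.

    One record per cohort (or one pooled record), labelled ``risk`` when
    p < 0.05 with HR > 1, ``protective`` when p < 0.05 with HR < 1, else
    ``ns`` — the published reading of score prognosis.
    """
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    merged = scores.merge(clinical[["sample", tcol, ecol]], on="sample").dropna(
        subset=[tcol, ecol, "kifscore"]
    )
    rows = []
    groups = merged.groupby("cohort") if per_cohort else [("pooled", merged)]
    for cohort, grp in groups:
        fit = fit_univariate_cox(grp["kifscore"], grp[tcol], grp[ecol])
        label = "ns"
        if fit.p < 0.05:
            label = "risk" if fit.hr > 1 else "protective"
        rows.append(
            {"cohort": cohort, "endpoint": endpoint, "hr": fit.hr, "p": fit.p,
             "ci_low": fit.ci_low, "ci_high": fit.ci_high, "label": label}
        )
    return pd.DataFrame(rows)


def km_logrank(
    times: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    groups: np.ndarray | pd.Series,
) -> tuple[dict[str, pd.DataFrame], AssociationRecord]:
    """Product-limit curves per group plus the two-sample log-rank test."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank comparison needs exactly 2 groups, got {len(labels)}")
    curves = {}
    for lbl in labels:
        m = groups == lbl
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m], label=str(lbl))
        curves[str(lbl)] = kmf.survival_function_
    m0 = groups == labels[0]
    res = logrank_test(times[m0], times[~m0], events[m0], events[~m0])
    rec = AssociationRecord(
        target=f"{labels[0]}_vs_{labels[1]}", kind="log_rank",
        estimate=float(res.test_statistic), p=float(res.p_value),
    )
    return curves, rec


def adjusted_linear_assoc(
    score: pd.Series,
    response: pd.Series,
    covariates: pd.DataFrame,
    target: str = "response",
) -> AssociationRecord:
    """OLS of a genomic response (burden, TMB, ...) on the score adjusted for
    age / sex / race style covariates.

    Categorical covariates are one-hot encoded with the alphabetically first
    level as reference.  Complete cases only; a rank-deficient design raises
    with the names of the collinear columns.
    """
    df = pd.DataFrame({"score": score, "y": response}).join(covariates, how="inner").dropna()
    design = pd.DataFrame({"intercept": 1.0, "score": df["score"]}, index=df.index)
    for col in covariates.columns:
        vals = df[col]
        if vals.dtype.kind in "if":
            design[col] = vals.astype(float)
        else:
            levels = sorted(vals.astype(str).unique())
            for lvl in levels[1:]:
                design[f"{col}[{lvl}]"] = (vals.astype(str) == lvl).astype(float)
    if len(df) < design.shape[1] + 2:
        raise ValueError("too few complete cases for the adjusted model")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        _, r = np.linalg.qr(design.to_numpy())
        bad = [design.columns[i] for i in range(design.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear column(s): {bad}")
    fit = OLS(df["y"].to_numpy(dtype=float), design.to_numpy()).fit()
    i = design.columns.get_loc("score")
    return AssociationRecord(target=target, kind="linear_coef",
                             estimate=float(fit.params[i]), p=float(fit.pvalues[i]))


def spearman_panel(
    score: pd.Series,
    features: pd.DataFrame,
    family: str = "panel",
) -> pd.DataFrame:
    """Spearman rho of the score against every feature, BH-adjusted within
    the named family.

    Constant features (rho undefined) are reported with NaN estimates and a
    warning rather than dropped silently.
    """
    rows = []
    for name in features.columns:
        pair = pd.DataFrame({"score": score, "f": features[name]}).dropna()
        if len(pair) < 3:
            raise ValueError(f"feature {name!r} has fewer than 3 paired observations")
        if pair["f"].nunique() == 1:
            logger.warning("feature %s is constant; Spearman rho undefined", name)
            rows.append({"target": name, "kind": "spearman_rho",
                         "estimate": np.nan, "p": np.nan})
            continue
        rho, p = stats.spearmanr(pair["score"], pair["f"])
        rows.append({"target": name, "kind": "spearman_rho",
                     "estimate": float(rho), "p": float(p)})
    out = pd.DataFrame(rows)
    out["padj"] = bh_adjust(out["p"])
    out["family"] = family
    return out


def group_tests(values, group_labels=None, kind: str = "wilcoxon", table=None) -> AssociationRecord:
    """Two-or-more-group comparisons: wilcoxon (rank-sum), t (Welch),
    kruskal, paired_wilcoxon (signed-rank), or fisher on a 2x2 table.

    ``values``/``group_labels`` feed the sample tests; ``table`` feeds
    fisher.  paired_wilcoxon interprets ``values`` as (first, second) paired
    arrays — the tumor-versus-adjacent comparison.
    """
    if kind == "fisher":
        tab = np.asarray(table if table is not None else values)
        if tab.ndim != 2 or tab.shape != (2, 2):
            raise ValueError("fisher test requires a 2x2 contingency table")
        odds, p = stats.fisher_exact(tab)
        return AssociationRecord(target="fisher", kind="fisher_or", estimate=float(odds), p=float(p))
    if kind == "paired_wilcoxon":
        first, second = values
        first = np.asarray(first, dtype=float)
        second = np.asarray(second, dtype=float)
        if len(first) == 0 or len(first) != len(second):
            raise ValueError("paired test needs two equal-length non-empty arrays")
        res = stats.wilcoxon(first, second)
        return AssociationRecord(target="paired", kind="paired_wilcoxon",
                                 estimate=float(res.statistic), p=float(res.pvalue))

    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    labels = pd.unique(group_labels)
    samples = [values[group_labels == lbl] for lbl in labels]
    if any(len(s) == 0 for s in samples):
        raise ValueError("empty group")
    if kind == "wilcoxon":
        if len(samples) != 2:
            raise ValueError("rank-sum test requires exactly 2 groups")
        stat, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
    elif kind == "t":
        if len(samples) != 2:
            raise ValueError("t-test requires exactly 2 groups")
        stat, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
    elif kind == "kruskal":
        if len(samples) < 2:
            raise ValueError("Kruskal–Wallis requires at least 2 groups")
        stat, p = stats.kruskal(*samples)
    else:
        raise ValueError(f"unknown test kind {kind!r}")
    return AssociationRecord(target=kind, kind=kind, estimate=float(stat), p=float(p))


def differential_filter(
    expression: pd.DataFrame,
    groups: pd.Series,
    lfc_cut: float = 1.0,
    padj_cut: float = 0.05,
) -> pd.DataFrame:
    """Differential genes between the high and low score groups.

    log2FC is the difference of group means on the (already log2) matrix;
    Welch t-test per gene; BH over all genes; kept genes satisfy
    |log2FC| > lfc_cut and padj < padj_cut.  Returns the full per-gene table
    with a boolean ``selected`` column, sorted by gene id.
    """
    groups = groups.reindex(expression.columns)
    labels = sorted(groups.dropna().unique().tolist())  # "high" sorts before "low"
    if len(labels) != 2:
        raise ValueError(f"differential filter needs exactly 2 groups, got {labels}")
    a_cols = expression.columns[(groups == labels[0]).to_numpy()]
    b_cols = expression.columns[(groups == labels[1]).to_numpy()]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("each group needs at least 2 samples")
    a = expression[a_cols].to_numpy(dtype=float)
    b = expression[b_cols].to_numpy(dtype=float)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    _, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    padj = bh_adjust(p)
    out = pd.DataFrame(
        {"gene": expression.index, "log2fc": lfc, "p": p, "padj": padj}
    ).sort_values("gene", kind="stable").reset_index(drop=True)
    out["selected"] = (out["log2fc"].abs() > lfc_cut) & (out["padj"] < padj_cut)
    return out
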