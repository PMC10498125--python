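"""Single-sample gene-set enrichment (GSVA-style rank random walk) and the
directional set score.

The statistic is computed in three stages:

1. *Kernel CDF estimate.* For gene i and sample j,
   z_ij = (1/n) * sum_k Phi((x_ij - x_ik) / h_i) with a Gaussian kernel and
   per-gene bandwidth h_i = sd_i / 4 (an empirical-CDF variant is available;
   it is exactly invariant under strictly monotone per-gene transforms).
2. *Symmetric rank statistic.* Within each sample, genes are ranked by z in
   descending order (ties broken by gene identifier); the statistic is
   r_ij = |p/2 - rank_ij| where p is the gene count, so mid-ranked genes
   carry no weight and extreme genes carry the most.
3. *Random walk.* Walking the genes of a sample in descending-z order,
   in-set genes add |r|^tau normalized over the set, out-of-set genes
   subtract 1/(p - |set|).  The enrichment score is the maximum positive
   deviation plus the minimum negative deviation of the walk (the
   magnitude-difference variant), hence always in [-1, 1].

The directional score of a sample is ES(positive set) - ES(negative set);
samples are split into high/low groups at the cohort-wise median (scores at
exactly the median fall to the low group).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "RankStats",
    "kernel_cdf_stat",
    "enrichment_score",
    "set_scores",
    "compute_kifscore",
    "split_by_median",
]

_BANDWIDTH_FLOOR_SCALE = 1e-8


@dataclasses.dataclass
class RankStats:
    """Per-sample gene ordering and symmetric rank statistics.

    order:  (p, n) integer array; column j lists gene row indices in the
            walk order of sample j (descending kernel-CDF value).
    r:      (p, n) float array of |p/2 - rank| aligned with the *original*
            gene order of the expression matrix.
    genes / samples: the matrix labels.
    bandwidths: per-gene kernel bandwidths actually used.
    """

    order: np.ndarray
    r: np.ndarray
    genes: pd.Index
    samples: pd.Index
    bandwidths: np.ndarray
    z: np.ndarray | None = None


def kernel_cdf_stat(
    expression: pd.DataFrame,
    kernel: str = "gauss",
    bandwidth_factor: float = 4.0,
) -> RankStats:
    """Stage 1+2: kernel CDF estimates and symmetric rank statistics.

    Zero-variance genes get a floored bandwidth (1e-8 * (global sd + 1)) so
    they receive mid-rank statistics instead of dividing by zero.  Rank ties
    are broken by gene-identifier lexicographic order, making the whole
    computation deterministic.
    """
    values = expression.to_numpy(dtype=float)
    p, n = values.shape
    if n < 2:
        raise ValueError("kernel CDF estimation requires at least 2 samples")
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")

    if kernel == "gauss":
        sd = values.std(axis=1, ddof=1)
        floor = _BANDWIDTH_FLOOR_SCALE * (values.std() + 1.0)
        h = np.maximum(sd / bandwidth_factor, floor)
        # z_ij = mean_k Phi((x_ij - x_ik) / h_i), one (n, n) block per gene
        diffs = (values[:, :, None] - values[:, None, :]) / h[:, None, None]
        z = norm.cdf(diffs).mean(axis=2)
    elif kernel == "ecdf":
        h = np.zeros(p)
        z = np.empty_like(values)
        for i in range(p):
            z[i] = (values[i][:, None] >= values[i][None, :]).mean(axis=1)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")

    # descending-z order per sample, ties by gene id (lexicographic)
    gene_rank_key = np.argsort(np.argsort(expression.index.to_numpy().astype(str)))
    order = np.empty((p, n), dtype=int)
    r = np.empty((p, n), dtype=float)
    half_p = p / 2.0
    for j in range(n):
        idx = np.lexsort((gene_rank_key, -z[:, j]))
        order[:, j] = idx
        ranks = np.empty(p, dtype=float)
        ranks[idx] = np.arange(1, p + 1)
        r[:, j] = np.abs(half_p - ranks)
    return RankStats(order=order, r=r, genes=expression.index,
                     samples=expression.columns, bandwidths=h, z=z)


def _membership(rank_stats: RankStats, gene_set) -> np.ndarray:
    gene_set = set(gene_set)
    if not gene_set:
        raise ValueError("empty gene set")
    members = rank_stats.genes.isin(gene_set)
    if not members.any():
        raise ValueError("gene set shares no genes with the matrix universe")
    if members.all():
        raise ValueError("gene set equals the gene universe; outside-step undefined")
    return members


def enrichment_score(rank_stats: RankStats, gene_set, tau: float = 1.0) -> pd.Series:
    """Stage 3: the walk statistic of one gene set, for every sample.

    Returns a Series of enrichment scores indexed by sample.  If every
    in-set statistic is exactly zero (possible only for tiny sets at even
    p), in-set steps fall back to uniform weights 1/|set|.
    """
    members = _membership(rank_stats, gene_set)
    p, n = rank_stats.r.shape
    n_out = p - members.sum()
    es = np.empty(n)
    for j in range(n):
        idx = rank_stats.order[:, j]
        in_set = members[idx]
        w = rank_stats.r[idx, j] ** tau
        w_in = np.where(in_set, w, 0.0)
        denom = w_in.sum()
        if denom > 0:
            steps = w_in / denom
        else:
            steps = in_set / members.sum()
        steps = steps - (~in_set) / n_out
        walk = np.cumsum(steps)
        es[j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
    return pd.Series(es, index=rank_stats.samples, name="es")


def set_scores(
    expression: pd.DataFrame,
    positive_set,
    negative_set,
    tau: float = 1.0,
    kernel: str = "gauss",
    bandwidth_factor: float = 4.0,
) -> pd.DataFrame:
    """Both set activities and their difference for one expression matrix."""
    positive = [g for g in positive_set if g in expression.index]
    negative = [g for g in negative_set if g in expression.index]
    if not positive:
        raise ValueError("positive set is empty after intersecting with the matrix")
    if not negative:
        raise ValueError("negative set is empty after intersecting with the matrix")
    rank_stats = kernel_cdf_stat(expression, kernel=kernel, bandwidth_factor=bandwidth_factor)
    es_pos = enrichment_score(rank_stats, positive, tau=tau)
    es_neg = enrichment_score(rank_stats, negative, tau=tau)
    return pd.DataFrame(
        {"sample": expression.columns, "es_positive": es_pos.to_numpy(),
         "es_negative": es_neg.to_numpy(),
         "kifscore": es_pos.to_numpy() - es_neg.to_numpy()}
    )


def compute_kifscore(
    expression: pd.DataFrame,
    positive_set,
    negative_set,
    cohorts: pd.Series | None = None,
    tau: float = 1.0,
    kernel: str = "gauss",
    bandwidth_factor: float = 4.0,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-sample directional score with cohort-wise median-split grouping.

    cohorts maps sample id -> cohort label.  By default the kernel CDF (and
    hence the whole score) is estimated within each cohort, matching the
    per-cohort median split; ``pooled=True`` estimates it once on the full
    matrix.  Without cohort labels all samples form one cohort.
    """
    if cohorts is None:
        cohorts = pd.Series("all", index=expression.columns)
    cohorts = cohorts.reindex(expression.columns)
    if cohorts.isna().any():
        missing = list(expression.columns[cohorts.isna()])
        raise ValueError(f"samples without cohort label: {missing[:5]}")

    if pooled:
        scores = set_scores(expression, positive_set, negative_set,
                            tau=tau, kernel=kernel, bandwidth_factor=bandwidth_factor)
        scores["cohort"] = cohorts.to_numpy()
    else:
        parts = []
        for cohort in pd.unique(cohorts):
            cols = expression.columns[(cohorts == cohort).to_numpy()]
            part = set_scores(expression[cols], positive_set, negative_set,
                              tau=tau, kernel=kernel, bandwidth_factor=bandwidth_factor)
            part["cohort"] = cohort
            parts.append(part)
        scores = pd.concat(parts, ignore_index=True)
        scores = scores.set_index("sample").loc[expression.columns]
        scores.index.name = "sample"
        scores = scores.reset_index()
    return split_by_median(scores)


def split_by_median(scores: pd.DataFrame) -> pd.DataFrame:
    """Cohort-wise median split: score > median -> 'high', else 'low'.

    Requires at least 2 samples per cohort (a singleton cohort has no
    meaningful split).
    """
    scores = scores.copy()
    groups = pd.Series(index=scores.index, dtype=object)
    for cohort, grp in scores.groupby("cohort"):
        if len(grp) < 2:
            raise ValueError(f"cohort {cohort!r} has fewer than 2 samples")
        med = grp["kifscore"].median()
        groups.loc[grp.index] = np.where(grp["kifscore"] > med, "high", "low")
    scores["group"] = groups
    return scores
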