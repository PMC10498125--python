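"""Per-gene univariate proportional-hazards screening and the majority-vote
partition of a gene family into positive (mostly high-risk) and negative sets.

The screen fits, for each gene within each cohort, a single-covariate Cox
model of the survival endpoint on continuous expression.  A gene is
*high-risk* in a cohort when the Wald p-value is below alpha and the hazard
ratio exceeds 1, *low-risk* when p < alpha and HR < 1.  Across cohorts, a
gene whose high-risk count strictly exceeds its low-risk count joins the
positive set; every other screened gene (ties, never-significant) falls to
the negative set.

The Cox engine is a Newton solver on the Breslow partial likelihood: tied
event times each contribute a full risk-set term.  Iterations are capped and
step-halved on likelihood decrease; a non-converged fit is reported as
not-significant rather than propagating a spurious estimate.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("kifscore")

HIGH_RISK = "high_risk"
LOW_RISK = "low_risk"
NOT_SIGNIFICANT = "not_significant"

_MAX_NEWTON_STEPS = 100
_NEWTON_TOL = 1e-9


@dataclasses.dataclass
class CoxResult:
    """Single-covariate Cox fit: hazard ratio, Wald inference, convergence flag."""

    log_hr: float
    hr: float
    se: float
    p: float
    ci_low: float
    ci_high: float
    converged: bool


def breslow_loglik(beta: float, x: np.ndarray, times: np.ndarray, events: np.ndarray) -> float:
    """Breslow log partial likelihood of a single coefficient.

    Each event contributes beta*x_i - log(sum of exp(beta*x_j) over the risk
    set at its time); tied events repeat the full risk-set term.
    """
    eta = beta * x
    ll = 0.0
    for i in np.flatnonzero(events == 1):
        at_risk = times >= times[i]
        ll += eta[i] - np.log(np.sum(np.exp(eta[at_risk])))
    return float(ll)


def _score_info(beta: float, x: np.ndarray, times: np.ndarray, events: np.ndarray) -> tuple[float, float, float]:
    """(log-likelihood, score, observed information) at beta, vectorized.

    Sorting by descending time turns every risk-set sum into a prefix
    cumulative sum.
    """
    order = np.argsort(-times, kind="stable")
    x_s = x[order]
    t_s = times[order]
    e_s = events[order]
    w = np.exp(beta * x_s)
    s0 = np.cumsum(w)
    s1 = np.cumsum(w * x_s)
    s2 = np.cumsum(w * x_s * x_s)
    # risk set of event i = all samples with time >= t_i; with descending
    # sort, that is the prefix ending at the last index sharing t_i
    last_idx = np.searchsorted(-t_s, -t_s, side="right") - 1
    ev = e_s == 1
    idx = last_idx[ev]
    ll = float(np.sum(beta * x_s[ev] - np.log(s0[idx])))
    mean1 = s1[idx] / s0[idx]
    score = float(np.sum(x_s[ev] - mean1))
    info = float(np.sum(s2[idx] / s0[idx] - mean1**2))
    return ll, score, info


def fit_univariate_cox(
    x: np.ndarray | pd.Series,
    times: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
) -> CoxResult:
    """Fit hazard = h0(t) * exp(beta * x) by Breslow partial likelihood.

    Raises ValueError for zero events or a constant covariate; both make the
    coefficient unidentifiable.
    """
    x = np.asarray(x, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    if x.shape != times.shape or x.shape != events.shape:
        raise ValueError("covariate, times and events must have equal length")
    if not np.isfinite(x).all():
        raise ValueError("non-finite covariate values")
    if events.sum() == 0:
        raise ValueError("no events: cannot fit Cox model")
    if np.ptp(x) == 0:
        raise ValueError("constant covariate: coefficient unidentifiable")

    # standardize internally for conditioning; rescale the estimate after
    scale = x.std()
    z = (x - x.mean()) / scale

    beta = 0.0
    ll, score, info = _score_info(beta, z, times, events)
    converged = False
    for _ in range(_MAX_NEWTON_STEPS):
        if info <= 0:
            break
        step = score / info
        new_beta = beta + step
        new_ll, new_score, new_info = _score_info(new_beta, z, times, events)
        # step-halving if the likelihood went down or overflowed
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_score, new_info = _score_info(new_beta, z, times, events)
            halvings += 1
        if abs(new_beta - beta) < _NEWTON_TOL:
            beta, ll, score, info = new_beta, new_ll, new_score, new_info
            converged = True
            break
        beta, ll, score, info = new_beta, new_ll, new_score, new_info

    beta_x = beta / scale
    se_x = (1.0 / np.sqrt(info)) / scale if info > 0 else np.inf
    zstat = beta_x / se_x if np.isfinite(se_x) and se_x > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(zstat)))
    half = 1.959963984540054 * se_x
    return CoxResult(
        log_hr=float(beta_x),
        hr=float(np.exp(beta_x)),
        se=float(se_x),
        p=p,
        ci_low=float(np.exp(beta_x - half)),
        ci_high=float(np.exp(beta_x + half)),
        converged=converged,
    )


def classify_gene(hr: float, p: float, alpha: float = 0.05) -> str:
    """Risk class from a univariate fit: high_risk (p<alpha, HR>1),
    low_risk (p<alpha, HR<1), otherwise not_significant."""
    if p < alpha and hr > 1:
        return HIGH_RISK
    if p < alpha and hr < 1:
        return LOW_RISK
    return NOT_SIGNIFICANT


def screen_genes(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    endpoint: str = "OS",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate Cox of every gene within every cohort.

    Returns one record per (gene, cohort): HR, p, 95% CI and risk class.
    Samples missing the endpoint are excluded listwise; cohorts with no
    events or a constant gene are recorded as not_significant.
    """
    tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
    clin = clinical.dropna(subset=[tcol, ecol])
    records = []
    for cohort, grp in clin.groupby("cohort", sort=True):
        samples = [s for s in grp["sample"] if s in expression.columns]
        sub = grp.set_index("sample").loc[samples]
        times = sub[tcol].to_numpy(dtype=float)
        events = sub[ecol].to_numpy(dtype=float)
        for gene in expression.index:
            xs = expression.loc[gene, samples].to_numpy(dtype=float)
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    fit = fit_univariate_cox(xs, times, events)
            except ValueError:
                records.append(
                    {"gene": gene, "cohort": cohort, "hr": np.nan, "p": np.nan,
                     "ci_low": np.nan, "ci_high": np.nan, "class": NOT_SIGNIFICANT}
                )
                continue
            if not fit.converged:
                logger.warning("Cox did not converge for gene %s in cohort %s", gene, cohort)
                cls = NOT_SIGNIFICANT
            else:
                cls = classify_gene(fit.hr, fit.p, alpha)
            records.append(
                {"gene": gene, "cohort": cohort, "hr": fit.hr, "p": fit.p,
                 "ci_low": fit.ci_low, "ci_high": fit.ci_high, "class": cls}
            )
    return pd.DataFrame.from_records(records)


def partition_genes(
    records: pd.DataFrame,
    drop_never_significant: bool = False,
) -> tuple[list[str], list[str]]:
    """Majority vote across cohorts: more high-risk cohorts than low-risk
    cohorts puts a gene in the positive set; everything else (ties included)
    falls to the negative set.

    With ``drop_never_significant``, genes significant in no cohort are
    excluded from both sets instead.
    """
    if records.empty:
        raise ValueError("empty record set: nothing to partition")
    positive, negative = [], []
    for gene, grp in records.groupby("gene", sort=True):
        n_high = int((grp["class"] == HIGH_RISK).sum())
        n_low = int((grp["class"] == LOW_RISK).sum())
        if drop_never_significant and n_high == 0 and n_low == 0:
            continue
        if n_high > n_low:
            positive.append(gene)
        else:
            negative.append(gene)
    return positive, negative
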