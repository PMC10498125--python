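import numpy as np
import pandas as pd
import pytest

from kifscore import synthetic_cohort as sc
from kifscore.io_core import toy_arm_model


@pytest.fixture(scope="session")
def arms():
    return toy_arm_model()


@pytest.fixture(scope="session")
def small_bundle():
    """Two cohorts of 100 samples, 4+4 truth genes among 20 — fast shared cohort."""
    spec = sc.CohortSpec(
        n_samples=100, n_cohorts=2, n_genes=20, n_positive=4, n_negative=4, seed=3
    )
    return sc.generate_cohort(spec)


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive; never share code with the package)


def naive_enrichment_score(values_one_sample, z_column, gene_ids, gene_set, tau):
    """Literal step-by-step walk over genes ordered by descending kernel-CDF
    value (ties by gene id), tracking extreme deviations."""
    order = sorted(range(len(gene_ids)), key=lambda i: (-z_column[i], gene_ids[i]))
    p = len(gene_ids)
    ranks = {}
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    r = {i: abs(p / 2.0 - ranks[i]) for i in range(p)}
    inside = [i for i in range(p) if gene_ids[i] in gene_set]
    denom = sum(r[i] ** tau for i in inside)
    n_out = p - len(inside)
    v, vmax, vmin = 0.0, 0.0, 0.0
    for i in order:
        if gene_ids[i] in gene_set:
            v += (r[i] ** tau) / denom if denom > 0 else 1.0 / len(inside)
        else:
            v -= 1.0 / n_out
        vmax = max(vmax, v)
        vmin = min(vmin, v)
    return vmax + vmin


def naive_breslow_loglik(beta, x, times, events):
    """Double-loop Breslow log partial likelihood."""
    ll = 0.0
    for i in range(len(x)):
        if events[i] == 1:
            risk = sum(np.exp(beta * x[j]) for j in range(len(x)) if times[j] >= times[i])
            ll += beta * x[i] - np.log(risk)
    return ll


def grid_search_breslow(x, times, events, lo=-5.0, hi=5.0, tol=1e-6):
    """Brute-force maximizer of the Breslow partial likelihood: coarse grid
    followed by repeated refinement around the best point."""
    for _ in range(8):
        grid = np.linspace(lo, hi, 101)
        lls = [naive_breslow_loglik(b, x, times, events) for b in grid]
        best = grid[int(np.argmax(lls))]
        width = (hi - lo) / 10
        lo, hi = best - width, best + width
        if width < tol:
            break
    return best
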