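"""Independent brute-force oracles used by the test-suite.

Each oracle is deliberately written in the most literal way possible
(explicit loops, exact tail sums, textbook formulas) and shares no code
with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import rankdata


def bh_fdr_bruteforce(p):
    """O(m^2) Benjamini-Hochberg: q_i = min over {j: p_j >= p_i} of p_j*m/rank_j."""
    p = list(map(float, p))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, i in enumerate(order):
        best = math.inf
        for pos2 in range(pos, m):
            j = order[pos2]
            best = min(best, p[j] * m / (pos2 + 1))
        q[i] = min(best, 1.0)
    return q


def spearman_bruteforce(x, y):
    """Rank-transform then textbook Pearson."""
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    mx, my = rx.mean(), ry.mean()
    num = float(np.sum((rx - mx) * (ry - my)))
    den = math.sqrt(float(np.sum((rx - mx) ** 2)) * float(np.sum((ry - my) ** 2)))
    return num / den


def partial_spearman_residual(x, y, z):
    """Residual-regression oracle: regress ranks of x and y on ranks of z,
    then Pearson-correlate the residuals."""
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    rz = rankdata(z, method="average")
    zc = np.column_stack([np.ones(len(rz)), rz])
    bx, *_ = np.linalg.lstsq(zc, rx, rcond=None)
    by, *_ = np.linalg.lstsq(zc, ry, rcond=None)
    ex = rx - zc @ bx
    ey = ry - zc @ by
    return float(np.sum(ex * ey) / math.sqrt(np.sum(ex**2) * np.sum(ey**2)))


def ssgsea_bruteforce(ranks, mask, alpha):
    """Explicit double-loop ECDF summation of the ssGSEA running statistic."""
    n = len(ranks)
    order = sorted(range(n), key=lambda i: (-ranks[i], i))
    denom_in = sum(ranks[i] ** alpha for i in order if mask[i])
    n_out = sum(1 for i in order if not mask[i])
    es = 0.0
    for pos in range(n):
        cin = 0.0
        cout = 0
        for pos2 in range(pos + 1):
            i = order[pos2]
            if mask[i]:
                cin += ranks[i] ** alpha
            else:
                cout += 1
        es += cin / denom_in - cout / n_out
    return es


def binom_tail_bruteforce(k, n, p, alternative="greater"):
    """Exact binomial tail by direct summation of pmf terms."""

    def pmf(j):
        return math.comb(n, j) * p**j * (1 - p) ** (n - j)

    if alternative == "greater":
        return sum(pmf(j) for j in range(k, n + 1))
    return sum(pmf(j) for j in range(0, k + 1))


def cox_newton_bruteforce(x, time, event, tol=1e-12, max_iter=100):
    """Newton-Raphson on the Cox partial likelihood, distinct event times.

    Single covariate, Breslow form (equals Efron when no ties).  Returns the
    maximum-partial-likelihood estimate of beta.
    """
    x = np.asarray(x, float)
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    assert len(set(time[event == 1])) == event.sum(), "tied event times"
    beta = 0.0
    for _ in range(max_iter):
        u = 0.0
        info = 0.0
        for i in np.flatnonzero(event):
            risk = time >= time[i]
            w = np.exp(beta * x[risk])
            s0 = w.sum()
            s1 = (w * x[risk]).sum()
            s2 = (w * x[risk] ** 2).sum()
            u += x[i] - s1 / s0
            info += s2 / s0 - (s1 / s0) ** 2
        step = u / info
        beta += step
        if abs(step) < tol:
            break
    return beta


def common_dependency_bruteforce(score_matrix, gene_ids, percentile, top_fraction):
    """Explicit sort + quantile common-dependency flags.

    ``score_matrix`` is genes x lines.  Returns (stat list, flag list).
    """
    mat = np.asarray(score_matrix, float)
    n_genes, n_lines = mat.shape
    norm_ranks = np.empty_like(mat)
    for j in range(n_lines):
        norm_ranks[:, j] = rankdata(mat[:, j], method="average") / n_genes
    stats = [float(np.quantile(norm_ranks[i], percentile, method="linear"))
             for i in range(n_genes)]
    k = math.ceil(n_genes * top_fraction)
    order = sorted(range(n_genes), key=lambda i: (stats[i], gene_ids[i]))
    flagged = set(order[:k])
    return stats, [i in flagged for i in range(n_genes)]


def uq_logcpm_bruteforce(counts, pseudocount=0.5):
    """Two-step oracle: upper-quartile scale factors, then log2-CPM."""
    mat = np.asarray(counts, float)
    lib = mat.sum(axis=0)
    uq = np.array([np.quantile(c[c > 0], 0.75) for c in mat.T])
    rel = uq / lib
    factors = rel / np.exp(np.mean(np.log(rel)))
    eff = lib * factors
    out = np.empty_like(mat)
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            out[i, j] = math.log2((mat[i, j] + pseudocount) / (eff[j] + 1.0) * 1e6)
    return out


def pan_label_bruteforce(n_up, n_down, min_n=3, ratio=3.0):
    """Literal restatement of the pan-cancer rule."""
    up_ok = n_up >= min_n and n_up >= ratio * n_down
    down_ok = n_down >= min_n and n_down >= ratio * n_up
    if up_ok:
        return "pan-up"
    if down_ok:
        return "pan-down"
    return "neither"
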