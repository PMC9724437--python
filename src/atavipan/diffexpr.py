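"""Tumor-vs-normal differential expression and pan-cancer up/down classification.

Counts are upper-quartile normalized and transformed to log2-CPM; a moderated
two-group t-test with empirical-Bayes variance shrinkage (a Smyth-style prior
fitted by method of moments) supplies per-gene p-values, corrected per cancer
type by Benjamini-Hochberg.  A gene is called *up* in a cancer when
FDR < alpha and log2FC >= +lfc (direction-specific), mirrored for *down*.

The pan-cancer rule: a gene is pan-cancer upregulated when it is up in at
least ``min_n`` cancer types and the number of up cancers is at least
``ratio`` times the number of down cancers (mirrored for pan-down).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "normalize_and_transform",
    "moderated_two_group_test",
    "bh_fdr",
    "classify_pan_cancer",
]


def normalize_and_transform(
    counts: pd.DataFrame, pseudocount: float = 0.5
) -> pd.DataFrame:
    """Upper-quartile-scaled log2-CPM transform of a genes x samples count matrix.

    Per sample the upper quartile of the nonzero counts defines a scaling
    factor (relative to the geometric mean of all samples' upper quartiles);
    the effective library size is total counts times that factor.  Values are
    log2((count + pseudocount) / (effective library + 1) * 1e6).
    """
    mat = counts.to_numpy(dtype=float)
    if (mat < 0).any():
        raise ValueError("counts must be nonnegative")
    if mat.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    lib = mat.sum(axis=0)
    if (lib == 0).any():
        raise ValueError("zero-count sample")
    uq = np.array([np.quantile(col[col > 0], 0.75) for col in mat.T])
    uq_rel = uq / lib
    factors = uq_rel / np.exp(np.mean(np.log(uq_rel)))
    eff_lib = lib * factors
    logcpm = np.log2((mat + pseudocount) / (eff_lib + 1.0) * 1e6)
    return pd.DataFrame(logcpm, index=counts.index, columns=counts.columns)


def _fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Returns (d0, s0^2): prior degrees of freedom and prior variance.  With a
    single gene (or no spread in the log-variances) there is no information
    about the prior and d0 = 0, i.e. no shrinkage.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return 0.0, float(s2[ok][0]) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1)
    target = evar - special.polygamma(1, df / 2.0)
    if target <= 0:
        # log-variances less dispersed than the chi-square alone: infinite
        # prior d.f.; shrink fully to the common value.
        d0 = np.inf
        s0 = float(np.exp(emean))
        return d0, s0
    # solve trigamma(d0/2) = target for d0 by Newton on x = d0/2
    x = 0.5 + 1.0 / target
    for _ in range(100):
        tri = special.polygamma(1, x)
        step = tri * (1.0 - tri / target) / special.polygamma(2, x)
        x += step
        if abs(step) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s0 = float(np.exp(emean + special.digamma(x) - np.log(x)))
    return float(d0), s0


@dataclass
class ModeratedTestResult:
    table: pd.DataFrame  # gene-indexed: log2fc, t, p, fdr, call
    prior_df: float
    prior_var: float


def moderated_two_group_test(
    logexpr: pd.DataFrame,
    groups,
    alpha: float = 0.05,
    lfc: float = 0.4,
) -> ModeratedTestResult:
    """Moderated t-test of tumor vs normal on a log-expression matrix.

    ``groups`` labels each column ``"tumor"`` or ``"normal"`` (>= 2 samples
    each).  log2FC = mean(tumor) - mean(normal); the pooled per-gene variance
    is shrunk toward a prior fitted across genes, and the t statistic is
    referred to a t distribution with (residual + prior) degrees of freedom.
    BH FDR is computed across genes; calls are direction-specific
    (up: FDR < alpha and log2FC >= +lfc; down mirrored).
    """
    groups = np.asarray(groups)
    t_mask = groups == "tumor"
    n_mask = groups == "normal"
    n1, n2 = int(t_mask.sum()), int(n_mask.sum())
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    df = n1 + n2 - 2
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")

    mat = logexpr.to_numpy(dtype=float)
    m1 = mat[:, t_mask].mean(axis=1)
    m2 = mat[:, n_mask].mean(axis=1)
    ss1 = mat[:, t_mask].var(axis=1, ddof=1) * (n1 - 1)
    ss2 = mat[:, n_mask].var(axis=1, ddof=1) * (n2 - 1)
    s2 = (ss1 + ss2) / df

    d0, s0 = _fit_variance_prior(s2, df)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
        df_total = np.inf
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df) if d0 > 0 else s2
        df_total = d0 + df

    lfc_hat = m1 - m2
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = lfc_hat / se
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(tstat))
    else:
        p = 2.0 * stats.t.sf(np.abs(tstat), df_total)
    p = np.where(se == 0, np.where(lfc_hat == 0, 1.0, 0.0), p)
    fdr = bh_fdr(p)
    call = np.where(
        (fdr < alpha) & (lfc_hat >= lfc), "up",
        np.where((fdr < alpha) & (lfc_hat <= -lfc), "down", "ns"),
    )
    tab = pd.DataFrame(
        {"log2fc": lfc_hat, "t": tstat, "p": p, "fdr": fdr, "call": call},
        index=logexpr.index,
    )
    return ModeratedTestResult(table=tab, prior_df=float(d0), prior_var=float(s0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone in p)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def classify_pan_cancer(
    de_tables: dict[str, pd.DataFrame],
    min_n: int = 3,
    ratio: float = 3.0,
) -> pd.DataFrame:
    """Pan-cancer up/down labels from per-cancer differential-expression calls.

    ``de_tables`` maps cancer type -> gene-indexed table with a ``call``
    column (up/down/ns).  A gene is pan-up iff n_up >= ``min_n`` and
    n_up >= ``ratio`` * n_down; pan-down mirrored; otherwise neither.
    """
    genes = sorted(set().union(*(t.index for t in de_tables.values())))
    n_up = pd.Series(0, index=genes, dtype=int)
    n_down = pd.Series(0, index=genes, dtype=int)
    for tab in de_tables.values():
        call = tab["call"]
        n_up = n_up.add((call == "up").astype(int), fill_value=0).astype(int)
        n_down = n_down.add((call == "down").astype(int), fill_value=0).astype(int)
    label = np.where(
        (n_up >= min_n) & (n_up >= ratio * n_down), "pan-up",
        np.where((n_down >= min_n) & (n_down >= ratio * n_up), "pan-down", "neither"),
    )
    return pd.DataFrame({"n_up": n_up, "n_down": n_down, "label": label}, index=genes)


def pan_cancer_label(n_up: int, n_down: int, min_n: int = 3, ratio: float = 3.0) -> str:
    """Label a single (n_up, n_down) pair under the pan-cancer rule."""
    if n_up >= min_n and n_up >= ratio * n_down:
        return "pan-up"
    if n_down >= min_n and n_down >= ratio * n_up:
        return "pan-down"
    return "neither"
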