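"""Single-sample gene set enrichment (ssGSEA) scoring with group rescaling.

Expression values are rank-normalized within each sample; the enrichment
score of a gene set is the sum, over the gene list ordered by decreasing
rank, of the difference between a rank-weighted in-set ECDF (weight
rank^alpha, alpha = 0.25 by default) and the uniform out-of-set ECDF.  The
score therefore depends only on the within-sample ranking and is invariant
to any strictly monotone transform of the expression values.

Raw scores are rescaled per age group and cancer type: divide by the
(max - min) range across that cancer's samples, then subtract the median of
the normal samples so that the normal median is 0 by construction.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

__all__ = ["rank_normalize", "ssgsea_es", "score_samples", "rescale_scores"]


def rank_normalize(values) -> np.ndarray:
    """Within-sample rank normalization: ranks 1..G, average ranks for ties,
    highest expression = highest rank."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 genes")
    return rankdata(x, method="average")


def ssgsea_es(ranks, in_set, alpha: float = 0.25) -> float:
    """Raw ssGSEA enrichment score of one gene set in one sample.

    Parameters
    ----------
    ranks : per-gene rank values (output of :func:`rank_normalize`).
    in_set : boolean mask (or index array) marking gene-set membership.
    alpha : rank-weighting exponent.

    Walking the genes in decreasing rank order, the score accumulates
    P_in(i) - P_out(i), where P_in is the in-set ECDF weighted by rank^alpha
    and P_out is the unweighted out-of-set ECDF.  The sum statistic (not the
    extremum) is used.
    """
    r = np.asarray(ranks, dtype=float)
    sel = np.asarray(in_set)
    if sel.dtype == bool:
        mask = sel.copy()
    else:
        mask = np.zeros(r.size, dtype=bool)
        mask[sel] = True
    n = r.size
    n_in = int(mask.sum())
    if n_in == 0 or n_in == n:
        raise ValueError("gene set must be a proper nonempty subset of the universe")
    order = np.argsort(-r, kind="stable")
    r_ord = r[order]
    m_ord = mask[order]
    w = np.where(m_ord, r_ord**alpha, 0.0)
    denom_in = w.sum()
    p_in = np.cumsum(w) / denom_in
    p_out = np.cumsum(~m_ord) / (n - n_in)
    return float(np.sum(p_in - p_out))


def score_samples(
    expr: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    alpha: float = 0.25,
) -> pd.DataFrame:
    """Raw ES for each sample x gene set on a genes x samples matrix.

    Genes absent from the matrix are dropped from each set; empty or
    universe-covering sets raise.
    """
    masks = {}
    for name, members in gene_sets.items():
        mask = expr.index.isin(members)
        masks[name] = mask
    rows = []
    mat = expr.to_numpy(dtype=float)
    for j, sample in enumerate(expr.columns):
        ranks = rank_normalize(mat[:, j])
        for name, mask in masks.items():
            rows.append((sample, name, ssgsea_es(ranks, mask, alpha=alpha)))
    return pd.DataFrame(rows, columns=["sample", "gene_set", "raw_es"])


def rescale_scores(
    scores: pd.DataFrame,
    sample_meta: pd.DataFrame,
) -> pd.DataFrame:
    """Rescale raw ES within each (cancer type, gene set) group.

    ``scores`` is long format (sample, gene_set, raw_es); ``sample_meta`` is
    indexed by sample with columns ``cancer_type`` and ``is_tumor``.  Per
    cancer type and gene set, scores are divided by the (max - min) range over
    that cancer's pooled tumor+normal samples and the normal-sample median is
    subtracted, anchoring the normal median at 0.  Degenerate groups (zero
    range) are skipped with a log entry.
    """
    df = scores.merge(
        sample_meta[["cancer_type", "is_tumor"]], left_on="sample", right_index=True
    )
    out = []
    for (cancer, gs), grp in df.groupby(["cancer_type", "gene_set"], sort=True):
        if not grp["is_tumor"].any() or grp["is_tumor"].all():
            raise ValueError(f"{cancer}/{gs}: need >= 1 tumor and >= 1 normal sample")
        rng = grp["raw_es"].max() - grp["raw_es"].min()
        if rng == 0:
            logger.warning("rescale_scores: constant scores for %s/%s, skipped", cancer, gs)
            continue
        scaled = grp["raw_es"] / rng
        med_norm = scaled[~grp["is_tumor"]].median()
        grp = grp.assign(rescaled_es=scaled - med_norm)
        out.append(grp)
    if not out:
        return df.iloc[0:0].assign(rescaled_es=pd.Series(dtype=float))
    return pd.concat(out, ignore_index=True)
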