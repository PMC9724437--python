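"""Purity-controlled coexpression partners and gene-set functional assignment.

Most primate-specific genes are uncharacterized, so function is inferred by
guilt-by-association: within each cancer type the Spearman correlation of a
query gene with every other retained gene is computed *partially*,
controlling for tumor purity (immune/stromal contamination drives spurious
co-variation); per-pair medians across cancer types define partners
(|median rho| >= cutoff, default 0.4), excluding same-chromosome genes whose
co-expression may only reflect chromosomal proximity.  Partners are then
tested for overrepresentation in each hallmark gene set with a one-sided
binomial test; a set is assigned when odds ratio > 1 and p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from .age import expressed_genes
from .diffexpr import bh_fdr

logger = logging.getLogger(__name__)


def partial_spearman(x, y, covariate) -> float:
    """First-order partial Spearman correlation of x and y given a covariate.

    All three vectors are rank-transformed (average ranks); then
    rho_xy.z = (rho_xy - rho_xz * rho_yz) / sqrt((1 - rho_xz^2)(1 - rho_yz^2)).
    Undefined (NaN) when |rho_xz| = 1 or |rho_yz| = 1 or any vector is
    constant.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    if not (x.size == y.size == z.size) or x.size < 10:
        raise ValueError("need equal-length vectors of size >= 10")
    rx, ry, rz = (rankdata(v, method="average") for v in (x, y, z))
    c = np.corrcoef(np.vstack([rx, ry, rz]))
    rxy, rxz, ryz = c[0, 1], c[0, 2], c[1, 2]
    if np.isnan(rxy) or np.isnan(rxz) or np.isnan(ryz):
        return float("nan")
    denom = (1.0 - rxz**2) * (1.0 - ryz**2)
    if denom <= 0:
        logger.info("partial_spearman: covariate perfectly correlated, undefined")
        return float("nan")
    return float((rxy - rxz * ryz) / np.sqrt(denom))


def _partial_spearman_vs_all(
    query_ranks: np.ndarray, gene_ranks: np.ndarray, purity_ranks: np.ndarray
) -> np.ndarray:
    """Vectorized partial Spearman of one query against every row of a rank
    matrix, controlling for the purity rank vector."""

    def _std(m):
        return (m - m.mean(axis=-1, keepdims=True)) / np.where(
            m.std(axis=-1, keepdims=True) == 0, np.nan, m.std(axis=-1, keepdims=True)
        )

    q = _std(query_ranks[None, :])[0]
    g = _std(gene_ranks)
    z = _std(purity_ranks[None, :])[0]
    n = query_ranks.size
    rxy = g @ q / n
    rxz = np.full(g.shape[0], np.dot(q, z) / n)
    ryz = g @ z / n
    denom = (1.0 - rxz**2) * (1.0 - ryz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (rxy - rxz * ryz) / np.sqrt(denom)
    out[denom <= 0] = np.nan
    return out


@dataclass
class PartnerSet:
    """Coexpression partners of one query gene."""

    query: str
    partners: list[str]
    median_rho: pd.Series  # per-partner median partial rho across cancers
    n_cancers: int = 0
    skipped_cancers: list[str] = field(default_factory=list)


def find_partners(
    query: str,
    cohorts: dict[str, pd.DataFrame],
    purity: dict[str, pd.Series],
    chrom: pd.Series,
    cutoff: float = 0.4,
    min_cancers: int = 3,
    max_zero_frac: float = 0.2,
) -> PartnerSet:
    """Median purity-controlled partial Spearman partners of a query gene.

    ``cohorts`` maps cancer type -> genes x tumor-sample expression matrix
    (the retained universe); ``purity`` the matching per-sample purity;
    ``chrom`` maps gene id -> chromosome.  Cancers where the query fails the
    expression filter (zero in more than ``max_zero_frac`` of samples) are
    skipped; at least ``min_cancers`` must remain, else the partner set is
    empty.  Partners satisfy |median rho| >= ``cutoff`` and lie on a
    different chromosome from the query.
    """
    per_cancer: dict[str, pd.Series] = {}
    skipped = []
    for cancer, expr in sorted(cohorts.items()):
        if query not in expr.index:
            skipped.append(cancer)
            continue
        ok_genes = expressed_genes(expr, max_zero_frac=max_zero_frac)
        if query not in ok_genes:
            skipped.append(cancer)
            continue
        sub = expr.loc[ok_genes]
        mat = sub.to_numpy(dtype=float)
        ranks = np.apply_along_axis(rankdata, 1, mat)
        pr = rankdata(purity[cancer].loc[sub.columns].to_numpy(dtype=float))
        qi = sub.index.get_loc(query)
        rho = _partial_spearman_vs_all(ranks[qi], ranks, pr)
        per_cancer[cancer] = pd.Series(rho, index=sub.index)
    if len(per_cancer) < min_cancers:
        logger.info(
            "find_partners[%s]: only %d usable cancers (< %d), no call",
            query, len(per_cancer), min_cancers,
        )
        return PartnerSet(query, [], pd.Series(dtype=float), len(per_cancer), skipped)
    med = pd.DataFrame(per_cancer).median(axis=1).drop(index=query)
    strong = med[med.abs() >= cutoff]
    diff_chrom = strong.index[chrom.loc[strong.index] != chrom.loc[query]]
    partners = sorted(diff_chrom)
    if not partners:
        logger.info("find_partners[%s]: no partner passed cutoff %.2f", query, cutoff)
    return PartnerSet(query, partners, med.loc[partners], len(per_cancer), skipped)


def _binom_greater(k: int, n: int, p: float) -> float:
    """One-sided binomial tail P(X >= k)."""
    return float(stats.binom.sf(k - 1, n, p)) if n > 0 else 1.0


def _odds_ratio(k: int, n: int, K: int, N: int) -> float:
    """Odds ratio of the 2x2 table (partners in/out of set vs rest of universe)."""
    a, b = k, n - k
    c, d = K - k, (N - n) - (K - k)
    if b == 0 or c == 0:
        return float("inf") if a > 0 and d >= 0 else float("nan")
    if a == 0 or d == 0:
        return 0.0
    return (a * d) / (b * c)


def assign_sets(
    partner_set: PartnerSet,
    gene_sets: dict[str, list[str]],
    universe,
    alpha: float = 0.05,
    exclude: set[str] | None = None,
) -> pd.DataFrame:
    """Hallmark assignment of one query from its partner list.

    For each set S (intersected with the universe minus the query):
    k = |partners in S| successes in n = |partners| trials at success
    probability |S| / |universe|, one-sided binomial tail; the odds ratio
    comes from the corresponding 2x2 table.  Assigned iff OR > 1 and
    p < ``alpha``.  ``exclude`` optionally removes genes (e.g. putative
    E2F-regulated targets) from the universe, partner list and sets before
    testing.
    """
    uni = set(universe) - {partner_set.query}
    if exclude:
        uni -= set(exclude)
    partners = [g for g in partner_set.partners if g in uni]
    n = len(partners)
    N = len(uni)
    rows = []
    for name in sorted(gene_sets):
        members = set(gene_sets[name]) & uni
        K = len(members)
        if K == 0 or N == 0:
            continue
        k = len(members.intersection(partners))
        p_set = K / N
        pval = _binom_greater(k, n, p_set)
        orat = _odds_ratio(k, n, K, N)
        rows.append((partner_set.query, name, k, n, K, N, orat, pval,
                     bool(orat > 1 and pval < alpha)))
    return pd.DataFrame(
        rows,
        columns=["query", "gene_set", "k", "n", "set_size", "universe_size",
                 "odds_ratio", "p", "assigned"],
    )


def group_overrepresentation(
    group,
    memberships: dict[str, list[str]],
    universe,
    alpha_fdr: float = 0.05,
) -> pd.DataFrame:
    """One-sided binomial overrepresentation of a gene group across sets.

    For each set (e.g. each hallmark, or a single curated cell-cycle list):
    k = |group in set| successes in n = |group| trials at the universe's
    membership fraction; BH FDR across sets.  Used both for
    hallmark-assignment summaries and for direct curated-list membership
    tests.
    """
    uni = set(universe)
    grp = [g for g in group if g in uni]
    n = len(grp)
    if n == 0:
        raise ValueError("empty group (after restricting to the universe)")
    rows = []
    for name in sorted(memberships):
        members = set(memberships[name]) & uni
        p_bg = len(members) / len(uni)
        k = len(members.intersection(grp))
        rows.append((name, k, n, p_bg, _binom_greater(k, n, p_bg)))
    out = pd.DataFrame(rows, columns=["gene_set", "k", "n", "background_p", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["enriched"] = out["fdr"] < alpha_fdr
    return out
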