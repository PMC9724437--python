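"""Attribution of tumor expression changes to copy number and promoter methylation.

Per cancer type, gene expression is Spearman-correlated with the gene-level
somatic copy-number (SCNA) score and with the beta value of one promoter
probe per gene.  Promoter probes lie within -1500..+500 bp of the principal
TSS (strand-aware, signed distance; negative = upstream); when a gene has
several, the probe with the strongest negative expression correlation is
kept.  A gene counts as *strongly* SCNA-driven when rho > cutoff and as
strongly methylation-driven when rho < -cutoff (strict inequalities,
default cutoff 0.3).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

PROMOTER_UPSTREAM = 1500  # bp 5' of the TSS
PROMOTER_DOWNSTREAM = 500  # bp 3' of the TSS


def spearman(x, y) -> float:
    """Spearman rank correlation with average-rank ties.

    Returns NaN when either vector is constant (undefined correlation).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = rankdata(x, method="average")
    ry = rankdata(y, method="average")
    sx = rx.std()
    sy = ry.std()
    if sx == 0 or sy == 0:
        return float("nan")
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def filter_probes(beta: pd.DataFrame, max_na: float = 0.05) -> pd.Index:
    """Retain probes whose NA fraction across this cancer's samples is <= max_na."""
    na_frac = beta.isna().to_numpy().mean(axis=1)
    keep = na_frac <= max_na
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_probes: %d probes dropped (> %.0f%% NA)", dropped, 100 * max_na)
    return beta.index[keep]


def annotate_probes(probe_bed: pd.DataFrame, catalog: pd.DataFrame) -> pd.DataFrame:
    """Signed strand-aware probe-to-TSS distances.

    ``probe_bed`` has BED-like columns (0-based half-open): chrom, start, end,
    probe_id, gene_id.  ``catalog`` is gene-indexed with chrom, tss, strand.
    The signed distance is (probe start - TSS) on the coding strand: negative
    = upstream (5') of the TSS.  A probe is a promoter probe when
    -PROMOTER_UPSTREAM <= distance <= +PROMOTER_DOWNSTREAM.
    """
    ann = probe_bed.merge(
        catalog[["chrom", "tss", "strand"]],
        left_on="gene_id", right_index=True, suffixes=("", "_gene"),
    )
    same_chrom = ann["chrom"] == ann["chrom_gene"]
    sign = np.where(ann["strand"] == "+", 1, -1)
    dist = sign * (ann["start"].to_numpy() - ann["tss"].to_numpy())
    ann = ann.assign(
        tss_distance=np.where(same_chrom, dist, np.nan),
        is_promoter=same_chrom
        & (dist >= -PROMOTER_UPSTREAM)
        & (dist <= PROMOTER_DOWNSTREAM),
    )
    return ann[["probe_id", "gene_id", "chrom", "start", "end", "tss_distance", "is_promoter"]]


def select_promoter_probe(
    annotation: pd.DataFrame,
    beta: pd.DataFrame,
    expression: pd.DataFrame,
) -> pd.Series:
    """One promoter probe per gene: the one most negatively correlated with
    expression (ties broken by lexicographically smallest probe id).

    ``beta`` (probes x samples) and ``expression`` (genes x samples) must
    share sample columns.  Genes without retained promoter probes are dropped.
    """
    promoter = annotation[annotation["is_promoter"] & annotation["probe_id"].isin(beta.index)]
    chosen: dict[str, str] = {}
    samples = beta.columns
    for gene, grp in promoter.groupby("gene_id", sort=True):
        if gene not in expression.index:
            continue
        ex = expression.loc[gene, samples].to_numpy(dtype=float)
        best = None
        for pid in sorted(grp["probe_id"]):
            b = beta.loc[pid, samples].to_numpy(dtype=float)
            ok = ~np.isnan(b)
            rho = spearman(ex[ok], b[ok]) if ok.sum() >= 3 else float("nan")
            if np.isnan(rho):
                continue
            if best is None or rho < best[0]:
                best = (rho, pid)
        if best is not None:
            chosen[gene] = best[1]
    return pd.Series(chosen, name="probe_id", dtype=object)


def expr_factor_correlation(
    expression: pd.DataFrame,
    factor: pd.DataFrame,
    factor_name: str,
    cancer_type: str,
    min_samples: int = 10,
) -> pd.DataFrame:
    """Per-gene Spearman rho between expression and a regulatory factor.

    Both frames are gene-indexed with identical (tumor) sample columns.
    Genes with a constant factor or expression vector (rho undefined) are
    excluded with a logged reason; pairs need >= ``min_samples`` complete
    observations.
    """
    common = expression.index.intersection(factor.index)
    rows = []
    skipped = 0
    for gene in common:
        x = expression.loc[gene].to_numpy(dtype=float)
        y = factor.loc[gene].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < min_samples:
            skipped += 1
            continue
        rho = spearman(x[ok], y[ok])
        if np.isnan(rho):
            skipped += 1
            continue
        rows.append((gene, cancer_type, factor_name, rho))
    if skipped:
        logger.info(
            "expr_factor_correlation[%s/%s]: %d genes excluded (constant or short)",
            cancer_type, factor_name, skipped,
        )
    return pd.DataFrame(rows, columns=["gene_id", "cancer_type", "factor", "rho"])


def strong_flag(corr: pd.DataFrame, cutoff: float = 0.3) -> pd.Series:
    """Strong-correlation flag: rho > cutoff for SCNA, rho < -cutoff for
    methylation (strict inequalities)."""
    is_scna = corr["factor"] == "SCNA"
    return pd.Series(
        np.where(is_scna, corr["rho"] > cutoff, corr["rho"] < -cutoff),
        index=corr.index,
    )


def strong_proportions(
    correlations: pd.DataFrame,
    gene_groups: pd.Series,
    cutoff: float = 0.3,
) -> pd.DataFrame:
    """Per cancer type x gene group: fraction of genes strongly correlated.

    ``correlations`` is the long table from :func:`expr_factor_correlation`
    (all cancers and factors concatenated); ``gene_groups`` maps gene id to a
    group label (age class, optionally with the broad/tissue-biased PSG
    split).  Returns long format with per-group cross-cancer medians
    attached.
    """
    df = correlations.copy()
    df["group"] = df["gene_id"].map(gene_groups)
    df = df.dropna(subset=["group"])
    df["strong"] = strong_flag(df, cutoff=cutoff).to_numpy()
    prop = (
        df.groupby(["factor", "cancer_type", "group"], sort=True)["strong"]
        .agg(proportion="mean", n="size")
        .reset_index()
    )
    med = (
        prop.groupby(["factor", "group"])["proportion"]
        .median()
        .rename("cross_cancer_median")
        .reset_index()
    )
    return prop.merge(med, on=["factor", "group"])
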