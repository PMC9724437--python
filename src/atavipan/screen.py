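"""CRISPR knockout screen reprocessing: dependency scores and calls.

A screen is an sgRNA x (cell line, replicate) matrix of log fold changes in
guide abundance.  Processing steps:

1. drop sgRNAs that do not map uniquely to their gene (uniqueness is an
   input flag; genes left without guides leave the screen universe);
2. per cell line, affinely rescale fold changes so the median of a reference
   nonessential gene set is exactly 0 and the median of a reference
   essential set is exactly -1;
3. gene score = one flat median over the gene's retained sgRNAs and
   replicates;
4. per cell line, flag the most-depleted top fraction (default 11.7%,
   ceiling count) of genes as essential; a gene *depends* on a cancer type
   when it is essential in >= 3 of that cancer's cell lines (cancers with
   < 5 screened lines are excluded);
5. common dependencies: per line, genes are ranked ascending (most depleted
   = rank 1, normalized by gene count); per gene the 90th percentile of its
   normalized ranks across lines is recorded, and the smallest top fraction
   (default 6.2%) is flagged common.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass
class Screen:
    """sgRNA-level screen with annotations.

    ``lfc``: sgRNA-indexed frame; columns are MultiIndex (cell_line,
    replicate) or plain cell-line labels.  ``guide_map`` maps sgRNA -> gene.
    ``unique`` flags uniquely mapping sgRNAs.  ``line_cancer`` maps cell line
    -> cancer type.  Reference gene lists must be disjoint.
    """

    lfc: pd.DataFrame
    guide_map: pd.Series
    unique: pd.Series
    line_cancer: pd.Series
    essential_refs: list[str] = field(default_factory=list)
    nonessential_refs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.essential_refs) & set(self.nonessential_refs):
            raise ValueError("reference essential/nonessential lists overlap")

    @property
    def cell_lines(self) -> list[str]:
        cols = self.lfc.columns
        if isinstance(cols, pd.MultiIndex):
            return sorted(set(cols.get_level_values(0)))
        return sorted(set(cols))

    def line_columns(self, line: str):
        cols = self.lfc.columns
        if isinstance(cols, pd.MultiIndex):
            return [c for c in cols if c[0] == line]
        return [c for c in cols if c == line]


def filter_unique_sgrnas(screen: Screen) -> Screen:
    """Drop non-unique sgRNAs; genes left with zero guides leave the universe."""
    keep = screen.unique.reindex(screen.lfc.index).fillna(False).astype(bool)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_unique_sgrnas: %d sgRNAs dropped", dropped)
    lfc = screen.lfc.loc[keep[keep].index]
    return Screen(
        lfc=lfc,
        guide_map=screen.guide_map.loc[lfc.index],
        unique=screen.unique.loc[lfc.index],
        line_cancer=screen.line_cancer,
        essential_refs=screen.essential_refs,
        nonessential_refs=screen.nonessential_refs,
    )


def normalize_screen(
    gene_or_sgrna_scores: pd.DataFrame,
    gene_of_row: pd.Series,
    essential_refs,
    nonessential_refs,
) -> pd.DataFrame:
    """Anchor each cell line: median(nonessential) -> 0, median(essential) -> -1.

    The affine map x -> (x - m_non) / (m_non - m_ess) is applied per column
    (cell line or line:replicate); the reference medians are taken over all
    rows belonging to reference genes.  Raises on a degenerate screen (equal
    reference medians).
    """
    ess = set(essential_refs)
    non = set(nonessential_refs)
    genes = gene_of_row.reindex(gene_or_sgrna_scores.index)
    ess_rows = genes.isin(ess).to_numpy()
    non_rows = genes.isin(non).to_numpy()
    if not ess_rows.any() or not non_rows.any():
        raise ValueError("reference genes absent from the screen")
    mat = gene_or_sgrna_scores.to_numpy(dtype=float)
    m_ess = np.median(mat[ess_rows], axis=0)
    m_non = np.median(mat[non_rows], axis=0)
    if np.any(m_ess == m_non):
        raise ValueError("degenerate screen: essential and nonessential medians equal")
    scaled = (mat - m_non) / (m_non - m_ess)
    return pd.DataFrame(scaled, index=gene_or_sgrna_scores.index,
                        columns=gene_or_sgrna_scores.columns)


def gene_scores(scaled: pd.DataFrame, guide_map: pd.Series) -> pd.DataFrame:
    """Gene-level score per cell line: one flat median over the gene's
    retained sgRNAs and replicates (not a median of medians)."""
    genes = guide_map.reindex(scaled.index)
    cols = scaled.columns
    if isinstance(cols, pd.MultiIndex):
        lines = sorted(set(cols.get_level_values(0)))
    else:
        lines = sorted(set(cols))
    out = {}
    grouped = {g: idx for g, idx in genes.groupby(genes).groups.items()}
    for line in lines:
        sub = scaled[[c for c in cols if (c[0] if isinstance(cols, pd.MultiIndex) else c) == line]]
        vals = sub.to_numpy(dtype=float)
        out[line] = {g: float(np.median(vals[genes.index.get_indexer(idx)]))
                     for g, idx in grouped.items()}
    res = pd.DataFrame(out)
    res.index.name = "gene_id"
    return res.sort_index()


def essential_count(n_genes: int, fraction: float) -> int:
    """Number of essential genes per line under the top-fraction rule (ceiling)."""
    return math.ceil(n_genes * fraction)


def call_dependencies(
    scores: pd.DataFrame,
    line_cancer: pd.Series,
    fraction: float = 0.117,
    min_lines: int = 3,
    min_lines_per_cancer: int = 5,
) -> "DependencyCalls":
    """Per-line essential flags and per-cancer dependency calls.

    Per cell line the lowest-scoring ceil(fraction * n_genes) genes are
    essential (ties broken by gene id).  Cancer types with fewer than
    ``min_lines_per_cancer`` screened lines are excluded; a gene depends on a
    cancer type when it is essential in >= ``min_lines`` of its lines.
    """
    n_genes = scores.shape[0]
    k = essential_count(n_genes, fraction)
    ess = pd.DataFrame(False, index=scores.index, columns=scores.columns)
    for line in scores.columns:
        order = (
            pd.DataFrame({"score": scores[line].to_numpy(), "gene_id": scores.index})
            .sort_values(["score", "gene_id"], kind="stable")["gene_id"]
            .head(k)
        )
        ess.loc[order, line] = True
    lines_by_cancer: dict[str, list[str]] = {}
    for line in scores.columns:
        lines_by_cancer.setdefault(str(line_cancer.get(line)), []).append(line)
    dep = {}
    excluded = []
    for cancer, lines in sorted(lines_by_cancer.items()):
        if len(lines) < min_lines_per_cancer:
            excluded.append(cancer)
            continue
        dep[cancer] = ess[lines].sum(axis=1) >= min_lines
    if excluded:
        logger.info("call_dependencies: cancers excluded (<%d lines): %s",
                    min_lines_per_cancer, excluded)
    dep_df = pd.DataFrame(dep, index=scores.index) if dep else pd.DataFrame(index=scores.index)
    return DependencyCalls(essential=ess, dependency=dep_df,
                           excluded_cancers=excluded, n_essential_per_line=k)


@dataclass
class DependencyCalls:
    essential: pd.DataFrame  # gene x line bool
    dependency: pd.DataFrame  # gene x cancer bool
    excluded_cancers: list[str]
    n_essential_per_line: int

    def n_dependent_lines(self) -> pd.Series:
        """Number of cell lines depending on each gene (across all lines)."""
        return self.essential.sum(axis=1)


def common_dependency(
    scores: pd.DataFrame,
    percentile: float = 0.90,
    top_fraction: float = 0.062,
) -> pd.DataFrame:
    """Common-dependency statistic and flags.

    Per cell line, genes are ranked ascending (most depleted = rank 1;
    average ranks for ties) and normalized by the gene count.  Per gene the
    ``percentile`` quantile (linear interpolation) of its normalized ranks
    across lines summarizes its *worst typical* essentiality; the
    ceil(top_fraction * n_genes) genes with the smallest statistic (ties by
    gene id) are flagged common dependencies.
    """
    if scores.shape[1] < 1:
        raise ValueError("need >= 1 cell line")
    mat = scores.to_numpy(dtype=float)
    n_genes = mat.shape[0]
    ranks = np.apply_along_axis(rankdata, 0, mat) / n_genes
    stat = np.quantile(ranks, percentile, axis=1, method="linear")
    out = pd.DataFrame({"rank90": stat}, index=scores.index)
    k = math.ceil(n_genes * top_fraction)
    order = pd.DataFrame({"rank90": stat, "gene_id": scores.index}).sort_values(
        ["rank90", "gene_id"], kind="stable"
    )
    flagged = set(order["gene_id"].head(k))
    out["common"] = out.index.isin(flagged)
    return out
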