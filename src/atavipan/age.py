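"""Gene-age catalog: merging two dating sources, age classes, tissue bias, filters.

Two complementary dating strategies are merged into a single 14-group age
scale.  Synteny-based (locus-level) dating resolves genes that arose after the
vertebrate split into groups 9-14; genes older than that are one "vertebrate
ancestor" bucket which family-level phylostratigraphy splits into groups 1-8.
Because a gene family is always at least as old as any locus it contains, a
family stratum *younger* than the locus age is an inconsistency and the gene
is excluded as conflicting.

Age classes partition the 14 groups into four contiguous blocks:
unicellular-ancestor genes (UC), early-metazoan genes (EM), mammal-specific
genes (MM) and primate-specific genes (PSG).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Synteny code for "vertebrate common ancestor or older" (the oldest locus call).
VERTEBRATE_ANCESTOR = 0

#: First post-vertebrate age group on the merged 1..14 scale.
POST_VERTEBRATE_MIN = 9

DEFAULT_CLASS_BOUNDARIES: dict[str, tuple[int, int]] = {
    "UC": (1, 3),
    "EM": (4, 9),
    "MM": (10, 13),
    "PSG": (14, 14),
}

#: Phylostrata counted as unicellular in family-level (duplicate-origin) tests.
DEFAULT_UC_STRATA: tuple[int, int] = (1, 3)


class InputError(ValueError):
    """Malformed input table (duplicate keys, bad values)."""


def merge_ages(synteny: pd.DataFrame, family: pd.DataFrame) -> pd.DataFrame:
    """Merge synteny-based and family-level (phylostratigraphy) gene ages.

    Parameters
    ----------
    synteny : DataFrame with columns ``gene_id`` and ``synteny_group``
        (``0`` = vertebrate ancestor or older, ``9``-``14`` = post-vertebrate
        clades, youngest = 14).  Genes absent from the table or with NA have
        no synteny call.
    family : DataFrame with columns ``gene_id`` and ``phylostratum``
        (1..14 on the same merged scale; 1..8 are pre-vertebrate strata).

    Returns
    -------
    DataFrame indexed by gene id with columns ``synteny_group``,
    ``phylostratum``, ``merged_group`` (nullable Int64), ``conflict`` (bool)
    and ``reason`` for unmerged genes.

    Rules
    -----
    - post-vertebrate synteny call (9-14) -> merged group = synteny group;
      a family stratum strictly younger than the locus call is a conflict.
    - vertebrate-ancestor synteny call -> the family phylostratum (1-8) is
      adopted; a post-vertebrate family stratum is a conflict; without a
      family call the gene stays undated.
    - family-only genes adopt their phylostratum; genes in neither source
      stay undated.
    """
    for name, tab, col in (("synteny", synteny, "synteny_group"),
                           ("family", family, "phylostratum")):
        if tab["gene_id"].duplicated().any():
            dups = tab.loc[tab["gene_id"].duplicated(), "gene_id"].tolist()
            raise InputError(f"duplicate gene ids in {name} table: {dups[:5]}")
        if col not in tab.columns:
            raise InputError(f"{name} table lacks column {col!r}")

    merged = pd.merge(
        synteny[["gene_id", "synteny_group"]],
        family[["gene_id", "phylostratum"]],
        on="gene_id", how="outer",
    ).set_index("gene_id").sort_index()
    syn = merged["synteny_group"]
    fam = merged["phylostratum"]

    has_syn = syn.notna()
    has_fam = fam.notna()
    post_vert = has_syn & (syn >= POST_VERTEBRATE_MIN)
    pre_vert = has_syn & (syn == VERTEBRATE_ANCESTOR)

    conflict = (
        (post_vert & has_fam & (fam > syn))
        | (pre_vert & has_fam & (fam >= POST_VERTEBRATE_MIN))
    )

    group = pd.Series(pd.NA, index=merged.index, dtype="Int64")
    group[post_vert & ~conflict] = syn[post_vert & ~conflict].astype(int)
    take_fam = (pre_vert | ~has_syn) & has_fam & ~conflict
    group[take_fam] = fam[take_fam].astype(int)

    reason = pd.Series("", index=merged.index, dtype=object)
    reason[conflict] = "conflicting_sources"
    undated = group.isna() & ~conflict
    reason[undated] = "no_resolvable_age"
    n_conf = int(conflict.sum())
    if n_conf:
        logger.info("merge_ages: %d genes excluded as conflicting", n_conf)

    merged["merged_group"] = group
    merged["conflict"] = conflict.to_numpy()
    merged["reason"] = reason
    return merged


def classify_age_class(
    assignments: pd.DataFrame,
    boundaries: dict[str, tuple[int, int]] | None = None,
) -> pd.Series:
    """Map merged age groups to the four age classes.

    ``boundaries`` maps class name -> inclusive (lo, hi) group range; the
    ranges must partition 1..14 contiguously.  Conflicting/undated genes get
    NA.
    """
    boundaries = boundaries or DEFAULT_CLASS_BOUNDARIES
    covered = sorted(g for lo, hi in boundaries.values() for g in range(lo, hi + 1))
    if covered != list(range(1, 15)):
        raise InputError(f"class boundaries must partition groups 1..14, got {boundaries}")
    out = pd.Series(pd.NA, index=assignments.index, dtype=object)
    grp = assignments["merged_group"]
    for cls, (lo, hi) in boundaries.items():
        out[(grp >= lo) & (grp <= hi)] = cls
    return out


def tau_index(profile) -> float:
    """Tissue-specificity index tau in [0, 1].

    tau = sum_i (1 - x_i / x_max) / (N - 1) over per-tissue mean expression
    values.  0 = perfectly uniform, 1 = expressed in a single tissue.  Values
    must be nonnegative with at least one positive entry (the index is
    undefined on an all-zero profile) and at least two tissues.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("tau requires a 1-D profile over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("tau requires nonnegative expression values")
    xmax = x.max()
    if xmax == 0:
        raise ValueError("tau undefined for an all-zero profile")
    return float(np.sum(1.0 - x / xmax) / (x.size - 1))


@dataclass
class TissueProfileResult:
    """Per-gene tissue profile summary over the normal-tissue panel."""

    table: pd.DataFrame  # index gene, columns tau, bias_class, top_tissue
    excluded: list[str] = field(default_factory=list)  # all-zero genes


def classify_tissue_bias(
    panel_means: pd.DataFrame,
    cutoff: float = 0.8,
    log_transform: bool = True,
) -> TissueProfileResult:
    """Compute tau on the tissue panel and call broad vs tissue-biased genes.

    ``panel_means`` is genes x tissues mean TPM (each tissue already averaged
    over >= 3 replicates).  tau is computed on log2(TPM + 1) by default, which
    damps single-tissue outliers; a gene is tissue-biased iff tau > ``cutoff``
    (strict).  All-zero genes are excluded with a logged reason.
    """
    vals = panel_means.to_numpy(dtype=float)
    if log_transform:
        vals = np.log2(vals + 1.0)
    xmax = vals.max(axis=1)
    ok = xmax > 0
    excluded = panel_means.index[~ok].tolist()
    if excluded:
        logger.info("classify_tissue_bias: %d all-zero genes excluded", len(excluded))
    n_tissue = vals.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = np.sum(1.0 - vals / xmax[:, None], axis=1) / (n_tissue - 1)
    tab = pd.DataFrame(
        {
            "tau": tau[ok],
            "bias_class": np.where(tau[ok] > cutoff, "tissue-biased", "broad"),
            "top_tissue": panel_means.columns.to_numpy()[np.argmax(vals, axis=1)][ok],
        },
        index=panel_means.index[ok],
    )
    return TissueProfileResult(table=tab, excluded=excluded)


def filter_gene_models(
    catalog: pd.DataFrame,
    panel_means: pd.DataFrame,
    cohort_counts: dict[str, pd.DataFrame],
    min_length: int = 150,
    max_identity: float = 0.975,
    min_panel_tpm: float = 0.2,
    unexpressed_frac: float = 0.2,
) -> pd.Index:
    """Apply the four protein-coding gene-model filters; return retained ids.

    1. biotype == "protein_coding" and transcript length >= ``min_length`` bp;
    2. paralog sequence identity <= ``max_identity`` (too-similar paralogs
       cannot be quantified unambiguously from short reads);
    3. expressed somewhere in the normal-tissue panel (TPM >= ``min_panel_tpm``
       in at least one tissue);
    4. not unexpressed in *every* cancer type, where "unexpressed in a cancer"
       means zero reads in more than ``unexpressed_frac`` of its samples.

    Each filter is a pure per-gene predicate, so the retained set does not
    depend on application order.
    """
    cat = catalog
    f1 = (cat["biotype"] == "protein_coding") & (cat["length"] >= min_length)
    f2 = cat["paralog_identity"] <= max_identity

    panel = panel_means.reindex(cat.index)
    f3 = (panel.to_numpy(dtype=float) >= min_panel_tpm).any(axis=1)

    unexpressed_everywhere = np.ones(len(cat), dtype=bool)
    for counts in cohort_counts.values():
        mat = counts.reindex(cat.index).to_numpy(dtype=float)
        zero_frac = np.mean(mat == 0, axis=1)
        unexpressed_everywhere &= zero_frac > unexpressed_frac
    f4 = ~unexpressed_everywhere if cohort_counts else np.ones(len(cat), dtype=bool)

    keep = f1.to_numpy() & f2.to_numpy() & f3 & f4
    logger.info(
        "filter_gene_models: %d/%d retained (coding/length %d, identity %d, "
        "panel %d, cancer-expression %d removed)",
        int(keep.sum()), len(cat), int((~f1).sum()), int((~f2).sum()),
        int((~f3).sum()), int((~f4).sum()),
    )
    return cat.index[keep]


def expressed_genes(counts: pd.DataFrame, max_zero_frac: float = 0.2) -> pd.Index:
    """Genes adequately expressed within one cancer type.

    Correlation-style analyses (survival, coexpression) need expression
    variance, so genes with zero reads in more than ``max_zero_frac`` of the
    cancer's samples are excluded for that cancer.
    """
    zero_frac = (counts.to_numpy(dtype=float) == 0).mean(axis=1)
    return counts.index[zero_frac <= max_zero_frac]
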