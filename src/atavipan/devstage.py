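"""Developmental-stage assignment and per-stage enrichment in the cerebrum.

A 12-stage embryonic-to-adult time course (each stage the median of >= 2
replicate samples) summarizes the developing cerebrum.  Weakly expressed
genes (all 12 stage medians below an expression floor) are removed.  Each
remaining gene's stage medians are Z-scored (sample SD, n-1) and the gene is
assigned to its argmax stage when Z_max > 1.2 (about the 90% quantile of the
Z distribution); constant rows and tied maxima stay unassigned.

Gene groups (primate-specific genes, curated cell-cycle genes, positively
selected genes) are then tested per stage for excess or depletion relative
to the background assignment proportions with one-sided binomial tests, BH
FDR over 12 stages x 2 directions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_fdr

logger = logging.getLogger(__name__)

N_STAGES = 12
Z_CUTOFF = 1.2


def stage_medians(samples: pd.DataFrame, stage_map: pd.Series) -> pd.DataFrame:
    """Per-gene per-stage medians of a genes x samples matrix.

    ``stage_map`` maps sample id -> stage label; every stage needs >= 2
    replicate samples.  Columns of the result follow the stage order of
    ``stage_map``'s categories (or first appearance).
    """
    stages = (
        list(stage_map.cat.categories)
        if isinstance(stage_map.dtype, pd.CategoricalDtype)
        else list(dict.fromkeys(stage_map))
    )
    cols = {}
    for stage in stages:
        members = stage_map.index[stage_map == stage]
        if len(members) < 2:
            raise ValueError(f"stage {stage!r} has {len(members)} replicates (< 2)")
        cols[stage] = samples[members].median(axis=1)
    return pd.DataFrame(cols)


def filter_low(series: pd.DataFrame, floor: float = 0.2) -> pd.Index:
    """Retain genes with at least one stage median >= ``floor``.

    A gene is removed iff *all* stage medians are strictly below the floor
    (a median exactly at the floor keeps the gene).
    """
    keep = (series.to_numpy(dtype=float) >= floor).any(axis=1)
    return series.index[keep]


def assign_stage(series: pd.DataFrame, z_cutoff: float = Z_CUTOFF) -> pd.DataFrame:
    """Z-score stage assignment of every gene in a DevSeries.

    Returns a frame with columns ``z_max``, ``stage`` (NA when unassigned)
    and ``reason`` (constant / tie / below_cutoff / empty when assigned).
    """
    mat = series.to_numpy(dtype=float)
    mean = mat.mean(axis=1, keepdims=True)
    sd = mat.std(axis=1, ddof=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (mat - mean) / sd
    zmax = np.nanmax(np.where(sd > 0, z, -np.inf), axis=1)
    constant = (sd == 0).ravel()
    argmax = mat.argmax(axis=1)
    is_max = mat == mat.max(axis=1, keepdims=True)
    tied = is_max.sum(axis=1) > 1

    stage = pd.Series(pd.NA, index=series.index, dtype=object)
    reason = pd.Series("", index=series.index, dtype=object)
    reason[constant] = "constant"
    tie_only = tied & ~constant
    reason[tie_only] = "tied_maximum"
    if tie_only.any():
        logger.info("assign_stage: %d genes with tied maxima left unassigned",
                    int(tie_only.sum()))
    ok = ~constant & ~tied & (zmax > z_cutoff)
    below = ~constant & ~tied & ~(zmax > z_cutoff)
    reason[below] = "below_cutoff"
    stage[ok] = series.columns.to_numpy()[argmax[ok]]
    return pd.DataFrame(
        {"z_max": np.where(constant, np.nan, zmax), "stage": stage, "reason": reason},
        index=series.index,
    )


def binomial_tail(k: int, n: int, p: float, alternative: str = "greater") -> float:
    """One-sided exact binomial tail used by the enrichment engine.

    ``greater``: P(X >= k); ``less``: P(X <= k), for X ~ Binomial(n, p).
    """
    if not 0 <= p <= 1:
        raise ValueError("background proportion must be in [0, 1]")
    if alternative == "greater":
        return float(stats.binom.sf(k - 1, n, p))
    if alternative == "less":
        return float(stats.binom.cdf(k, n, p))
    raise ValueError(f"unknown alternative {alternative!r}")


def stage_enrichment(
    group,
    assignments: pd.DataFrame,
    universe=None,
    alpha_fdr: float = 0.1,
    background: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-stage excess/depletion of a gene group vs the background.

    ``assignments`` is the output of :func:`assign_stage`; ``universe``
    restricts the background (default: all assigned genes).  For each stage,
    k = group members assigned there out of n = assigned group members, with
    background probability = the universe's per-stage assigned proportion
    (or an explicit ``background`` Series of per-stage proportions).  Both
    one-sided tests are BH-corrected jointly (12 stages x 2 directions).
    """
    assigned = assignments.dropna(subset=["stage"])
    if universe is not None:
        assigned = assigned.loc[assigned.index.intersection(pd.Index(universe))]
    grp = assigned.loc[assigned.index.intersection(pd.Index(list(group)))]
    n = len(grp)
    if n == 0:
        raise ValueError("no assigned genes in the group")
    stages = list(dict.fromkeys(assignments["stage"].dropna()))
    if background is None:
        bg_counts = assigned["stage"].value_counts()
        background = bg_counts.reindex(stages, fill_value=0) / len(assigned)
    rows = []
    for stage in stages:
        k = int((grp["stage"] == stage).sum())
        p_bg = float(background[stage])
        for direction in ("excess", "depletion"):
            alt = "greater" if direction == "excess" else "less"
            rows.append((stage, direction, k, n, p_bg, binomial_tail(k, n, p_bg, alt)))
    out = pd.DataFrame(rows, columns=["stage", "direction", "k", "n", "background_p", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["significant"] = out["fdr"] < alpha_fdr
    return out


def selection_overlap(
    assignments: pd.DataFrame,
    selection_lists: dict[str, list[str]],
    universe=None,
    alpha_fdr: float = 0.1,
) -> pd.DataFrame:
    """Per-stage enrichment of positive-selection gene lists.

    Each list (genes with positively selected coding sequence, promoter,
    ...) runs through the same binomial engine as :func:`stage_enrichment`;
    results are concatenated with a ``list_name`` column.
    """
    frames = []
    for name in sorted(selection_lists):
        genes = selection_lists[name]
        if len(genes) == 0:
            raise ValueError(f"selection list {name!r} is empty")
        res = stage_enrichment(genes, assignments, universe=universe, alpha_fdr=alpha_fdr)
        res.insert(0, "list_name", name)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
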