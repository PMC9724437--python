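"""Per-gene Cox proportional-hazards prognosis and the net classification.

Each gene's (standardized log2) expression enters a Cox model of the
progression-free interval together with clinical covariates (age, ordinal
stage, gender) where available.  Fitting delegates to lifelines
(partial likelihood, Efron tie handling, Wald p for the expression term);
per-cancer BH FDR defines significance.  The bespoke logic is the *net*
classification: per gene, count cancer types where higher expression is
significantly unfavorable (HR > 1) or favorable (HR < 1); the sign of
(n_unfavorable - n_favorable) labels the gene unfavorable / favorable /
intermediate (net 0 with signal) / non-prognostic (no signal anywhere).

A rank-based alternative takes the top-k smallest-p genes per cancer as
"prognostic" regardless of FDR, feeding the same net classifier.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .diffexpr import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class CoxResult:
    gene_id: str
    cancer_type: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    p: float


def fit_cox(
    expression: pd.Series,
    time: pd.Series,
    event: pd.Series,
    covariates: pd.DataFrame | None = None,
    standardize: bool = True,
    min_patients: int = 30,
    min_events: int = 10,
) -> CoxResult | None:
    """Cox PH fit of one gene's expression against the PFI endpoint.

    Expression is z-scored by default so hazard ratios are per SD.  Patients
    with missing covariates are dropped listwise.  Returns None (with a
    logged reason) on insufficient data, a degenerate predictor, or
    non-convergence.
    """
    df = pd.DataFrame({"time": time, "event": event, "x": expression})
    if covariates is not None:
        df = df.join(covariates)
    df = df.dropna()
    if len(df) < min_patients or df["event"].sum() < min_events:
        logger.info("fit_cox: insufficient data (n=%d, events=%d)",
                    len(df), int(df["event"].sum()))
        return None
    if df["x"].std() == 0:
        logger.info("fit_cox: constant expression, skipped")
        return None
    if standardize:
        df["x"] = (df["x"] - df["x"].mean()) / df["x"].std()
    # drop degenerate covariate columns
    for col in list(df.columns):
        if col not in ("time", "event", "x") and df[col].nunique() < 2:
            df = df.drop(columns=col)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # convergence or singularity
        logger.info("fit_cox: fit failed (%s)", exc)
        return None
    s = cph.summary.loc["x"]
    return CoxResult(
        gene_id=str(expression.name),
        cancer_type="",
        beta=float(s["coef"]),
        hr=float(s["exp(coef)"]),
        ci_low=float(np.exp(s["coef lower 95%"])),
        ci_high=float(np.exp(s["coef upper 95%"])),
        p=float(s["p"]),
    )


def fit_cox_cancer(
    expression: pd.DataFrame,
    clinical: pd.DataFrame,
    cancer_type: str,
    covariate_cols: tuple[str, ...] = ("age", "stage", "gender"),
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-gene Cox fits within one cancer type, with per-cancer BH FDR.

    ``expression`` is genes x patients (log2 scale); ``clinical`` is
    patient-indexed with ``time``, ``event`` and any of the covariate
    columns.  Returns a table (gene_id, cancer_type, beta, hr, ci, p, fdr).
    """
    covs = clinical[[c for c in covariate_cols if c in clinical.columns]]
    rows = []
    for gene in expression.index:
        res = fit_cox(
            expression.loc[gene, clinical.index],
            clinical["time"], clinical["event"],
            covariates=covs if len(covs.columns) else None,
            standardize=standardize,
        )
        if res is None:
            continue
        rows.append((gene, cancer_type, res.beta, res.hr, res.ci_low, res.ci_high, res.p))
    out = pd.DataFrame(
        rows, columns=["gene_id", "cancer_type", "beta", "hr", "ci_low", "ci_high", "p"]
    )
    if len(out):
        out["fdr"] = bh_fdr(out["p"].to_numpy())
    else:
        out["fdr"] = pd.Series(dtype=float)
    return out


def classify_prognostic(cox_tables: pd.DataFrame, alpha_fdr: float = 0.05) -> pd.DataFrame:
    """Net prognostic classification across cancer types.

    ``cox_tables`` concatenates per-cancer Cox tables (gene_id, cancer_type,
    hr, fdr).  Per gene: n_unfavorable = significant cancers with HR > 1,
    n_favorable = significant with HR < 1, net = difference; label
    unfavorable (net > 0), favorable (net < 0), intermediate (net 0 with at
    least one significant cancer), non-prognostic (none).
    """
    sig = cox_tables[cox_tables["fdr"] < alpha_fdr]
    n_unf = sig[sig["hr"] > 1].groupby("gene_id").size()
    n_fav = sig[sig["hr"] < 1].groupby("gene_id").size()
    genes = sorted(cox_tables["gene_id"].unique())
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    out["n_unfavorable"] = n_unf.reindex(genes, fill_value=0).astype(int)
    out["n_favorable"] = n_fav.reindex(genes, fill_value=0).astype(int)
    out["net"] = out["n_unfavorable"] - out["n_favorable"]
    any_sig = (out["n_unfavorable"] + out["n_favorable"]) > 0
    out["label"] = np.select(
        [~any_sig, out["net"] > 0, out["net"] < 0],
        ["non-prognostic", "unfavorable", "favorable"],
        default="intermediate",
    )
    return out


def top_k_prognostic(cox_tables: pd.DataFrame, k: int = 1500) -> dict[str, list[str]]:
    """Per-cancer top-k genes by smallest Wald p (ties by gene id).

    The rank-based robustness mode: the count of prognostic genes under an
    FDR cutoff varies by orders of magnitude across cancers, so taking a
    fixed number of the most PFI-correlated genes per cancer removes that
    imbalance.  The returned sets feed :func:`classify_prognostic` after
    marking them significant.
    """
    out: dict[str, list[str]] = {}
    for cancer, grp in cox_tables.groupby("cancer_type", sort=True):
        ranked = grp.sort_values(["p", "gene_id"], kind="stable")
        out[cancer] = ranked["gene_id"].head(k).tolist()
    return out


def classify_prognostic_topk(cox_tables: pd.DataFrame, k: int = 1500) -> pd.DataFrame:
    """Net classification where per-cancer significance = membership of the
    top-k smallest-p set (rank mode) instead of the FDR cutoff."""
    selected = top_k_prognostic(cox_tables, k=k)
    marked = cox_tables.copy()
    sel_mask = np.zeros(len(marked), dtype=bool)
    for cancer, genes in selected.items():
        gs = set(genes)
        sel_mask |= ((marked["cancer_type"] == cancer)
                     & marked["gene_id"].isin(gs)).to_numpy()
    marked["fdr"] = np.where(sel_mask, 0.0, 1.0)
    return classify_prognostic(marked, alpha_fdr=0.5)
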