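"""End-to-end orchestration from a YAML manifest, plus ground-truth scoring.

``run_all`` loads every input declared in the manifest, runs the stages in
dependency order (age -> differential expression -> ssGSEA / regulation /
coexpression / survival -> screen -> developmental staging), writes each
output TSV with a provenance header and logs every exclusion.  The pipeline
is a pure function of (inputs, manifest): reruns are byte-identical.

``evaluate_against_truth`` scores the run against the planted ground truth
(precision/recall of pan-cancer calls, prognostic signs, dependency calls,
stage assignments and coexpression partners).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import age as age_mod
from . import coexpr as coexpr_mod
from . import devstage as dev_mod
from . import diffexpr as de_mod
from . import regulation as reg_mod
from . import screen as screen_mod
from . import ssgsea as ssgsea_mod
from . import survival as surv_mod
from .io import (read_gene_list, read_gmt, read_manifest, read_tsv, write_tsv)
from .synth import GroundTruth

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {
    "de_alpha": 0.05,
    "de_lfc": 0.4,
    "pan_min_n": 3,
    "pan_ratio": 3.0,
    "ssgsea_alpha": 0.25,
    "reg_cutoff": 0.3,
    "probe_max_na": 0.05,
    "coexpr_cutoff": 0.4,
    "coexpr_min_cancers": 3,
    "coexpr_max_queries": 20,
    "cox_alpha_fdr": 0.05,
    "screen_fraction": 0.117,
    "screen_min_lines": 3,
    "screen_min_lines_per_cancer": 5,
    "common_percentile": 0.90,
    "common_top_fraction": 0.062,
    "dev_floor": 0.2,
    "dev_z_cutoff": 1.2,
    "dev_alpha_fdr": 0.1,
    "tau_cutoff": 0.8,
}

DEFAULT_STAGES = ("ssgsea", "regulation", "coexpr", "survival", "screen", "devstage")


class ManifestError(ValueError):
    """Manifest fails validation (missing files, bad thresholds)."""


@dataclass
class RunResult:
    ages: pd.DataFrame
    retained: pd.Index
    classes: pd.Series
    groups: pd.Series  # age class with the broad/tissue PSG split
    de_tables: dict
    pan_calls: pd.DataFrame
    ssgsea_scores: pd.DataFrame | None = None
    reg_correlations: pd.DataFrame | None = None
    reg_proportions: pd.DataFrame | None = None
    partner_sets: dict = field(default_factory=dict)
    assignments: pd.DataFrame | None = None
    cellcycle_enrichment: pd.DataFrame | None = None
    cox: pd.DataFrame | None = None
    prognostic: pd.DataFrame | None = None
    screen_scores: pd.DataFrame | None = None
    screen_refs: set = field(default_factory=set)
    dependency: "screen_mod.DependencyCalls | None" = None
    common: pd.DataFrame | None = None
    dev_assignments: pd.DataFrame | None = None
    dev_enrichment: pd.DataFrame | None = None
    dev_selection: pd.DataFrame | None = None
    recovery: dict = field(default_factory=dict)


def _validate_manifest(manifest: dict, base: Path) -> None:
    def check(rel):
        if not (base / rel).exists():
            raise ManifestError(f"missing input file: {rel}")

    paths = manifest.get("paths")
    if not paths:
        raise ManifestError("manifest lacks a 'paths' section")
    for key, val in paths.items():
        if isinstance(val, str):
            check(val)
        elif isinstance(val, dict):
            for sub in val.values():
                if isinstance(sub, str):
                    check(sub)
                else:
                    for p in sub.values():
                        check(p)
    thr = {**DEFAULT_THRESHOLDS, **manifest.get("thresholds", {})}
    for key in ("de_alpha", "cox_alpha_fdr", "dev_alpha_fdr", "screen_fraction",
                "common_top_fraction", "probe_max_na"):
        if not 0 < thr[key] < 1:
            raise ManifestError(f"threshold {key} out of range: {thr[key]}")


def run_all(manifest_path, outdir) -> RunResult:
    """Run every enabled stage; write outputs + recovery report to outdir."""
    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = read_manifest(manifest_path)
    _validate_manifest(manifest, base)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    log_handler = logging.FileHandler(out / "run.log", mode="w")
    log_handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("atavipan")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        return _run_all_inner(manifest, base, out)
    finally:
        root.removeHandler(log_handler)
        log_handler.close()


def _run_all_inner(manifest: dict, base: Path, out: Path) -> RunResult:
    thr = {**DEFAULT_THRESHOLDS, **manifest.get("thresholds", {})}
    enabled = {s: manifest.get("stages", {}).get(s, True) for s in DEFAULT_STAGES}
    paths = manifest["paths"]
    seed = manifest.get("seed", 0)
    prov = {"seed": seed, **{k: v for k, v in sorted(thr.items())}}
    cancers = manifest["cancers"]

    catalog = read_tsv(base / paths["catalog"])
    synteny = read_tsv(base / paths["ages_synteny"], index_col=None)
    family = read_tsv(base / paths["ages_family"], index_col=None)
    panel = read_tsv(base / paths["tissue_panel"])

    cohorts = {}
    for c in cancers:
        cp = paths["cohorts"][c]
        cohorts[c] = {
            "counts": read_tsv(base / cp["counts"]),
            "tpm": read_tsv(base / cp["tpm"]),
            "samples": read_tsv(base / cp["samples"]),
            "cna": read_tsv(base / cp["cna"]),
            "meth": read_tsv(base / cp["meth"]),
            "survival": read_tsv(base / cp["survival"]),
        }

    # ---- age stage -------------------------------------------------------
    ages = age_mod.merge_ages(synteny, family)
    classes = age_mod.classify_age_class(ages)
    tissue_means = panel.T.groupby(
        panel.columns.str.split("|").str[0]).mean().T
    profile = age_mod.classify_tissue_bias(tissue_means, cutoff=thr["tau_cutoff"])
    retained = age_mod.filter_gene_models(
        catalog, tissue_means, {c: cohorts[c]["counts"] for c in cancers})

    ages_out = ages.copy()
    ages_out["age_class"] = classes
    ages_out = ages_out.join(profile.table, how="left")
    ages_out["retained"] = ages_out.index.isin(retained)
    write_tsv(ages_out, out / "age_assignments.tsv", prov)

    # group labels with the PSG broad/tissue split for regulation
    groups = classes.copy().astype(object)
    bias = profile.table["bias_class"].reindex(groups.index)
    is_psg = groups == "PSG"
    groups[is_psg & (bias == "broad")] = "B-PSG"
    groups[is_psg & (bias == "tissue-biased")] = "T-PSG"

    # ---- differential expression + pan-cancer calls ----------------------
    de_tables = {}
    for c in cancers:
        counts = cohorts[c]["counts"].loc[
            cohorts[c]["counts"].index.intersection(retained)]
        samples = cohorts[c]["samples"]
        grp = np.where(samples["is_tumor"].to_numpy(), "tumor", "normal")
        logexpr = de_mod.normalize_and_transform(counts)
        res = de_mod.moderated_two_group_test(
            logexpr, grp, alpha=thr["de_alpha"], lfc=thr["de_lfc"])
        de_tables[c] = res.table
        write_tsv(res.table, out / f"de_{c}.tsv", prov)
    pan = de_mod.classify_pan_cancer(
        de_tables, min_n=thr["pan_min_n"], ratio=thr["pan_ratio"])
    pan["age_class"] = classes.reindex(pan.index)
    write_tsv(pan, out / "pan_calls.tsv", prov)

    result = RunResult(ages=ages_out, retained=retained, classes=classes,
                       groups=groups, de_tables=de_tables, pan_calls=pan)

    # ---- ssGSEA ----------------------------------------------------------
    if enabled["ssgsea"]:
        class_sets = {
            cls: sorted(classes.index[(classes == cls)
                                      & classes.index.isin(retained)])
            for cls in ("UC", "EM", "MM", "PSG")
        }
        score_frames, meta_frames = [], []
        for c in cancers:
            tpm = cohorts[c]["tpm"].loc[
                cohorts[c]["tpm"].index.intersection(retained)]
            score_frames.append(ssgsea_mod.score_samples(
                tpm, class_sets, alpha=thr["ssgsea_alpha"]))
            meta_frames.append(cohorts[c]["samples"])
        raw = pd.concat(score_frames, ignore_index=True)
        meta = pd.concat(meta_frames)
        rescaled = ssgsea_mod.rescale_scores(raw, meta)
        write_tsv(rescaled, out / "ssgsea_scores.tsv", prov, index=False)
        result.ssgsea_scores = rescaled

    # ---- regulation ------------------------------------------------------
    if enabled["regulation"]:
        probes = read_tsv(base / paths["probes"], index_col=None)
        annotation = reg_mod.annotate_probes(probes, catalog)
        corr_frames = []
        for c in cancers:
            samples = cohorts[c]["samples"]
            tumor = samples.index[samples["is_tumor"]]
            tpm = cohorts[c]["tpm"]
            expr = np.log2(tpm.loc[tpm.index.intersection(retained), tumor] + 1.0)
            cna = cohorts[c]["cna"][tumor]
            corr_frames.append(reg_mod.expr_factor_correlation(
                expr, cna, "SCNA", c))
            beta = cohorts[c]["meth"][tumor]
            kept = reg_mod.filter_probes(beta, max_na=thr["probe_max_na"])
            chosen = reg_mod.select_promoter_probe(
                annotation, beta.loc[kept], expr)
            meth_gene = beta.loc[chosen.to_numpy(), :].copy()
            meth_gene.index = chosen.index
            corr_frames.append(reg_mod.expr_factor_correlation(
                expr, meth_gene, "methylation", c))
        corr = pd.concat(corr_frames, ignore_index=True)
        props = reg_mod.strong_proportions(corr, groups, cutoff=thr["reg_cutoff"])
        write_tsv(corr, out / "regulation_correlations.tsv", prov, index=False)
        write_tsv(props, out / "regulation_proportions.tsv", prov, index=False)
        result.reg_correlations = corr
        result.reg_proportions = props

    # ---- coexpression ----------------------------------------------------
    if enabled["coexpr"]:
        gene_sets = read_gmt(base / paths["gene_sets"])
        curated = read_gene_list(base / paths["cellcycle_list"])
        upsgs = sorted(pan.index[(pan["label"] == "pan-up")
                                 & (pan["age_class"] == "PSG")])
        queries = upsgs[: int(thr["coexpr_max_queries"])]
        expr_by_cancer, purity_by_cancer = {}, {}
        for c in cancers:
            samples = cohorts[c]["samples"]
            tumor = samples.index[samples["is_tumor"]]
            tpm = cohorts[c]["tpm"]
            expr_by_cancer[c] = np.log2(
                tpm.loc[tpm.index.intersection(retained), tumor] + 1.0)
            purity_by_cancer[c] = samples.loc[tumor, "purity"]
        assign_frames, partner_rows = [], []
        for q in queries:
            ps = coexpr_mod.find_partners(
                q, expr_by_cancer, purity_by_cancer, catalog["chrom"],
                cutoff=thr["coexpr_cutoff"],
                min_cancers=thr["coexpr_min_cancers"])
            result.partner_sets[q] = ps
            for g in ps.partners:
                partner_rows.append((q, g, ps.median_rho[g]))
            if ps.partners:
                assign_frames.append(coexpr_mod.assign_sets(
                    ps, gene_sets, retained))
            else:
                logger.info("coexpr: query %s has no partners, assignment skipped", q)
        partners_df = pd.DataFrame(
            partner_rows, columns=["query", "partner", "median_rho"])
        write_tsv(partners_df, out / "coexpr_partners.tsv", prov, index=False)
        if assign_frames:
            result.assignments = pd.concat(assign_frames, ignore_index=True)
            write_tsv(result.assignments, out / "coexpr_assignments.tsv",
                      prov, index=False)
        if upsgs:
            enr = coexpr_mod.group_overrepresentation(
                upsgs, {"cellcycle_curated": curated}, retained)
            write_tsv(enr, out / "upsg_cellcycle_enrichment.tsv", prov, index=False)
            result.cellcycle_enrichment = enr

    # ---- survival --------------------------------------------------------
    if enabled["survival"]:
        candidates = sorted(pan.index[pan["label"] != "neither"])
        max_genes = manifest.get("survival_max_genes")
        if max_genes:
            candidates = candidates[: int(max_genes)]
        cox_frames = []
        for c in cancers:
            clin = cohorts[c]["survival"]
            tpm = cohorts[c]["tpm"]
            genes_c = [g for g in candidates
                       if g in age_mod.expressed_genes(
                           cohorts[c]["counts"][clin.index])]
            expr = np.log2(tpm.loc[genes_c, clin.index] + 1.0)
            cox_frames.append(surv_mod.fit_cox_cancer(expr, clin, c))
        cox = pd.concat(cox_frames, ignore_index=True)
        prog = surv_mod.classify_prognostic(cox, alpha_fdr=thr["cox_alpha_fdr"])
        write_tsv(cox, out / "cox_results.tsv", prov, index=False)
        write_tsv(prog, out / "prognostic_classes.tsv", prov)
        result.cox = cox
        result.prognostic = prog

    # ---- screen ----------------------------------------------------------
    if enabled["screen"]:
        scr = load_screen(base, paths)
        scr = screen_mod.filter_unique_sgrnas(scr)
        scaled = screen_mod.normalize_screen(
            scr.lfc, scr.guide_map, scr.essential_refs, scr.nonessential_refs)
        scores = screen_mod.gene_scores(scaled, scr.guide_map)
        calls = screen_mod.call_dependencies(
            scores, scr.line_cancer,
            fraction=thr["screen_fraction"],
            min_lines=thr["screen_min_lines"],
            min_lines_per_cancer=thr["screen_min_lines_per_cancer"])
        common = screen_mod.common_dependency(
            scores, percentile=thr["common_percentile"],
            top_fraction=thr["common_top_fraction"])
        write_tsv(scores, out / "screen_gene_scores.tsv", prov)
        write_tsv(calls.dependency, out / "screen_dependency.tsv", prov)
        write_tsv(common, out / "screen_common.tsv", prov)
        result.screen_scores = scores
        result.screen_refs = set(scr.essential_refs) | set(scr.nonessential_refs)
        result.dependency = calls
        result.common = common

    # ---- developmental staging ------------------------------------------
    if enabled["devstage"]:
        series = read_tsv(base / paths["dev_series"])
        stage_map = read_tsv(base / paths["dev_stage_map"])["stage"]
        medians = dev_mod.stage_medians(series, stage_map)
        kept = dev_mod.filter_low(medians, floor=thr["dev_floor"])
        assign = dev_mod.assign_stage(medians.loc[kept],
                                      z_cutoff=thr["dev_z_cutoff"])
        write_tsv(assign, out / "dev_assignments.tsv", prov)
        result.dev_assignments = assign
        frames = []
        psgs = sorted(classes.index[classes == "PSG"])
        curated = read_gene_list(base / paths["cellcycle_list"])
        for name, grp_genes in (("PSG", psgs), ("cellcycle_curated", curated)):
            grp_present = [g for g in grp_genes
                           if g in assign.index and pd.notna(assign.loc[g, "stage"])]
            if not grp_present:
                logger.info("devstage: group %s has no assigned genes", name)
                continue
            enr = dev_mod.stage_enrichment(grp_present, assign,
                                           alpha_fdr=thr["dev_alpha_fdr"])
            enr.insert(0, "group", name)
            frames.append(enr)
        if frames:
            result.dev_enrichment = pd.concat(frames, ignore_index=True)
            write_tsv(result.dev_enrichment, out / "dev_enrichment.tsv",
                      prov, index=False)
        sel_lists = {name: read_gene_list(base / p)
                     for name, p in paths["selection_lists"].items()}
        result.dev_selection = dev_mod.selection_overlap(
            assign, sel_lists, alpha_fdr=thr["dev_alpha_fdr"])
        write_tsv(result.dev_selection, out / "dev_selection_overlap.tsv",
                  prov, index=False)

    # ---- ground-truth scoring -------------------------------------------
    truth_path = paths.get("ground_truth")
    if truth_path and (base / truth_path).exists():
        truth = GroundTruth.from_json(base / truth_path)
        result.recovery = evaluate_against_truth(result, truth)
        (out / "recovery.json").write_text(
            json.dumps(result.recovery, indent=1, sort_keys=True))
    return result


def load_screen(base: Path, paths: dict) -> "screen_mod.Screen":
    """Reassemble a Screen object from the bundle's TSV/text files."""
    tab = read_tsv(base / paths["screen"])
    value_cols = [c for c in tab.columns if "|" in c]
    lfc = tab[value_cols].copy()
    lfc.columns = pd.MultiIndex.from_tuples(
        [tuple(c.split("|", 1)) for c in value_cols],
        names=["cell_line", "replicate"])
    lines = read_tsv(base / paths["screen_lines"])
    return screen_mod.Screen(
        lfc=lfc,
        guide_map=tab["gene_id"],
        unique=tab["unique"].astype(bool),
        line_cancer=lines["cancer_type"],
        essential_refs=read_gene_list(base / paths["screen_essential_refs"]),
        nonessential_refs=read_gene_list(base / paths["screen_nonessential_refs"]),
    )


def _prf(predicted: set, truth: set, eligible: set) -> dict:
    """Precision/recall restricted to the eligible universe."""
    pred = predicted & eligible
    tru = truth & eligible
    tp = len(pred & tru)
    return {
        "n_predicted": len(pred),
        "n_truth": len(tru),
        "precision": tp / len(pred) if pred else None,
        "recall": tp / len(tru) if tru else None,
    }


def evaluate_against_truth(result: RunResult, truth: GroundTruth) -> dict:
    """Recovery report: how well each stage found the planted structure."""
    eligible = set(result.retained)
    rec: dict = {}

    pan = result.pan_calls
    pred_up = set(pan.index[pan["label"] == "pan-up"])
    rec["pan_up"] = _prf(pred_up, set(truth.pan_up), eligible)
    pred_down = set(pan.index[pan["label"] == "pan-down"])
    rec["pan_down"] = _prf(pred_down, set(truth.pan_down), eligible)
    psg = set(result.classes.index[result.classes == "PSG"])
    rec["pan_up_psg"] = _prf(pred_up & psg, set(truth.pan_up) & psg, eligible)

    if result.prognostic is not None and truth.prognostic:
        prog = result.prognostic
        correct = 0
        tested = [g for g in truth.prognostic if g in prog.index]
        for g in tested:
            want = "unfavorable" if truth.prognostic[g] > 0 else "favorable"
            correct += int(prog.loc[g, "label"] == want)
        rec["prognostic_sign"] = {
            "n_tested": len(tested),
            "recall": correct / len(tested) if tested else None,
        }

    if result.dependency is not None and truth.essential:
        dep = result.dependency.dependency
        truth_pairs = set()
        for g, lines in truth.essential.items():
            per_cancer: dict[str, int] = {}
            for ln in lines:
                per_cancer[ln.split("_L")[0]] = per_cancer.get(ln.split("_L")[0], 0) + 1
            for c, k in per_cancer.items():
                if k >= 3 and c in dep.columns:
                    truth_pairs.add((g, c))
        # reference essential genes are depleted everywhere by construction;
        # they are controls, not planted discoveries, so they leave the score
        pred_pairs = {(g, c) for c in dep.columns
                      for g in dep.index[dep[c]]
                      if g not in result.screen_refs}
        tp = len(pred_pairs & truth_pairs)
        rec["dependency"] = {
            "n_predicted": len(pred_pairs),
            "n_truth": len(truth_pairs),
            "precision": tp / len(pred_pairs) if pred_pairs else None,
            "recall": tp / len(truth_pairs) if truth_pairs else None,
        }

    if result.dev_assignments is not None and truth.stage:
        assign = result.dev_assignments
        hits, total = 0, 0
        for g, s in truth.stage.items():
            if g in assign.index:
                total += 1
                hits += int(assign.loc[g, "stage"] == s)
        rec["dev_stage"] = {"n_planted": total,
                            "recall": hits / total if total else None}

    if result.partner_sets:
        module_genes = {g for g, m in truth.module.items() if m == 0}
        hits, total = 0, 0
        for q, ps in result.partner_sets.items():
            if q not in module_genes:
                continue
            expected = (module_genes - {q}) & set(result.retained)
            total += len(expected)
            hits += len(expected & set(ps.partners))
        if total:
            rec["module_partners"] = {"n_expected": total, "recall": hits / total}

    if result.reg_proportions is not None:
        props = result.reg_proportions
        med = props.drop_duplicates(["factor", "group"]).set_index(["factor", "group"])
        try:
            b = float(med.loc[("SCNA", "B-PSG"), "cross_cancer_median"])
            t = float(med.loc[("SCNA", "T-PSG"), "cross_cancer_median"])
            rec["scna_bpsg_gt_tpsg"] = {"B-PSG": b, "T-PSG": t, "ordered": bool(b > t)}
        except KeyError:
            pass
    return rec
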