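"""Synthetic multi-omics generator with planted ground truth.

Every pipeline input is emulated at desk scale with known planted structure,
so each downstream stage has a recovery test: per-cancer tumor/normal
RNA-seq counts with age-class-linked planted fold changes, gene-level copy
number and promoter methylation rank-coupled to expression through a
Gaussian copula, tumor purity, progression-free survival with planted
per-gene log-hazards, an sgRNA-level CRISPR screen with reference
essential/nonessential genes, a 26-tissue normal panel, and a 12-stage
cerebral developmental series.

Counts are negative binomial with log-normal gene means (RNA-seq
overdispersion); TPM values derive from the counts with fixed transcript
lengths carried in the catalog.  Expression-CNA/methylation coupling uses a
Gaussian copula on normal scores of the within-cancer expression ranks, so
Spearman targets are met regardless of marginals.  Each emitted table draws
from its own RNG stream seeded from (config seed, file tag), making every
output byte-identical under a fixed seed.  One sample per patient is
emitted, never duplicates.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .age import DEFAULT_CLASS_BOUNDARIES

CLASSES = ("UC", "EM", "MM", "PSG")
CHROMS = [f"chr{i}" for i in range(1, 23)] + ["chrX"]


class ConfigError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    The defaults mirror the real study's shape at desk scale: four age
    classes with primate-specific genes the smallest, >= 15 normal controls
    per cancer, pan-up/down planting rates echoing the observed class-level
    proportions, copy-number coupling strongest for broadly transcribed PSGs
    and promoter-methylation coupling strongest for tissue-biased PSGs, an
    11.7%-scale essential fraction in the screen, and an embryonic-stage
    bias for the planted cell-cycle module.
    """

    n_genes: int = 800
    n_cancer_types: int = 6
    n_tumor: int = 60
    n_normal: int = 30
    seed: int = 0

    class_proportions: dict = field(default_factory=lambda: {
        "UC": 0.325, "EM": 0.48, "MM": 0.168, "PSG": 0.027})
    conflict_fraction: float = 0.02
    dispersion: float = 0.15
    base_log2_mean: float = 4.0
    base_log2_sd: float = 1.5

    # tissue panel
    n_tissues: int = 26
    n_tissue_reps: int = 3
    tissue_bias_fraction: dict = field(default_factory=lambda: {
        "UC": 0.09, "EM": 0.15, "MM": 0.30, "PSG": 0.45})

    # planted differential expression
    pan_up_fraction: dict = field(default_factory=lambda: {
        "UC": 0.32, "EM": 0.20, "MM": 0.20, "PSG": 0.33})
    pan_down_fraction: dict = field(default_factory=lambda: {
        "UC": 0.23, "EM": 0.34, "MM": 0.20, "PSG": 0.19})
    effect_log2: float = 1.0
    n_affected_cancers: int = 6

    # copy-number / methylation rank coupling (Spearman targets)
    cna_rho: dict = field(default_factory=lambda: {
        "default": 0.35, "PSG_broad": 0.6, "PSG_tissue": 0.0})
    meth_rho: dict = field(default_factory=lambda: {
        "default": -0.30, "PSG_broad": -0.20, "PSG_tissue": -0.60})
    probes_per_gene: int = 3  # 2 promoter + 1 distal
    probe_na_fraction: float = 0.01
    noisy_probe_fraction: float = 0.03  # probes pushed over the NA filter
    noisy_probe_na: float = 0.08

    # coexpression modules
    n_modules: int = 2
    module_size: int = 14
    module_factor_sd: float = 1.0
    purity_coef: float = 1.5

    # survival
    n_prognostic_unfavorable: int = 5
    n_prognostic_favorable: int = 3
    prognostic_beta: float = 0.8
    baseline_hazard: float = 1.0 / 1200.0

    # CRISPR screen
    n_lines_per_cancer: int = 6
    sgrnas_per_gene: int = 4
    n_screen_replicates: int = 2
    essential_fraction: float = 0.117
    n_planted_broad_essential: int = 4
    n_planted_narrow_essential: int = 4
    narrow_essential_cancers: int = 2
    essential_depletion: float = -1.0
    screen_noise_sd: float = 0.2
    nonunique_fraction: float = 0.05
    n_ref_nonessential: int = 40

    # developmental series
    n_dev_stages: int = 12
    n_dev_reps: int = 3
    stage_bias_fraction: float = 0.30
    embryonic_background: float = 0.272
    dev_fold: float = 4.0
    dev_noise_sd: float = 0.25
    dev_low_fraction: float = 0.05

    # catalog filter violations (fractions of genes)
    frac_noncoding: float = 0.02
    frac_short: float = 0.01
    frac_high_identity: float = 0.02
    frac_panel_silent: float = 0.01
    frac_cancer_silent: float = 0.01

    def validate(self) -> None:
        counts = (self.n_genes, self.n_cancer_types, self.n_tumor, self.n_normal,
                  self.n_tissues, self.n_tissue_reps, self.n_dev_reps)
        if any(c < 1 for c in counts):
            raise ConfigError("all counts must be >= 1")
        props = self.class_proportions
        if set(props) != set(CLASSES):
            raise ConfigError(f"class proportions must cover {CLASSES}")
        if any(p < 0 for p in props.values()) or abs(sum(props.values()) - 1.0) > 1e-9:
            raise ConfigError("class proportions must be a simplex (sum to 1)")
        if not 0 <= self.conflict_fraction < 1:
            raise ConfigError("conflict fraction must be in [0, 1)")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")


def _rng(config: SynthConfig, tag: str) -> np.random.Generator:
    """One RNG stream per output, seeded from (config seed, file tag)."""
    return np.random.default_rng([config.seed, zlib.crc32(tag.encode())])


@dataclass
class GroundTruth:
    """Planted labels; every id references an emitted catalog gene."""

    pan_up: list = field(default_factory=list)
    pan_down: list = field(default_factory=list)
    affected_cancers: dict = field(default_factory=dict)  # gene -> [cancer]
    prognostic: dict = field(default_factory=dict)  # gene -> +1/-1
    essential: dict = field(default_factory=dict)  # gene -> [cell line]
    module: dict = field(default_factory=dict)  # gene -> module id
    stage: dict = field(default_factory=dict)  # gene -> planted stage label
    cellcycle: list = field(default_factory=list)
    conflicting: list = field(default_factory=list)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


def _class_counts(n: int, proportions: dict) -> dict:
    """Largest-remainder allocation: each class within +-1 of p * n."""
    raw = {c: proportions[c] * n for c in CLASSES}
    counts = {c: int(np.floor(raw[c])) for c in CLASSES}
    rest = n - sum(counts.values())
    order = sorted(CLASSES, key=lambda c: raw[c] - counts[c], reverse=True)
    for c in order[:rest]:
        counts[c] += 1
    return counts


def generate_catalog(config: SynthConfig) -> pd.DataFrame:
    """Gene catalog with age groups, classes, family strata and annotation.

    Columns: chrom, strand, tss, length, biotype, paralog_identity,
    age_group (1-14), age_class, family_stratum, conflict, bias (planted
    broad/tissue label), top_tissue.  A ``round(conflict_fraction*n)``-sized
    subset carries inconsistent dual ages (vertebrate-ancestor locus call
    with a post-vertebrate family stratum) to exercise the merge step.
    """
    config.validate()
    rng = _rng(config, "catalog")
    n = config.n_genes
    gene_ids = [f"G{i:05d}" for i in range(n)]

    counts = _class_counts(n, config.class_proportions)
    classes = np.concatenate([[c] * counts[c] for c in CLASSES])
    rng.shuffle(classes)

    bounds = DEFAULT_CLASS_BOUNDARIES
    group = np.array([rng.integers(bounds[c][0], bounds[c][1] + 1) for c in classes])

    # family-level stratum: always <= locus group (a family predates its loci)
    family = np.array([int(rng.integers(1, g + 1)) for g in group])
    # PSGs are often derived duplicates of unicellular-ancestor families
    psg = classes == "PSG"
    uc_derived = rng.random(n) < 0.371
    family = np.where(psg & uc_derived, rng.integers(1, 4, size=n), family)

    n_conflict = int(round(config.conflict_fraction * n))
    conflict_idx = rng.choice(n, size=n_conflict, replace=False)
    conflict = np.zeros(n, dtype=bool)
    conflict[conflict_idx] = True

    bias_p = np.array([config.tissue_bias_fraction[c] for c in classes])
    biased = rng.random(n) < bias_p
    tissues = [f"tissue{t:02d}" for t in range(config.n_tissues)]
    top_tissue = rng.choice(tissues, size=n)

    cat = pd.DataFrame(
        {
            "chrom": rng.choice(CHROMS, size=n),
            "strand": rng.choice(["+", "-"], size=n),
            "tss": rng.integers(10_000, 5_000_000, size=n),
            "length": rng.integers(300, 5000, size=n),
            "biotype": "protein_coding",
            "paralog_identity": np.round(rng.uniform(0.0, 0.95, size=n), 4),
            "age_group": group,
            "age_class": classes,
            "family_stratum": family,
            "conflict": conflict,
            "bias": np.where(biased, "tissue-biased", "broad"),
            "top_tissue": top_tissue,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # planted filter violations, kept off the conflict set so the special
    # genes chosen later (from clean, retained genes) are unaffected
    clean = np.flatnonzero(~conflict)
    rng.shuffle(clean)
    k = 0

    def take(frac):
        nonlocal k
        m = int(round(frac * n))
        sel = clean[k:k + m]
        k += m
        return sel

    cat.iloc[take(config.frac_noncoding), cat.columns.get_loc("biotype")] = "lncRNA"
    cat.iloc[take(config.frac_short), cat.columns.get_loc("length")] = 120
    cat.iloc[take(config.frac_high_identity), cat.columns.get_loc("paralog_identity")] = 0.99
    # panel-silent and cancer-silent genes are drawn from their own streams
    # (see _panel_silent_genes / _cancer_silent_genes) so the expression
    # generators can reproduce the same choice independently
    return cat


def _panel_silent_genes(catalog: pd.DataFrame, config: SynthConfig) -> np.ndarray:
    rng = _rng(config, "panel_silent")
    ok = (~catalog["conflict"]) & (catalog["biotype"] == "protein_coding") \
        & (catalog["length"] >= 150) & (catalog["paralog_identity"] <= 0.975)
    pool = np.flatnonzero(ok.to_numpy())
    m = int(round(config.frac_panel_silent * config.n_genes))
    return rng.choice(pool, size=min(m, pool.size), replace=False)


def _cancer_silent_genes(catalog: pd.DataFrame, config: SynthConfig) -> np.ndarray:
    rng = _rng(config, "cancer_silent")
    silent_panel = set(_panel_silent_genes(catalog, config))
    ok = (~catalog["conflict"]) & (catalog["biotype"] == "protein_coding") \
        & (catalog["length"] >= 150) & (catalog["paralog_identity"] <= 0.975)
    pool = np.array([i for i in np.flatnonzero(ok.to_numpy()) if i not in silent_panel])
    m = int(round(config.frac_cancer_silent * config.n_genes))
    return rng.choice(pool, size=min(m, pool.size), replace=False)


def plan_truth(catalog: pd.DataFrame, config: SynthConfig) -> GroundTruth:
    """Choose the planted gene sets (deterministic given config seed).

    Special genes are drawn from clean genes (non-conflicting, passing all
    catalog filters and not planted silent), so every planted label survives
    the gene-model filters.  The planted cell-cycle module deliberately
    overlaps pan-up PSGs, the prognostic set, the essential set and the
    embryonic stage bias - the multi-omics convergence the pipeline is meant
    to recover.
    """
    rng = _rng(config, "truth")
    silent = set(_panel_silent_genes(catalog, config)) | set(_cancer_silent_genes(catalog, config))
    clean_mask = (
        (~catalog["conflict"])
        & (catalog["biotype"] == "protein_coding")
        & (catalog["length"] >= 150)
        & (catalog["paralog_identity"] <= 0.975)
    ).to_numpy()
    clean_mask[list(silent)] = False
    genes = catalog.index.to_numpy()
    truth = GroundTruth()
    truth.conflicting = sorted(genes[catalog["conflict"].to_numpy()])

    cancers = [f"C{c:02d}" for c in range(config.n_cancer_types)]
    n_aff = min(config.n_affected_cancers, config.n_cancer_types)

    up, down = [], []
    for cls in CLASSES:
        pool = np.flatnonzero(clean_mask & (catalog["age_class"] == cls).to_numpy())
        rng.shuffle(pool)
        n_up = int(round(config.pan_up_fraction[cls] * pool.size))
        n_down = int(round(config.pan_down_fraction[cls] * pool.size))
        if n_up + n_down > pool.size:
            raise ConfigError(f"more planted genes than available in class {cls}")
        up.extend(pool[:n_up])
        down.extend(pool[n_up:n_up + n_down])
    truth.pan_up = sorted(genes[sorted(up)])
    truth.pan_down = sorted(genes[sorted(down)])
    for g in truth.pan_up + truth.pan_down:
        truth.affected_cancers[g] = sorted(
            rng.choice(cancers, size=n_aff, replace=False))

    # coexpression modules; module 0 is the "cell cycle" module seeded with
    # pan-up PSGs on distinct chromosomes
    psg_up = [g for g in truth.pan_up if catalog.loc[g, "age_class"] == "PSG"]
    other_up = [g for g in truth.pan_up if g not in psg_up]
    used: set = set()
    for m in range(config.n_modules):
        members: list = []
        seen_chroms: set = set()
        seed_pool = (psg_up + other_up) if m == 0 else other_up
        for g in seed_pool:
            if g in used or catalog.loc[g, "chrom"] in seen_chroms:
                continue
            members.append(g)
            seen_chroms.add(catalog.loc[g, "chrom"])
            if len(members) == config.module_size:
                break
        for g in members:
            used.add(g)
            truth.module[g] = m
    truth.cellcycle = sorted(g for g, m in truth.module.items() if m == 0)

    # prognostic genes: unfavorable from pan-up PSGs/UC genes, favorable others
    prog_pool = [g for g in truth.pan_up if g not in truth.module or truth.module[g] == 0]
    unf = prog_pool[: config.n_prognostic_unfavorable]
    fav = [g for g in truth.pan_down][: config.n_prognostic_favorable]
    for g in unf:
        truth.prognostic[g] = 1
    for g in fav:
        truth.prognostic[g] = -1

    # essential genes: broad (all lines) from the cell-cycle module, narrow
    # (all lines of a couple of cancers) from the remaining pan-up genes
    lines = [f"{c}_L{i}" for c in cancers for i in range(config.n_lines_per_cancer)]
    broad = truth.cellcycle[: config.n_planted_broad_essential]
    narrow_pool = [g for g in truth.pan_up if g not in broad]
    narrow = narrow_pool[: config.n_planted_narrow_essential]
    for g in broad:
        truth.essential[g] = lines
    for i, g in enumerate(narrow):
        start = (i * config.narrow_essential_cancers) % config.n_cancer_types
        chosen = [cancers[(start + j) % config.n_cancer_types]
                  for j in range(config.narrow_essential_cancers)]
        truth.essential[g] = [ln for ln in lines if ln.split("_L")[0] in chosen]

    # developmental stage bias: cell-cycle genes mostly embryonic, the rest
    # of the biased genes follow the background stage distribution
    stages = [f"S{s:02d}" for s in range(1, config.n_dev_stages + 1)]
    biased = rng.random(config.n_genes) < config.stage_bias_fraction
    p_embryo = config.embryonic_background
    p_rest = (1 - p_embryo) / (config.n_dev_stages - 1)
    stage_p = np.array([p_embryo] + [p_rest] * (config.n_dev_stages - 1))
    for i in np.flatnonzero(biased & clean_mask):
        truth.stage[genes[i]] = str(rng.choice(stages, p=stage_p))
    for g in truth.cellcycle:  # 80%-style embryonic concentration
        truth.stage[g] = stages[0] if rng.random() < 0.8 else str(rng.choice(stages[1:]))
    return truth


def generate_age_tables(catalog: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit the two age sources consistent with the catalog.

    Post-vertebrate genes (groups 9-14) carry their group as the synteny
    call and their family stratum in the phylostratigraphy table; older
    genes carry the vertebrate-ancestor synteny code (0) and their group as
    the family stratum.  Conflicting genes get a vertebrate-ancestor locus
    call paired with a post-vertebrate family stratum.
    """
    syn_rows, fam_rows = [], []
    for gene, row in catalog.iterrows():
        grp = int(row["age_group"])
        fam = int(row["family_stratum"]) if grp >= 9 else grp
        syn = grp if grp >= 9 else 0
        if row["conflict"]:
            syn = 0
            fam = max(grp, 9)
        syn_rows.append((gene, syn))
        fam_rows.append((gene, fam))
    synteny = pd.DataFrame(syn_rows, columns=["gene_id", "synteny_group"])
    family = pd.DataFrame(fam_rows, columns=["gene_id", "phylostratum"])
    return synteny, family


def generate_tissue_panel(catalog: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """26-tissue normal panel, >= 3 replicates per tissue, TPM scale."""
    rng = _rng(config, "panel")
    n = len(catalog)
    tissues = [f"tissue{t:02d}" for t in range(config.n_tissues)]
    silent = np.zeros(n, dtype=bool)
    silent[_panel_silent_genes(catalog, config)] = True
    base = 2.0 ** rng.normal(config.base_log2_mean, 1.0, size=n)
    biased = (catalog["bias"] == "tissue-biased").to_numpy()
    top = catalog["top_tissue"].to_numpy()
    cols = {}
    for t in tissues:
        for r in range(config.n_tissue_reps):
            mean = base.copy()
            off = top != t
            mean[biased & off] = 0.02
            mean[biased & ~off] = base[biased & ~off] * 4
            mean[silent] = 0.01
            vals = mean * rng.lognormal(0.0, 0.3, size=n)
            cols[f"{t}|rep{r}"] = np.round(vals, 4)
    return pd.DataFrame(cols, index=catalog.index)


def _nb_counts(rng, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draws with mean ``mean`` and NB2 dispersion phi."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def _coupled_normal_scores(rng, anchor: np.ndarray, rho_s: float) -> np.ndarray:
    """Latent values with target Spearman ``rho_s`` against ``anchor``.

    Normal scores of the anchor's ranks are mixed with fresh noise at the
    Pearson level r = 2 sin(pi * rho_s / 6), the Gaussian-copula conversion
    from Spearman to Pearson correlation.
    """
    n = anchor.size
    u = (rankdata(anchor, method="average") - 0.5) / n
    z = norm.ppf(u)
    r = 2.0 * np.sin(np.pi * rho_s / 6.0)
    return r * z + np.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)


@dataclass
class OmicsCohort:
    """One cancer type's multi-omics bundle."""

    cancer_type: str
    counts: pd.DataFrame  # genes x samples (tumor + normal)
    tpm: pd.DataFrame
    samples: pd.DataFrame  # sample-indexed: patient, is_tumor, purity
    cna: pd.DataFrame  # genes x tumor samples
    meth: pd.DataFrame  # probes x tumor samples (beta values)
    survival: pd.DataFrame  # patient-indexed: time, event, age, stage, gender


def _gene_rho(catalog: pd.DataFrame, table: dict) -> np.ndarray:
    cls = catalog["age_class"].to_numpy()
    bias = catalog["bias"].to_numpy()
    rho = np.full(len(catalog), table["default"], dtype=float)
    rho[(cls == "PSG") & (bias == "broad")] = table["PSG_broad"]
    rho[(cls == "PSG") & (bias == "tissue-biased")] = table["PSG_tissue"]
    return rho


def generate_cohort(
    catalog: pd.DataFrame, config: SynthConfig, truth: GroundTruth, cancer_type: str
) -> OmicsCohort:
    """One cancer type: expression, copy number, methylation, purity, survival."""
    rng = _rng(config, f"cohort:{cancer_type}")
    n = len(catalog)
    genes = catalog.index
    n_t, n_n = config.n_tumor, config.n_normal
    tumor_ids = [f"{cancer_type}_T{i:03d}" for i in range(n_t)]
    normal_ids = [f"{cancer_type}_N{i:03d}" for i in range(n_n)]
    sample_ids = tumor_ids + normal_ids
    is_tumor = np.array([True] * n_t + [False] * n_n)

    purity = np.clip(rng.beta(8, 2, size=n_t), 0.05, 1.0)

    mu = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    silent = _cancer_silent_genes(catalog, config)
    mu[silent] = -3.0

    # planted tumor effects
    effect = np.zeros(n)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for g in truth.pan_up:
        if cancer_type in truth.affected_cancers[g]:
            effect[gene_pos[g]] = config.effect_log2
    for g in truth.pan_down:
        if cancer_type in truth.affected_cancers[g]:
            effect[gene_pos[g]] = -config.effect_log2

    # shared structure: per-sample module latent factors (coexpression is a
    # property of the tissue, tumor and normal alike) plus a tumor-only
    # purity loading that the partial correlation must control away
    factors = rng.standard_normal((config.n_modules, n_t + n_n)) * config.module_factor_sd
    module_of = np.full(n, -1)
    for g, m in truth.module.items():
        module_of[gene_pos[g]] = m
    purity_load = rng.uniform(0.2, 0.6, size=n)

    logmean = np.tile(mu[:, None], (1, n_t + n_n)).astype(float)
    logmean[:, :n_t] += effect[:, None]
    for m in range(config.n_modules):
        rows = module_of == m
        logmean[rows, :] += factors[m][None, :]
    logmean[:, :n_t] += purity_load[:, None] * config.purity_coef * (purity - purity.mean())[None, :]

    lib = rng.lognormal(0.0, 0.15, size=n_t + n_n)
    mean = (2.0 ** logmean) * lib[None, :]
    counts = _nb_counts(rng, mean, config.dispersion)
    counts_df = pd.DataFrame(counts, index=genes, columns=sample_ids)

    lengths = catalog["length"].to_numpy(dtype=float)
    rpk = counts / lengths[:, None]
    tpm = rpk / rpk.sum(axis=0, keepdims=True) * 1e6
    tpm_df = pd.DataFrame(np.round(tpm, 4), index=genes, columns=sample_ids)

    # copy number coupled to tumor expression ranks at the class-level rho
    cna_rho = _gene_rho(catalog, config.cna_rho)
    tumor_counts = counts[:, :n_t].astype(float)
    cna = np.empty((n, n_t))
    for i in range(n):
        z = _coupled_normal_scores(rng, tumor_counts[i], cna_rho[i])
        cna[i] = np.round(z * 0.5, 4)
    cna_df = pd.DataFrame(cna, index=genes, columns=tumor_ids)

    # methylation: probe 0 is the coupled promoter probe, probe 1 a neutral
    # promoter probe, probe 2 distal noise
    meth_rho = _gene_rho(catalog, config.meth_rho)
    probe_rows = []
    beta_rows = []
    for i, g in enumerate(genes):
        for pno in range(config.probes_per_gene):
            pid = f"{g}_p{pno}"
            if pno == 0:
                z = _coupled_normal_scores(rng, tumor_counts[i], meth_rho[i])
            else:
                z = rng.standard_normal(n_t)
            beta_rows.append(np.round(norm.cdf(z), 4))
            probe_rows.append(pid)
    beta = np.array(beta_rows)
    na_mask = rng.random(beta.shape) < config.probe_na_fraction
    noisy = rng.random(len(probe_rows)) < config.noisy_probe_fraction
    na_mask[noisy] |= rng.random((noisy.sum(), n_t)) < config.noisy_probe_na
    beta[na_mask] = np.nan
    meth_df = pd.DataFrame(beta, index=pd.Index(probe_rows, name="probe_id"),
                           columns=tumor_ids)

    # survival on tumor patients; planted genes act through standardized
    # log2 tumor expression
    log2t = np.log2(tumor_counts + 1.0)
    lin = np.zeros(n_t)
    for g, sign in truth.prognostic.items():
        x = log2t[gene_pos[g]]
        sd = x.std()
        if sd > 0:
            lin += sign * config.prognostic_beta * (x - x.mean()) / sd
    age = rng.normal(60, 10, size=n_t)
    stage = rng.integers(1, 5, size=n_t)
    gender = rng.integers(0, 2, size=n_t)
    lin += 0.01 * (age - 60) + 0.1 * (stage - 2.5)
    hazard = config.baseline_hazard * np.exp(lin)
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(200, 2500, size=n_t)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    surv_df = pd.DataFrame(
        {
            "time": np.round(time, 2),
            "event": event,
            "age": np.round(age, 1),
            "stage": stage,
            "gender": gender,
        },
        index=pd.Index(tumor_ids, name="patient"),
    )

    samples_df = pd.DataFrame(
        {
            "patient": sample_ids,
            "is_tumor": is_tumor,
            "purity": np.round(np.concatenate([purity, np.full(n_n, np.nan)]), 4),
            "cancer_type": cancer_type,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return OmicsCohort(cancer_type, counts_df, tpm_df, samples_df, cna_df,
                       meth_df, surv_df)


def generate_probe_annotation(catalog: pd.DataFrame, config: SynthConfig) -> pd.DataFrame:
    """BED-like probe annotation (0-based half-open), strand-aware placement.

    Probe 0 sits 800 bp upstream of the TSS, probe 1 sits 200 bp downstream
    (both inside the -1500..+500 promoter window), probe 2 sits 5 kb
    downstream (outside).
    """
    offsets = [-800, 200, 5000]
    rows = []
    for g, row in catalog.iterrows():
        sign = 1 if row["strand"] == "+" else -1
        for pno in range(config.probes_per_gene):
            d = offsets[pno % len(offsets)]
            start = int(row["tss"] + sign * d)
            rows.append((row["chrom"], start, start + 2, f"{g}_p{pno}", g))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "probe_id", "gene_id"])


def generate_screen(catalog: pd.DataFrame, config: SynthConfig, truth: GroundTruth):
    """sgRNA-level CRISPR screen with reference gene lists.

    Returns a :class:`atavipan.screen.Screen`.  Reference essential genes are
    centered at the planted depletion, nonessential references at zero; raw
    fold changes carry a per-line affine distortion that the anchored
    normalization must undo.  Reference list sizes track the essential
    fraction so that truly depleted genes fill the per-line essential quota.
    """
    from .screen import Screen  # local import to avoid cycle

    rng = _rng(config, "screen")
    genes = catalog.index.to_numpy()
    n = len(genes)
    cancers = [f"C{c:02d}" for c in range(config.n_cancer_types)]
    lines = [f"{c}_L{i}" for c in cancers for i in range(config.n_lines_per_cancer)]
    line_cancer = pd.Series({ln: ln.split("_L")[0] for ln in lines})

    planted = set(truth.essential)
    n_slots = math.ceil(config.essential_fraction * n)
    n_ref_ess = max(5, n_slots - len(planted))
    pool = [g for g in genes if g not in planted]
    rng.shuffle(pool)
    ess_refs = sorted(pool[:n_ref_ess])
    non_refs = sorted(pool[n_ref_ess:n_ref_ess + config.n_ref_nonessential])

    true_effect = pd.DataFrame(0.0, index=genes, columns=lines)
    true_effect.loc[ess_refs, :] = config.essential_depletion
    for g, gl in truth.essential.items():
        true_effect.loc[g, gl] = config.essential_depletion

    sg_ids = [f"sg_{g}_{j}" for g in genes for j in range(config.sgrnas_per_gene)]
    guide_map = pd.Series(
        np.repeat(genes, config.sgrnas_per_gene), index=sg_ids, name="gene_id")
    unique = pd.Series(
        rng.random(len(sg_ids)) >= config.nonunique_fraction, index=sg_ids, name="unique")

    cols = pd.MultiIndex.from_tuples(
        [(ln, f"rep{r}") for ln in lines for r in range(config.n_screen_replicates)],
        names=["cell_line", "replicate"],
    )
    scale = rng.uniform(0.8, 1.2, size=len(lines))
    shift = rng.normal(0.0, 0.1, size=len(lines))
    eff = true_effect.to_numpy()
    data = np.empty((len(sg_ids), len(cols)))
    for li, ln in enumerate(lines):
        for r in range(config.n_screen_replicates):
            col = li * config.n_screen_replicates + r
            noise = rng.normal(0.0, config.screen_noise_sd, size=len(sg_ids))
            truth_vals = np.repeat(eff[:, li], config.sgrnas_per_gene)
            data[:, col] = scale[li] * (truth_vals + noise) + shift[li]
    lfc = pd.DataFrame(np.round(data, 4), index=pd.Index(sg_ids, name="sgrna"), columns=cols)
    return Screen(lfc=lfc, guide_map=guide_map, unique=unique,
                  line_cancer=line_cancer, essential_refs=ess_refs,
                  nonessential_refs=non_refs)


def generate_dev_series(
    catalog: pd.DataFrame, config: SynthConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, pd.Series]:
    """Cerebral developmental series: genes x (stage, replicate) expression.

    Returns the sample-level matrix and the sample -> stage map.  Planted
    stage-biased genes are elevated ``dev_fold``-fold at their stage; a
    ``dev_low_fraction`` of genes stays below the downstream expression
    floor at every stage.
    """
    rng = _rng(config, "dev")
    n = len(catalog)
    genes = catalog.index
    stages = [f"S{s:02d}" for s in range(1, config.n_dev_stages + 1)]
    samples = [f"{s}|rep{r}" for s in stages for r in range(config.n_dev_reps)]
    stage_map = pd.Series({smp: smp.split("|")[0] for smp in samples})

    base = np.clip(rng.normal(2.0, 1.0, size=n), 0.4, None)
    low = rng.random(n) < config.dev_low_fraction
    planted_pos = {g: i for i, g in enumerate(genes)}
    base[low] = 0.05
    for g in truth.stage:  # planted genes stay expressed
        base[planted_pos[g]] = max(base[planted_pos[g]], 0.5)

    lift = np.log2(config.dev_fold)
    mat = np.empty((n, len(samples)))
    stage_idx = {s: i for i, s in enumerate(stages)}
    gene_stage = np.full(n, -1)
    for g, s in truth.stage.items():
        gene_stage[planted_pos[g]] = stage_idx[s]
    for j, smp in enumerate(samples):
        si = stage_idx[stage_map[smp]]
        mean = base + np.where(gene_stage == si, lift, 0.0)
        noise_sd = np.where(low, 0.02, config.dev_noise_sd)
        mat[:, j] = np.clip(mean + rng.normal(0.0, 1.0, size=n) * noise_sd, 0.0, None)
    series = pd.DataFrame(np.round(mat, 4), index=genes, columns=samples)
    return series, stage_map


def generate_gene_sets(
    catalog: pd.DataFrame, config: SynthConfig, truth: GroundTruth
) -> tuple[dict, list]:
    """Hallmark-style GMT collection plus the curated cell-cycle list.

    The first set contains the planted cell-cycle module (plus padding
    genes); the remaining sets are random draws, giving the binomial
    assignment engine true and null targets.  The curated list extends the
    module with additional cell-cycle genes, emulating an independent
    literature-curated catalog.
    """
    rng = _rng(config, "sets")
    genes = [g for g in catalog.index]
    sets = {}
    pad = [g for g in genes if g not in truth.cellcycle]
    rng.shuffle(pad)
    sets["HALLMARK_CELL_CYCLE"] = sorted(truth.cellcycle + pad[:40])
    # random sets are drawn independently and may overlap, like real
    # hallmark collections
    for i in range(1, 9):
        size = min(int(rng.integers(30, 80)), len(pad))
        sets[f"HALLMARK_RANDOM_{i:02d}"] = sorted(
            rng.choice(pad, size=size, replace=False))
    extra = rng.choice(pad, size=min(25, len(pad)), replace=False)
    curated = sorted(set(sets["HALLMARK_CELL_CYCLE"]) | set(extra))
    return sets, curated


def generate_selection_lists(
    catalog: pd.DataFrame, config: SynthConfig, truth: GroundTruth
) -> dict[str, list[str]]:
    """Positive-selection gene lists planted with an embryonic-stage excess."""
    rng = _rng(config, "selection")
    stage1 = [g for g, s in truth.stage.items() if s == "S01"]
    others = [g for g in truth.stage if truth.stage[g] != "S01"]
    rng.shuffle(stage1)
    rng.shuffle(others)
    out = {}
    for name, n_s1, n_rest in (("pos_sel_coding", 30, 40), ("pos_sel_promoter", 45, 60)):
        out[name] = sorted(stage1[:n_s1] + others[:n_rest])
    return out


def generate_all(config: SynthConfig) -> dict:
    """Generate every pipeline input in memory.

    Returns a dict with the catalog, age tables, tissue panel, per-cancer
    cohorts, probe annotation, screen, developmental series, gene sets,
    selection lists and ground truth.
    """
    config.validate()
    catalog = generate_catalog(config)
    truth = plan_truth(catalog, config)
    synteny, family = generate_age_tables(catalog)
    panel = generate_tissue_panel(catalog, config)
    cancers = [f"C{c:02d}" for c in range(config.n_cancer_types)]
    cohorts = {c: generate_cohort(catalog, config, truth, c) for c in cancers}
    probes = generate_probe_annotation(catalog, config)
    scr = generate_screen(catalog, config, truth)
    dev_series, dev_map = generate_dev_series(catalog, config, truth)
    gene_sets, curated = generate_gene_sets(catalog, config, truth)
    selection = generate_selection_lists(catalog, config, truth)
    return {
        "config": config,
        "catalog": catalog,
        "truth": truth,
        "synteny": synteny,
        "family": family,
        "panel": panel,
        "cancers": cancers,
        "cohorts": cohorts,
        "probes": probes,
        "screen": scr,
        "dev_series": dev_series,
        "dev_map": dev_map,
        "gene_sets": gene_sets,
        "cellcycle_list": curated,
        "selection_lists": selection,
    }


def write_bundle(config: SynthConfig, outdir) -> Path:
    """Generate all inputs and write them under ``outdir``.

    Emits TSV matrices, a BED-like probe annotation, a GMT gene-set file,
    plain-text gene lists, the ground-truth JSON and a ``manifest.yaml``
    declaring every path.  Returns the manifest path.
    """
    from .io import write_gene_list, write_gmt, write_manifest, write_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = generate_all(config)
    prov = {"seed": config.seed}

    catalog = bundle["catalog"]
    public_catalog = catalog[
        ["chrom", "strand", "tss", "length", "biotype", "paralog_identity"]
    ]
    write_tsv(public_catalog, out / "catalog.tsv", prov)
    write_tsv(bundle["synteny"], out / "ages_synteny.tsv", prov, index=False)
    write_tsv(bundle["family"], out / "ages_family.tsv", prov, index=False)
    write_tsv(bundle["panel"], out / "tissue_panel.tsv", prov)
    write_tsv(bundle["probes"], out / "probes.tsv", prov, index=False)

    cohort_paths = {}
    for c, coh in bundle["cohorts"].items():
        paths = {}
        for name, df, idx in (
            ("counts", coh.counts, True),
            ("tpm", coh.tpm, True),
            ("samples", coh.samples, True),
            ("cna", coh.cna, True),
            ("meth", coh.meth, True),
            ("survival", coh.survival, True),
        ):
            p = out / f"{name}_{c}.tsv"
            write_tsv(df, p, prov, index=idx)
            paths[name] = p.name
        cohort_paths[c] = paths

    scr = bundle["screen"]
    flat = scr.lfc.copy()
    flat.columns = [f"{ln}|{rep}" for ln, rep in scr.lfc.columns]
    screen_tab = pd.concat(
        [scr.guide_map.rename("gene_id"), scr.unique.rename("unique"), flat], axis=1
    )
    write_tsv(screen_tab, out / "screen.tsv", prov)
    write_tsv(
        scr.line_cancer.rename("cancer_type").rename_axis("cell_line").to_frame(),
        out / "screen_lines.tsv", prov,
    )
    write_gene_list(scr.essential_refs, out / "screen_essential_refs.txt")
    write_gene_list(scr.nonessential_refs, out / "screen_nonessential_refs.txt")

    write_tsv(bundle["dev_series"], out / "dev_cerebrum.tsv", prov)
    write_tsv(
        bundle["dev_map"].rename("stage").rename_axis("sample").to_frame(),
        out / "dev_stages.tsv", prov,
    )
    write_gmt(bundle["gene_sets"], out / "hallmark_sets.gmt")
    write_gene_list(bundle["cellcycle_list"], out / "cellcycle_list.txt")
    sel_paths = {}
    for name, genes in bundle["selection_lists"].items():
        write_gene_list(genes, out / f"{name}.txt")
        sel_paths[name] = f"{name}.txt"
    bundle["truth"].to_json(out / "ground_truth.json")

    manifest = {
        "seed": config.seed,
        "cancers": bundle["cancers"],
        "paths": {
            "catalog": "catalog.tsv",
            "ages_synteny": "ages_synteny.tsv",
            "ages_family": "ages_family.tsv",
            "tissue_panel": "tissue_panel.tsv",
            "probes": "probes.tsv",
            "gene_sets": "hallmark_sets.gmt",
            "cellcycle_list": "cellcycle_list.txt",
            "selection_lists": sel_paths,
            "ground_truth": "ground_truth.json",
            "dev_series": "dev_cerebrum.tsv",
            "dev_stage_map": "dev_stages.tsv",
            "screen": "screen.tsv",
            "screen_lines": "screen_lines.tsv",
            "screen_essential_refs": "screen_essential_refs.txt",
            "screen_nonessential_refs": "screen_nonessential_refs.txt",
            "cohorts": cohort_paths,
        },
    }
    write_manifest(manifest, out / "manifest.yaml")
    return out / "manifest.yaml"
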