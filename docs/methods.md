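# Methods

This note documents the models, parameter choices and numerical conventions
behind `atavipan`, including what the synthetic-data generator does and does
not emulate.

## Gene-age catalog

Two dating sources are merged onto one 14-group scale. The synteny source
dates loci: groups 9–14 for genes postdating the vertebrate split (youngest
= 14, primate), and a single "vertebrate ancestor or older" code for
everything else. The family source (phylostratigraphy) dates protein
families on strata 1–14, with 1–8 pre-vertebrate. Merge rules:

- post-vertebrate locus call → the locus group is the merged age; a family
  stratum *younger* than the locus is impossible (a family is at least as
  old as any locus it contains) and flags the gene as conflicting;
- vertebrate-ancestor locus call → the family stratum (1–8) is adopted; a
  post-vertebrate family stratum is a conflict; with no family call the
  gene stays undated;
- family-only genes adopt their stratum; conflicting and undated genes are
  excluded from all age-class analyses, with the reason logged.

Age classes partition the scale contiguously: UC = groups 1–3, EM = 4–9,
MM = 10–13, PSG = 14 (configurable). For family-level "UC-derived
duplicate" tests, strata 1–3 count as unicellular by default; the boundary
is a config knob because no authoritative split exists.

Tissue specificity is τ = Σᵢ(1 − xᵢ/x_max)/(N − 1) over per-tissue mean
expression. τ is computed on log₂(TPM + 1) means: the log damps
single-tissue outliers and matches common usage of the index; the raw-scale
variant is available by passing `log_transform=False`. Genes with τ > 0.8
(strict) are tissue-biased. The gene-model filters are four pure
predicates: protein-coding with transcript ≥ 150 bp; paralog identity
≤ 97.5% (short-read quantification is unreliable above it); TPM ≥ 0.2
somewhere in the 26-tissue panel; and not "unexpressed" (zero reads in
> 20% of samples) in every cancer type. Being predicates, their
application order cannot change the retained set.

## Differential expression

Counts are scaled by the per-sample upper quartile of nonzero counts
(relative to the geometric mean of upper quartiles across samples) and
transformed to log₂-CPM with pseudocount 0.5. The group test is a
moderated t: per-gene pooled variances are shrunk toward a scaled
inverse-chi-square prior whose degrees of freedom and scale are fitted by
method of moments on the log variances (digamma/trigamma matching, Newton
solve). This is a deliberate, documented stand-in for the limma-voom fit:
it preserves the statistical behavior (variance pooling across genes,
t-reference with inflated df) while keeping the code self-contained; the
voom precision-weight regression is not reproduced. With a single gene
there is no information about the prior, so the prior weight is zero and
the gene's own variance is used. A gene is called up in a cancer when
FDR < 0.05 *and* log₂FC ≥ +0.4 — the fold-change filter is applied
direction-specifically, since the call itself is directional (the
magnitude-only reading would let a strongly *down* gene qualify as "up").
The pan-cancer rule — up in ≥ 3 cancers and in ≥ 3× as many cancers as
down — is symmetric under up/down exchange and monotone in the fold-change
cutoff. FDR is Benjamini–Hochberg step-up.

## ssGSEA

Expression is rank-normalized per sample (average ranks for ties, highest
expression = highest rank), so the score depends only on the ordering.
Walking genes in decreasing rank, the enrichment score accumulates the
difference between the rank^α-weighted in-set ECDF and the uniform
out-of-set ECDF, α = 0.25; the *sum* over all positions is the statistic
(not the extremum). Raw scores are rescaled within each (cancer type, gene
set): divide by the max−min range over that cancer's pooled tumor+normal
samples, then subtract the normal-sample median, anchoring normals at 0.
Pooling the range per cancer type (rather than globally) was an open
choice; per-cancer pooling was selected because all downstream medians are
compared within a cancer. Degenerate (constant-score) groups are skipped
with a log entry rather than dividing by zero.

## Copy number and methylation attribution

Probes with > 5% missing beta values within a cancer are dropped. Probes
are mapped to genes by the annotation table and classified as promoter
probes when the strand-aware signed distance from the principal TSS lies
in [−1500, +500] (BED, 0-based half-open; upstream = 5′ of the TSS on the
coding strand). Among a gene's promoter probes, the one with the strongest
negative Spearman correlation with expression is kept (ties by smallest
probe id). Correlations use tumor samples only — copy-number alteration is
a tumor property, and the paper-level analysis is about tumor
deregulation; including normals is a config-level change, not a default.
"Strong" coupling is ρ > 0.3 for SCNA and ρ < −0.3 for methylation, strict
inequalities; 0.4 is the robustness cutoff. Constant vectors make ρ
undefined; such genes are excluded with a logged reason.

## Coexpression-based annotation

For a query gene, the partial Spearman correlation against every other
retained gene is computed per cancer on tumor samples, controlling for
tumor purity via the first-order partial-correlation formula on ranks
(equivalently: correlate the residuals of rank-regressions on purity
ranks). Cancers where the query fails the expression filter are skipped;
at least 3 usable cancers are required, otherwise no call. Partners
satisfy |median ρ across cancers| ≥ 0.4 and must lie on a different
chromosome from the query (proximity-driven coexpression carries no
functional signal). Gene sets are assigned by a one-sided binomial test of
the partner hit count against the set's universe fraction, with the 2×2
odds ratio required to exceed 1 and p < 0.05. The binomial form (sampling
with replacement) is kept deliberately even though partner draws are
without replacement, to match the method being reproduced; at the set/universe
ratios involved the difference is negligible. The same engine performs
direct curated-list overrepresentation tests (the cell-cycle-list mode)
with BH FDR across sets.

## Survival

Per gene and cancer, a Cox proportional-hazards model of the
progression-free interval includes the gene's log₂ expression plus age,
ordinal stage and gender where available (listwise deletion; degenerate
covariates dropped). Fitting delegates to lifelines (Efron ties, Wald p);
the contract — not the solver — is the specified behavior, and a
hand-coded Newton partial-likelihood oracle verifies it in the tests.
Expression is z-scored per gene by default so hazard ratios are per SD;
raw-scale fitting is a flag. Requirements: ≥ 30 patients and ≥ 10 events.
The net classification counts significant (per-cancer BH FDR < 0.05)
unfavorable (HR > 1) and favorable cancers; net > 0 → unfavorable, < 0 →
favorable, = 0 with signal → intermediate, no signal → non-prognostic.
The top-k mode (k = 1500) instead marks each cancer's k smallest-p genes
as prognostic — ties broken by gene id — and feeds the same classifier.

## CRISPR screens

Non-unique sgRNAs (an input flag; real-mode genome alignment is
infrastructure outside this package's scope and is replaced by a
precomputed uniqueness table) are dropped; genes losing all guides leave
the universe. Per cell line, fold changes are affinely mapped so the
reference nonessential median is exactly 0 and the reference essential
median exactly −1. Gene scores are one flat median over guides ×
replicates (reading "medians of fold changes between replicates"
literally, not a median of medians). Per line, the most-depleted
⌈0.117·G⌉ genes are essential (ceiling; ties by gene id); the fraction is
applied per line rather than as one global threshold, matching a per-line
cutoff choice. Cancers with < 5 lines are excluded; dependency = essential
in ≥ 3 of a cancer's lines. Common dependencies: per line, ascending
ranks (most depleted = 1) normalized by gene count; per gene the 90th
percentile (type-7 linear interpolation) of its normalized ranks across
lines; the smallest ⌈0.062·G⌉ flagged. Essential-calling and
common-dependency flags are invariant to any monotone increasing
transform of a line's scores.

## Developmental staging

The cerebral series is reduced to per-stage medians (12 stages, ≥ 2
replicates each). Genes with all stage medians < 0.2 are removed (a median
exactly 0.2 stays). Stage medians are log₂(TPM + 1)-scale values; each
gene's 12 values are Z-scored with the sample SD (n − 1; the population
variant would shift every Z by a constant factor ~4.5%, the cutoff was
calibrated against a 90% quantile so the sample form is used and flagged
as a choice). Assignment = argmax stage when Z_max > 1.2; constant rows
and tied maxima stay unassigned (ties logged). Group enrichment per stage
uses exact one-sided binomial tails in both directions against the
universe's per-stage assigned proportions (or an explicit background,
e.g. 0.272 for the embryonic stage), BH-corrected over 12 stages × 2
directions at FDR 0.1. Positive-selection gene lists run through the same
engine. Comparison organs are additional series through identical code.

## The synthetic-data generator

The generator emits every pipeline input with planted truth, all
deterministic: each output table draws from an RNG stream seeded by
(config seed, file tag), so identical configs give byte-identical files.

What it emulates, and the default study conditions:

- **Catalog**: 800 genes (2000 in the pan-cancer recovery condition),
  class proportions UC/EM/MM/PSG = 0.325/0.48/0.168/0.027 (the real
  catalog's shape), 2% conflicting dual ages, tissue-bias fractions
  declining with age (PSG 45% → UC 9%), paralog identities, transcript
  lengths, and planted violations of each gene-model filter (1–2% each).
- **Expression**: negative binomial counts, gene means log-normal
  (log₂ mean 4 ± 1.5), NB dispersion 0.15, per-sample library factors;
  TPM from counts with the catalog's fixed lengths. 6 cancer types
  (13 in the recovery condition) × 60 tumors + 30 normals. The 30 normals
  reflect typical normal-control counts for the studied cancer types
  rather than the 15-sample inclusion floor. Planted pan-up/down genes
  (class-level rates echoing the observed proportions, e.g. one third of
  PSGs pan-up) carry a ±1.0 log₂ effect in 6 of the cancers —
  about the observed breadth of pan-cancer deregulated genes.
- **Coexpression**: two module factors (SD 1.0 in log₂ space) shared by
  module genes in tumor *and* normal samples — a module is a property of
  the tissue — giving within-module correlations ≈ 0.7; module 0 ("cell
  cycle") deliberately overlaps the pan-up PSGs, the planted essential
  and prognostic genes and the embryonic stage bias, because that
  multi-omics convergence is the phenomenon the pipeline exists to
  recover. All genes additionally load on tumor purity (the confounder
  the partial correlation must remove).
- **Copy number / methylation**: rank-coupled to tumor expression through
  a Gaussian copula on normal scores (Pearson level r = 2 sin(πρ_s/6)), so
  Spearman targets hold for any marginal. Targets: broadly transcribed
  PSGs ρ = 0.6 (SCNA) / −0.2 (methylation); tissue-biased PSGs 0.0 /
  −0.6; other genes 0.35 / −0.3 — the amplification-vs-hypomethylation
  contrast between PSG classes. Three probes per gene (two promoter, one
  distal; only one promoter probe coupled), 1% missing betas plus 3% of
  probes pushed over the missingness filter.
- **Survival**: exponential baseline (rate 1/1200 per day), uniform
  censoring (~55–60% events), small real age/stage effects, and planted
  per-gene log-hazards ±0.8 per SD of expression on 5 unfavorable and 3
  favorable genes.
- **Screen**: 4 sgRNAs × 2 replicates per gene over 6 lines per cancer;
  reference essential genes at depletion −1 and nonessential at 0, with
  per-line affine distortions the normalization must undo; guide noise
  SD 0.2; 5% non-unique sgRNAs; planted broad essentials (all lines) and
  narrow essentials (two cancers). Reference list sizes track the 11.7%
  essential fraction so truly depleted genes fill the per-line quota.
- **Developmental series**: 12 stages × 3 replicates; 30% of genes
  stage-biased at 4-fold, stages drawn with the embryonic stage at
  probability 0.272 and the cell-cycle module concentrated there (80%);
  5% of genes below the expression floor; positive-selection lists
  planted with an embryonic excess.

What it does **not** emulate — and therefore what passing tests do *not*
show about real data: read-level artifacts and mapping bias (counts are
drawn, not aligned), segmental SCNA structure (gene-level scores are
independent draws given expression), methylation array chemistry, batch
effects, intra-tumor heterogeneity beyond a scalar purity, linkage between
neighboring genes, and realistic survival covariate structure. Recovery
rates here certify the pipeline's logic, not its power on TCGA-scale data.

## Problem sizes and runtime

Default end-to-end runs use 800 genes × 6 cancers (~90 samples each); the
pan-cancer recovery study uses 2000 genes × 13 cancers; Cox calibration
uses 1000 null replicates at n = 500 (Monte-Carlo error ≈ 0.7% on
coverage) and 100 replicates at n = 300 for sign recovery. These sizes
were chosen so the entire suite and the acceptance script each complete
in minutes on a single CPU while leaving the statistical conclusions
well-resolved.

## Known limitations

- The moderated test approximates, but does not reproduce, limma-voom;
  exact per-gene p-values differ from a voom fit.
- The survival stage in `run_all` tests only genes with a pan-cancer call
  (the set of interest downstream); a genome-wide Cox scan is available
  through the library API but is the slowest stage.
- The binomial set-assignment test ignores the without-replacement nature
  of partner draws (hypergeometric would be exact).
- The conflict rule for age merging encodes only the pre/post-vertebrate
  epoch inconsistency; finer cross-source disagreements pass through.
- Enrichment backgrounds are configurable but default to the retained
  universe; results are sensitive to that choice and both universes the
  literature uses are supported rather than one asserted.
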