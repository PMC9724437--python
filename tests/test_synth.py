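"""Synthetic-data generator: determinism, planted structure, copula coupling."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from atavipan import synth
from atavipan.regulation import spearman


@pytest.fixture(scope="module")
def small_config():
    return synth.SynthConfig(n_genes=400, n_cancer_types=4, n_tumor=40,
                             n_normal=10, seed=7)


@pytest.fixture(scope="module")
def small_catalog(small_config):
    return synth.generate_catalog(small_config)


class TestConfig:
    def test_invalid_proportions_rejected(self):
        cfg = synth.SynthConfig(class_proportions={
            "UC": 0.5, "EM": 0.5, "MM": 0.5, "PSG": 0.5})
        with pytest.raises(synth.ConfigError):
            cfg.validate()

    def test_bad_counts_rejected(self):
        with pytest.raises(synth.ConfigError):
            synth.SynthConfig(n_genes=0).validate()

    def test_too_many_planted_genes_rejected(self):
        cfg = synth.SynthConfig(
            n_genes=100, seed=1,
            pan_up_fraction={"UC": 0.9, "EM": 0.9, "MM": 0.9, "PSG": 0.9},
            pan_down_fraction={"UC": 0.9, "EM": 0.9, "MM": 0.9, "PSG": 0.9})
        cat = synth.generate_catalog(cfg)
        with pytest.raises(synth.ConfigError):
            synth.plan_truth(cat, cfg)


class TestCatalog:
    def test_class_counts_within_one_of_proportions(self):
        cfg = synth.SynthConfig(n_genes=2000, seed=1)
        cat = synth.generate_catalog(cfg)
        counts = cat["age_class"].value_counts()
        for cls, p in cfg.class_proportions.items():
            assert abs(counts[cls] - p * 2000) <= 1

    def test_conflict_count_exact(self):
        cfg = synth.SynthConfig(n_genes=400, conflict_fraction=0.05, seed=3)
        cat = synth.generate_catalog(cfg)
        assert int(cat["conflict"].sum()) == round(0.05 * 400)

    def test_same_seed_identical_catalogs(self, small_config):
        c1 = synth.generate_catalog(small_config)
        c2 = synth.generate_catalog(small_config)
        pd.testing.assert_frame_equal(c1, c2)

    def test_family_stratum_never_younger_than_locus(self, small_catalog):
        clean = small_catalog[~small_catalog["conflict"]]
        assert (clean["family_stratum"] <= clean["age_group"]).all()


class TestGroundTruthConsistency:
    def test_planted_ids_exist_and_cancers_valid(self, small_config, small_catalog):
        truth = synth.plan_truth(small_catalog, small_config)
        cancers = {f"C{c:02d}" for c in range(small_config.n_cancer_types)}
        genes = set(small_catalog.index)
        planted = (set(truth.pan_up) | set(truth.pan_down)
                   | set(truth.prognostic) | set(truth.essential)
                   | set(truth.module) | set(truth.stage))
        assert planted <= genes
        for g, cc in truth.affected_cancers.items():
            assert set(cc) <= cancers
        for g, lines in truth.essential.items():
            assert all(ln.split("_L")[0] in cancers for ln in lines)

    def test_planted_genes_survive_model_filters(self, small_config, small_catalog):
        truth = synth.plan_truth(small_catalog, small_config)
        cat = small_catalog
        for g in set(truth.pan_up) | set(truth.prognostic) | set(truth.module):
            assert cat.loc[g, "biotype"] == "protein_coding"
            assert cat.loc[g, "length"] >= 150
            assert cat.loc[g, "paralog_identity"] <= 0.975
            assert not cat.loc[g, "conflict"]


class TestCopulaCoupling:
    def test_target_spearman_within_tolerance(self):
        """|realized - planted| < 0.1 at n=500 across 20 seeds."""
        for rho in (0.35, 0.6, -0.6):
            errs = []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                anchor = rng.gamma(2.0, 10.0, size=500)
                z = synth._coupled_normal_scores(rng, anchor, rho)
                errs.append(abs(spearman(anchor, z) - rho))
            assert max(errs) < 0.1

    def test_zero_coupling_independent(self):
        """Planted rho=0: realized expression-CNA Spearman within 0.15 at n=200."""
        rng = np.random.default_rng(42)
        anchor = rng.gamma(2.0, 10.0, size=200)
        z = synth._coupled_normal_scores(rng, anchor, 0.0)
        assert abs(spearman(anchor, z)) < 0.15

    def test_cohort_level_coupling_by_psg_bias(self, small_config, small_catalog):
        truth = synth.plan_truth(small_catalog, small_config)
        coh = synth.generate_cohort(small_catalog, small_config, truth, "C00")
        tumor = coh.samples.index[coh.samples["is_tumor"]]
        cat = small_catalog
        bpsg = cat.index[(cat["age_class"] == "PSG") & (cat["bias"] == "broad")]
        tpsg = cat.index[(cat["age_class"] == "PSG") & (cat["bias"] == "tissue-biased")]
        rho_b = [spearman(coh.counts.loc[g, tumor], coh.cna.loc[g, tumor])
                 for g in bpsg]
        rho_t = [spearman(coh.counts.loc[g, tumor], coh.cna.loc[g, tumor])
                 for g in tpsg]
        assert np.median(rho_b) > np.median(rho_t) + 0.2


class TestCohort:
    def test_deterministic_under_fixed_seed(self, small_config, small_catalog):
        truth = synth.plan_truth(small_catalog, small_config)
        c1 = synth.generate_cohort(small_catalog, small_config, truth, "C01")
        c2 = synth.generate_cohort(small_catalog, small_config, truth, "C01")
        pd.testing.assert_frame_equal(c1.counts, c2.counts)
        pd.testing.assert_frame_equal(c1.meth, c2.meth)
        pd.testing.assert_frame_equal(c1.survival, c2.survival)

    def test_planted_shift_visible_in_affected_cancer(self, small_config, small_catalog):
        truth = synth.plan_truth(small_catalog, small_config)
        g = truth.pan_up[0]
        cancer = truth.affected_cancers[g][0]
        coh = synth.generate_cohort(small_catalog, small_config, truth, cancer)
        tumor = coh.samples.index[coh.samples["is_tumor"]]
        normal = coh.samples.index[~coh.samples["is_tumor"]]
        lfc = (np.log2(coh.counts.loc[g, tumor].mean() + 1)
               - np.log2(coh.counts.loc[g, normal].mean() + 1))
        assert lfc > 0.4

    def test_purity_in_unit_interval(self, small_config, small_catalog):
        truth = synth.plan_truth(small_catalog, small_config)
        coh = synth.generate_cohort(small_catalog, small_config, truth, "C02")
        pur = coh.samples.loc[coh.samples["is_tumor"], "purity"]
        assert ((pur > 0) & (pur <= 1)).all()


class TestScreenGenerator:
    def test_zero_nonunique_filter_removes_nothing(self, small_catalog):
        cfg = synth.SynthConfig(n_genes=400, n_cancer_types=4, n_tumor=40,
                                n_normal=10, seed=7, nonunique_fraction=0.0)
        truth = synth.plan_truth(small_catalog, cfg)
        scr = synth.generate_screen(small_catalog, cfg, truth)
        from atavipan.screen import filter_unique_sgrnas

        out = filter_unique_sgrnas(scr)
        assert out.lfc.shape == scr.lfc.shape

    def test_reference_genes_centered_at_planted_depletion(self, small_config,
                                                           small_catalog):
        truth = synth.plan_truth(small_catalog, small_config)
        scr = synth.generate_screen(small_catalog, small_config, truth)
        from atavipan.screen import gene_scores, normalize_screen

        scaled = normalize_screen(scr.lfc, scr.guide_map,
                                  scr.essential_refs, scr.nonessential_refs)
        scores = gene_scores(scaled, scr.guide_map)
        ess = scores.loc[scores.index.isin(scr.essential_refs)]
        non = scores.loc[scores.index.isin(scr.nonessential_refs)]
        assert ess.median(axis=0).mean() == pytest.approx(-1.0, abs=0.05)
        assert non.median(axis=0).mean() == pytest.approx(0.0, abs=0.05)


class TestDevSeriesGenerator:
    def test_deterministic(self, small_config, small_catalog):
        truth = synth.plan_truth(small_catalog, small_config)
        s1, m1 = synth.generate_dev_series(small_catalog, small_config, truth)
        s2, m2 = synth.generate_dev_series(small_catalog, small_config, truth)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_series_equal(m1, m2)

    def test_planted_fold_visible_at_true_stage(self, small_config, small_catalog):
        from atavipan.devstage import assign_stage, stage_medians

        truth = synth.plan_truth(small_catalog, small_config)
        series, stage_map = synth.generate_dev_series(small_catalog, small_config, truth)
        medians = stage_medians(series, stage_map)
        assign = assign_stage(medians)
        planted = list(truth.stage)[:50]
        hits = sum(assign.loc[g, "stage"] == truth.stage[g] for g in planted)
        assert hits / len(planted) >= 0.9
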