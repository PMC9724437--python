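"""Probe filtering, promoter-probe selection and expression-factor correlation."""

import numpy as np
import pandas as pd
import pytest

from _oracles import spearman_bruteforce
from atavipan import regulation as reg


class TestProbeFilter:
    def test_na_fraction_cutoff(self):
        """6% NA removed, 0% NA kept (50-sample cancer, 5% cutoff)."""
        cols = [f"s{i}" for i in range(50)]
        beta = pd.DataFrame(0.5, index=["clean", "noisy"], columns=cols)
        beta.loc["noisy", cols[:3]] = np.nan  # 6%
        kept = reg.filter_probes(beta, max_na=0.05)
        assert list(kept) == ["clean"]

    def test_retained_set_matches_hand_count(self):
        rng = np.random.default_rng(1)
        cols = [f"s{i}" for i in range(20)]
        probes = [f"p{i}" for i in range(10)]
        na_counts = [0, 0, 1, 1, 2, 2, 3, 4, 5, 6]  # 5% of 20 = 1 allowed
        beta = pd.DataFrame(rng.random((10, 20)), index=probes, columns=cols)
        for p, k in zip(probes, na_counts):
            beta.loc[p, cols[:k]] = np.nan
        kept = reg.filter_probes(beta, max_na=0.05)
        assert sorted(kept) == ["p0", "p1", "p2", "p3"]


class TestProbeAnnotation:
    def _catalog(self):
        return pd.DataFrame(
            {"chrom": ["chr1", "chr2"], "tss": [10_000, 50_000],
             "strand": ["+", "-"]},
            index=pd.Index(["gA", "gB"], name="gene_id"),
        )

    def test_strand_aware_signed_distance(self):
        bed = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr2", "chr2"],
                "start": [9_200, 10_400, 50_800, 49_600],
                "end": [9_202, 10_402, 50_802, 49_602],
                "probe_id": ["pA1", "pA2", "pB1", "pB2"],
                "gene_id": ["gA", "gA", "gB", "gB"],
            }
        )
        ann = reg.annotate_probes(bed, self._catalog()).set_index("probe_id")
        # + strand: upstream = smaller coordinate
        assert ann.loc["pA1", "tss_distance"] == -800
        assert ann.loc["pA2", "tss_distance"] == 400
        # - strand: upstream = larger coordinate
        assert ann.loc["pB1", "tss_distance"] == -800
        assert ann.loc["pB2", "tss_distance"] == 400
        assert ann["is_promoter"].all()

    def test_promoter_window_boundaries(self):
        bed = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "start": [10_000 - 1500, 10_000 + 500, 10_000 - 1501],
                "end": [10_000 - 1498, 10_000 + 502, 10_000 - 1499],
                "probe_id": ["edge_up", "edge_down", "outside"],
                "gene_id": ["gA"] * 3,
            }
        )
        ann = reg.annotate_probes(bed, self._catalog()).set_index("probe_id")
        assert ann.loc["edge_up", "is_promoter"]
        assert ann.loc["edge_down", "is_promoter"]
        assert not ann.loc["outside", "is_promoter"]


class TestPromoterProbeSelection:
    def _inputs(self, rhos, probe_ids):
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(60)]
        expr_vals = rng.normal(size=60)
        expr = pd.DataFrame([expr_vals], index=["gA"], columns=samples)
        rows = []
        for rho in rhos:
            noise = rng.normal(size=60)
            rows.append(rho * expr_vals + np.sqrt(1 - rho**2) * noise)
        beta = pd.DataFrame(rows, index=probe_ids, columns=samples)
        ann = pd.DataFrame(
            {"probe_id": probe_ids, "gene_id": "gA", "is_promoter": True})
        return ann, beta, expr

    def test_strongest_negative_correlation_wins(self):
        ann, beta, expr = self._inputs([-0.5, -0.2], ["p_strong", "p_weak"])
        chosen = reg.select_promoter_probe(ann, beta, expr)
        assert chosen["gA"] == "p_strong"

    def test_single_probe_selected(self):
        ann, beta, expr = self._inputs([-0.3], ["only"])
        assert reg.select_promoter_probe(ann, beta, expr)["gA"] == "only"

    def test_tie_broken_by_smallest_probe_id(self):
        """Identical beta vectors give identical rho: lexicographic tie-break."""
        ann, beta, expr = self._inputs([-0.4], ["pZ"])
        beta = pd.concat([beta, beta.rename(index={"pZ": "pA"})])
        ann = pd.DataFrame({"probe_id": ["pZ", "pA"], "gene_id": "gA",
                            "is_promoter": True})
        assert reg.select_promoter_probe(ann, beta, expr)["gA"] == "pA"


class TestSpearman:
    def test_perfect_monotone(self):
        assert reg.spearman([1, 2, 3, 4], [10, 20, 80, 90]) == pytest.approx(1.0)
        assert reg.spearman([1, 2, 3, 4], [9, 7, 5, 3]) == pytest.approx(-1.0)

    def test_independent_pair_near_zero(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=500), rng.normal(size=500)
        assert abs(reg.spearman(x, y)) < 0.1

    def test_matches_rank_pearson_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(500):
            n = int(rng.integers(4, 30))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            if rng.random() < 0.3:
                x = np.round(x, 0)  # ties
            assert reg.spearman(x, y) == pytest.approx(
                spearman_bruteforce(x, y), abs=1e-12)

    def test_constant_vector_undefined(self):
        assert np.isnan(reg.spearman([1, 1, 1], [1, 2, 3]))


class TestStrongProportions:
    def _corr(self):
        # 3 groups x 2 cancers, two genes per group, hand-countable strong
        # flags at cutoff 0.3
        rows = []
        groups = {}
        gid = 0
        for grp in ("grpA", "grpB", "grpC"):
            for k in range(2):
                groups[f"g{gid}"] = grp
                gid += 1
        vals = {
            "C1": {"g0": 0.5, "g1": 0.2, "g2": 0.1, "g3": 0.0, "g4": 0.35, "g5": 0.35},
            "C2": {"g0": 0.9, "g1": 0.31, "g2": 0.29, "g3": -0.5, "g4": 0.3, "g5": 0.3},
        }
        for cancer, d in vals.items():
            for g, rho in d.items():
                rows.append((g, cancer, "SCNA", rho))
        corr = pd.DataFrame(rows, columns=["gene_id", "cancer_type", "factor", "rho"])
        return corr, pd.Series(groups)

    def test_proportions_equal_hand_counts(self):
        corr, groups = self._corr()
        out = reg.strong_proportions(corr, groups, cutoff=0.3).set_index(
            ["factor", "cancer_type", "group"])
        # C1: grpA 1/2 strong (0.5), grpB 0/2, grpC 2/2 (0.35 > 0.3)
        assert out.loc[("SCNA", "C1", "grpA"), "proportion"] == 0.5
        assert out.loc[("SCNA", "C1", "grpB"), "proportion"] == 0.0
        assert out.loc[("SCNA", "C1", "grpC"), "proportion"] == 1.0
        # C2: grpA 2/2 (0.9, 0.31), grpB 0/2 (0.29 and -0.5), grpC 0/2 (0.3 not > 0.3)
        assert out.loc[("SCNA", "C2", "grpA"), "proportion"] == 1.0
        assert out.loc[("SCNA", "C2", "grpB"), "proportion"] == 0.0
        assert out.loc[("SCNA", "C2", "grpC"), "proportion"] == 0.0

    def test_cutoff_exactly_at_threshold_not_strong(self):
        corr = pd.DataFrame(
            [("g", "C", "SCNA", 0.3), ("h", "C", "methylation", -0.3)],
            columns=["gene_id", "cancer_type", "factor", "rho"])
        flags = reg.strong_flag(corr, cutoff=0.3)
        assert not flags.any()

    def test_monotone_nonincreasing_in_cutoff(self):
        corr, groups = self._corr()
        p03 = reg.strong_proportions(corr, groups, cutoff=0.3)["proportion"]
        p04 = reg.strong_proportions(corr, groups, cutoff=0.4)["proportion"]
        assert (p04.to_numpy() <= p03.to_numpy() + 1e-12).all()

    def test_degenerate_extremes(self):
        corr = pd.DataFrame(
            [("g", "C", "SCNA", 0.0), ("h", "C", "SCNA", 1.0)],
            columns=["gene_id", "cancer_type", "factor", "rho"])
        groups = pd.Series({"g": "X", "h": "Y"})
        out = reg.strong_proportions(corr, groups).set_index("group")
        assert out.loc["X", "proportion"] == 0.0
        assert out.loc["Y", "proportion"] == 1.0


def test_expr_factor_correlation_excludes_constant_factor():
    rng = np.random.default_rng(12)
    samples = [f"s{i}" for i in range(20)]
    expr = pd.DataFrame(rng.normal(size=(2, 20)),
                        index=["g_ok", "g_const"], columns=samples)
    factor = pd.DataFrame(
        np.vstack([rng.normal(size=20), np.zeros(20)]),
        index=["g_ok", "g_const"], columns=samples)
    out = reg.expr_factor_correlation(expr, factor, "SCNA", "C1")
    assert list(out["gene_id"]) == ["g_ok"]
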