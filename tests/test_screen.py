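"""Screen reprocessing: uniqueness filter, anchoring, scores, dependency calls."""

import numpy as np
import pandas as pd
import pytest

from _oracles import common_dependency_bruteforce
from atavipan import screen as sm


def _toy_screen(unique=None):
    sgrnas = [f"sg{i}" for i in range(8)]
    genes = ["gA"] * 4 + ["gB"] * 4
    lfc = pd.DataFrame(
        np.arange(16, dtype=float).reshape(8, 2),
        index=pd.Index(sgrnas, name="sgrna"),
        columns=pd.MultiIndex.from_tuples(
            [("L1", "rep0"), ("L1", "rep1")], names=["cell_line", "replicate"]),
    )
    return sm.Screen(
        lfc=lfc,
        guide_map=pd.Series(genes, index=sgrnas),
        unique=pd.Series(unique if unique is not None else [True] * 8, index=sgrnas),
        line_cancer=pd.Series({"L1": "C0"}),
        essential_refs=["gA"],
        nonessential_refs=["gB"],
    )


class TestUniqueFilter:
    def test_all_unique_is_identity(self):
        scr = _toy_screen()
        out = sm.filter_unique_sgrnas(scr)
        pd.testing.assert_frame_equal(out.lfc, scr.lfc)

    def test_gene_with_no_unique_sgrnas_leaves_universe(self):
        scr = _toy_screen(unique=[True] * 4 + [False] * 4)
        out = sm.filter_unique_sgrnas(scr)
        assert set(out.guide_map) == {"gA"}

    def test_mixed_flags_match_hand_filter(self):
        flags = [True, False, True, False, False, True, True, True]
        scr = _toy_screen(unique=flags)
        out = sm.filter_unique_sgrnas(scr)
        want = [s for s, f in zip(scr.lfc.index, flags) if f]
        assert list(out.lfc.index) == want

    def test_overlapping_reference_lists_rejected(self):
        with pytest.raises(ValueError):
            sm.Screen(
                lfc=pd.DataFrame(), guide_map=pd.Series(dtype=object),
                unique=pd.Series(dtype=bool), line_cancer=pd.Series(dtype=object),
                essential_refs=["g1"], nonessential_refs=["g1"],
            )


class TestNormalize:
    def _frame(self, values):
        genes = [f"g{i}" for i in range(len(values))]
        df = pd.DataFrame({"L1": values}, index=genes)
        return df, pd.Series(genes, index=genes)

    def test_anchoring_identities(self):
        # essential genes at -1.9, nonessential at 0.1
        df, gmap = self._frame([-1.9, -1.9, 0.1, 0.1, -0.9])
        out = sm.normalize_screen(df, gmap, ["g0", "g1"], ["g2", "g3"])
        assert out.loc["g0", "L1"] == pytest.approx(-1.0)
        assert out.loc["g2", "L1"] == pytest.approx(0.0)
        # affine evaluation of the midpoint
        assert out.loc["g4", "L1"] == pytest.approx(-0.5)

    def test_degenerate_screen_rejected(self):
        df, gmap = self._frame([0.5, 0.5, 0.5, 0.5])
        with pytest.raises(ValueError):
            sm.normalize_screen(df, gmap, ["g0", "g1"], ["g2", "g3"])

    def test_median_anchors_hold_exactly_per_line(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(60)]
        ess, non = genes[:15], genes[15:30]
        df = pd.DataFrame(rng.normal(size=(60, 5)), index=genes,
                          columns=[f"L{j}" for j in range(5)])
        df.loc[ess] -= 2.0
        out = sm.normalize_screen(df, pd.Series(genes, index=genes), ess, non)
        for col in out.columns:
            assert np.median(out.loc[ess, col]) == pytest.approx(-1.0, abs=1e-12)
            assert np.median(out.loc[non, col]) == pytest.approx(0.0, abs=1e-12)


class TestGeneScores:
    def test_single_sgrna_single_replicate_identity(self):
        lfc = pd.DataFrame({"L1": [0.7]}, index=["sg0"])
        out = sm.gene_scores(lfc, pd.Series({"sg0": "gA"}))
        assert out.loc["gA", "L1"] == 0.7

    def test_flat_median_over_guides_and_replicates(self):
        """{-1, -1, 0, 0} -> -0.5; and 4 sgRNAs x 2 replicates collapse in
        one flat median, not a median of medians."""
        cols = pd.MultiIndex.from_tuples([("L1", "rep0"), ("L1", "rep1")])
        lfc = pd.DataFrame([[-1.0, -1.0], [0.0, 0.0]],
                           index=["sg0", "sg1"], columns=cols)
        out = sm.gene_scores(lfc, pd.Series({"sg0": "gA", "sg1": "gA"}))
        assert out.loc["gA", "L1"] == -0.5

        rng = np.random.default_rng(1)
        vals = rng.normal(size=(4, 2))
        lfc = pd.DataFrame(vals, index=[f"sg{i}" for i in range(4)], columns=cols)
        gmap = pd.Series("gB", index=lfc.index)
        out = sm.gene_scores(lfc, gmap)
        assert out.loc["gB", "L1"] == pytest.approx(np.median(vals), abs=1e-12)


class TestDependencyCalls:
    def test_ceiling_rule_essential_count(self):
        assert sm.essential_count(100, 0.117) == 12

    def test_two_of_six_lines_is_no_dependency(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(50)]
        lines = [f"L{j}" for j in range(6)]
        scores = pd.DataFrame(rng.normal(size=(50, 6)), index=genes, columns=lines)
        scores.loc["g0", ["L0", "L1"]] = -10.0  # essential in exactly 2 lines
        scores.loc["g0", lines[2:]] = 10.0
        calls = sm.call_dependencies(
            scores, pd.Series("C0", index=lines), fraction=0.1)
        assert calls.essential.loc["g0"].sum() == 2
        assert not calls.dependency.loc["g0", "C0"]

    def test_small_cancers_excluded(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(20)]
        lines = [f"L{j}" for j in range(8)]
        cancer = pd.Series(["big"] * 5 + ["small"] * 3, index=lines)
        scores = pd.DataFrame(rng.normal(size=(20, 8)), index=genes, columns=lines)
        calls = sm.call_dependencies(scores, cancer)
        assert calls.excluded_cancers == ["small"]
        assert list(calls.dependency.columns) == ["big"]

    def test_planted_essentials_recovered_without_false_calls(self):
        """Planted depletion -1, noise sd 0.2: every planted gene called, no
        false dependencies."""
        rng = np.random.default_rng(4)
        n_genes, n_lines = 200, 12
        genes = [f"g{i:03d}" for i in range(n_genes)]
        lines = [f"L{j}" for j in range(n_lines)]
        cancer = pd.Series(["C0"] * 6 + ["C1"] * 6, index=lines)
        k = sm.essential_count(n_genes, 0.117)  # 24 planted essentials
        scores = pd.DataFrame(rng.normal(0, 0.2, size=(n_genes, n_lines)),
                              index=genes, columns=lines)
        scores.iloc[:k] -= 1.0
        calls = sm.call_dependencies(scores, cancer)
        dep = calls.dependency
        assert dep.iloc[:k].all().all()
        assert not dep.iloc[k:].any().any()


class TestCommonDependency:
    def test_single_line_statistic_is_own_rank(self):
        scores = pd.DataFrame({"L1": [-2.0, 0.0, 1.0]},
                              index=pd.Index(["a", "b", "c"], name="gene_id"))
        out = sm.common_dependency(scores)
        np.testing.assert_allclose(out["rank90"], [1 / 3, 2 / 3, 1.0])

    def test_rank_one_everywhere_flagged(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(40)]
        scores = pd.DataFrame(rng.normal(size=(40, 4)), index=genes,
                              columns=list("wxyz"))
        scores.loc["g0"] = -99.0
        out = sm.common_dependency(scores)
        assert out.loc["g0", "rank90"] == pytest.approx(1 / 40)
        assert out.loc["g0", "common"]

    def test_matches_bruteforce_on_toys(self):
        """20-gene x 5-line random toys: flags equal the explicit
        sort/quantile oracle."""
        rng = np.random.default_rng(6)
        genes = [f"g{i:02d}" for i in range(20)]
        for _ in range(25):
            mat = rng.normal(size=(20, 5))
            scores = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                                  columns=[f"L{j}" for j in range(5)])
            out = sm.common_dependency(scores, top_fraction=0.2)
            stats, flags = common_dependency_bruteforce(mat, genes, 0.90, 0.2)
            np.testing.assert_allclose(out["rank90"], stats, atol=1e-12)
            assert list(out["common"]) == flags

    def test_invariant_to_monotone_transform_of_a_line(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(30)]
        scores = pd.DataFrame(rng.normal(size=(30, 3)), index=genes,
                              columns=["L0", "L1", "L2"])
        warped = scores.copy()
        warped["L1"] = np.exp(warped["L1"]) * 3 + 1  # strictly increasing
        out1 = sm.common_dependency(scores)
        out2 = sm.common_dependency(warped)
        pd.testing.assert_frame_equal(out1, out2)

    def test_superset_stability(self):
        """Adding a strictly worse-ranked gene never unflags a common gene."""
        rng = np.random.default_rng(8)
        genes = [f"g{i:02d}" for i in range(20)]
        mat = rng.normal(size=(20, 4))
        scores = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"),
                              columns=list("abcd"))
        before = sm.common_dependency(scores, top_fraction=0.2)
        worse = pd.DataFrame([mat.max(axis=0) + 1.0],
                             index=pd.Index(["zzz"], name="gene_id"),
                             columns=list("abcd"))
        after = sm.common_dependency(pd.concat([scores, worse]), top_fraction=0.2)
        flagged_before = set(before.index[before["common"]])
        flagged_after = set(after.index[after["common"]])
        assert flagged_before <= flagged_after
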