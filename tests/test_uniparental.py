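import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ancestrykit.uniparental import (
    ContinentMap,
    ExactTestResult,
    HaplogroupConflictError,
    HaplogroupTree,
    ancestry_count_table,
    ancestry_proportions,
    call_haplogroup,
    compare_systems,
    fisher_exact_rc,
    regional_heterogeneity,
    two_tier_typing,
)

CORE_24 = {
    "SRY1532", "M91", "M168", "M145", "M174", "12f2", "M96", "M213", "M201",
    "M69", "M52", "M170", "M172", "M9", "M20", "M106", "M214", "Tat", "M175",
    "M45", "MEH2", "M207", "M269", "M124",
}
E_SUBTYPE_18 = {
    "M33", "P2", "M2", "M154", "M191", "M215", "M35", "M78", "V12", "M224",
    "V32", "V13", "V22", "M81", "M123", "M281", "V6", "M75",
}


@pytest.fixture(scope="module")
def tree():
    return HaplogroupTree.packaged()


class TestPackagedTree:
    def test_contains_all_42_markers(self, tree):
        assert tree.markers == CORE_24 | E_SUBTYPE_18
        assert len(tree.markers) == 42

    def test_markers_unique_along_paths(self, tree):
        for node in tree.by_label.values():
            path = node.path_markers()
            assert len(path) == len(set(path))


class TestCallHaplogroup:
    def test_all_ancestral_calls_root(self, tree):
        geno = {m: "A" for m in CORE_24}
        label, support = call_haplogroup(geno, tree)
        assert label == "Y"
        assert support == []

    def test_e_path_reaches_subclade(self, tree):
        geno = {m: "A" for m in CORE_24 | E_SUBTYPE_18}
        for m in ("M168", "M145", "M96", "P2", "M2"):
            geno[m] = "D"
        label, support = call_haplogroup(geno, tree)
        assert label == "E1b1a"
        assert support == ["M168", "M145", "M96", "P2", "M2"]

    def test_sibling_conflict_raises_and_names_markers(self, tree):
        geno = {"M201": "D", "M170": "D"}  # G and I are siblings under F
        with pytest.raises(HaplogroupConflictError) as err:
            call_haplogroup(geno, tree)
        assert {"M201", "M170"} <= set(err.value.markers)

    def test_missing_does_not_block_descent(self, tree):
        # M168/M145 untyped, deeper derived M96 confirms the path
        label, _ = call_haplogroup({"M96": "D"}, tree)
        assert label == "E"

    def test_input_order_invariance(self, tree):
        markers = ["M168", "M213", "M9", "M45", "M207", "M269"]
        geno = {m: "D" for m in markers}
        ref = call_haplogroup(geno, tree)
        flipped = dict(reversed(list(geno.items())))
        assert call_haplogroup(flipped, tree) == ref
        assert ref[0] == "R1b1b2"

    def test_adding_missing_marker_never_changes_call(self, tree):
        geno = {"M168": "D", "M213": "D", "M170": "D"}
        ref = call_haplogroup(geno, tree)
        geno2 = dict(geno, M9=None, Tat=None)
        assert call_haplogroup(geno2, tree) == ref

    def test_unknown_marker_rejected(self, tree):
        with pytest.raises(KeyError, match="not in tree"):
            call_haplogroup({"M999": "D"}, tree)


class TestTwoTierTyping:
    def test_non_e_call_ignores_subtype_markers(self, tree):
        geno = {"M168": "D", "M213": "D", "M201": "D", "M191": "D"}
        label, _ = two_tier_typing(geno, CORE_24, E_SUBTYPE_18, tree)
        assert label == "G"

    def test_e_call_descends_with_subtype_markers(self, tree):
        geno = {
            "M168": "D", "M145": "D", "M96": "D",
            "P2": "D", "M2": "D", "M191": "D",
        }
        label, _ = two_tier_typing(geno, CORE_24, E_SUBTYPE_18, tree)
        assert label == "E1b1a7"

    def test_e_call_with_missing_subtypes_stays_at_e(self, tree):
        geno = {"M168": "D", "M145": "D", "M96": "D"}
        label, _ = two_tier_typing(geno, CORE_24, E_SUBTYPE_18, tree)
        assert label == "E"

    def test_overlapping_marker_sets_rejected(self, tree):
        with pytest.raises(ValueError, match="disjoint"):
            two_tier_typing({}, {"M96"}, {"M96"}, tree)


class TestContinentMap:
    def test_longest_prefix_wins(self):
        cmap = ContinentMap.packaged("mtDNA")
        assert cmap.resolve("D4") == "EastAsia"
        assert cmap.resolve("D1") == "America"
        assert cmap.resolve("L2a") == "Africa"

    def test_unresolvable_label_raises(self):
        cmap = ContinentMap({"R": "Europe"})
        with pytest.raises(KeyError, match="resolves to no continent"):
            cmap.resolve("Q1a")

    def test_checksum_stable_and_sensitive(self):
        a = ContinentMap({"R": "Europe"})
        b = ContinentMap({"R": "Europe"})
        c = ContinentMap({"R": "Asia"})
        assert a.checksum() == b.checksum()
        assert a.checksum() != c.checksum()


class TestAncestryProportions:
    def test_simple_counting(self):
        cmap = ContinentMap.packaged("NRY")
        haps = ["R1b1b2"] * 10 + ["E1b1a", "Q1a"]
        tab = ancestry_proportions(haps, cmap)
        assert tab.loc["Europe", "count"] == 10
        assert tab.loc["Europe", "proportion"] == pytest.approx(10 / 12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ancestry_proportions([], ContinentMap.packaged("NRY"))

    def test_sampled_origins_within_binomial_bound(self, rng):
        cmap = ContinentMap.packaged("NRY")
        pool = {"Africa": "E1b1a", "Europe": "R1b1b2"}
        draws = rng.choice(["Africa", "Europe"], p=[0.7, 0.3], size=1000)
        tab = ancestry_proportions([pool[c] for c in draws], cmap)
        assert tab.loc["Africa", "proportion"] == pytest.approx(0.7, abs=0.04)

    def test_count_table_columns_sum_to_group_sizes(self):
        cmap = ContinentMap.packaged("NRY")
        tab = ancestry_count_table(
            {"g1": ["R1b1b2"] * 5 + ["E2"] * 3, "g2": ["Q1a"] * 4}, cmap
        )
        assert tab["g1"].sum() == 8
        assert tab["g2"].sum() == 4


class TestExactTest:
    def test_identical_counts_give_p_one(self):
        res = compare_systems([5, 3, 2], [5, 3, 2])
        assert res.p_value == pytest.approx(1.0)

    def test_2x2_matches_hypergeometric_enumeration(self):
        res = fisher_exact_rc(np.array([[1, 9], [11, 3]]))
        assert res.method == "enumeration"
        assert res.p_value == pytest.approx(0.00276, abs=2e-5)
        # independent oracle
        assert res.p_value == pytest.approx(
            stats.fisher_exact([[1, 9], [11, 3]])[1], abs=1e-12
        )

    def test_monte_carlo_agrees_with_enumeration(self, rng):
        for _ in range(5):
            t = rng.multinomial(60, np.full(8, 1 / 8)).reshape(2, 4)
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
                continue
            full = fisher_exact_rc(t, max_enumeration=10_000_000)
            mc = fisher_exact_rc(t, mc_tables=20_000, rng=rng, max_enumeration=0)
            assert mc.method == "monte_carlo"
            assert abs(mc.p_value - full.p_value) <= 3 * mc.mc_se + 1e-4

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fisher_exact_rc(np.array([[0, 0], [1, 2]]))

    def test_null_p_values_are_uniform(self, rng):
        ps = []
        probs = np.array([0.5, 0.3, 0.15, 0.05])
        for _ in range(300):
            a = rng.multinomial(120, probs)
            b = rng.multinomial(150, probs)
            ps.append(compare_systems(a, b, mc_tables=2000, rng=rng).p_value)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestRegionalHeterogeneity:
    def test_requires_two_eligible_regions(self):
        vals = np.arange(15.0)
        regions = ["a"] * 12 + ["b"] * 3  # b has n <= 10
        with pytest.raises(ValueError, match="fewer than 2 regions"):
            regional_heterogeneity(vals, regions, min_n=10)

    def test_complete_ties_return_h0_p1(self):
        vals = np.ones(40)
        regions = ["a"] * 20 + ["b"] * 20
        stat, p = regional_heterogeneity(vals, regions, min_n=10)
        assert stat == 0.0 and p == 1.0

    def test_shifted_region_detected_with_high_power(self, rng):
        hits = 0
        n_sim = 40
        for _ in range(n_sim):
            g1 = rng.normal(0.5, 0.1, size=30)
            g2 = rng.normal(0.5, 0.1, size=30)
            g3 = rng.normal(0.8, 0.1, size=30)  # +0.3 mean shift
            _, p = regional_heterogeneity(
                np.concatenate([g1, g2, g3]),
                np.repeat(["a", "b", "c"], 30),
                min_n=10,
            )
            hits += p < 0.05
        assert hits >= int(0.85 * n_sim)

    def test_exact_kind_on_categorical_origins(self, rng):
        conts = np.array(["Africa"] * 20 + ["Europe"] * 20)
        regions = np.array((["r1"] * 10 + ["r2"] * 10) * 2)
        stat, p = regional_heterogeneity(
            conts, regions, min_n=5, kind="exact", rng=rng
        )
        assert 0 < p <= 1
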