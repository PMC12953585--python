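"""SNP windows, window trees, topology enumeration and exact weighting."""

from __future__ import annotations

import io
import random

import numpy as np
import pytest
from skbio import TreeNode

import lupus_popgen as lp
from lupus_popgen.cohort import CohortError
from lupus_popgen.topoweights import SnpWindow, StratificationConfig

from conftest import make_cohort
from twisst_oracle import oracle_weights, random_binary_newick


def tree_of(newick: str) -> TreeNode:
    return TreeNode.read(io.StringIO(newick))


def uniform_map(length=10_000_000, rate=1.0):
    return lp.RecombinationMap(["chr1"], np.array([0]), np.array([length]), np.array([rate]))


class TestMakeSnpWindows:
    def test_terminal_remainder_dropped(self):
        gts = [[(0, 1), (0, 0)]] * 250
        cohort = make_cohort(gts, positions=list(range(0, 250 * 400, 400)))
        wins = lp.make_snp_windows(cohort, uniform_map(), 100)
        assert len(wins) == 2
        assert all(w.n_snps == 100 for w in wins)

    def test_overlap_weighted_rate(self):
        gts = [[(0, 1)]] * 100
        # 100 SNPs spanning 0..2 Mb, evenly: half in a 0.1 region, half in 3.0
        positions = list(range(0, 2_000_000, 20_000))
        cohort = make_cohort(gts, positions=positions)
        rmap = lp.RecombinationMap(
            ["chr1", "chr1"],
            np.array([0, 1_000_000]),
            np.array([1_000_000, 2_000_000]),
            np.array([0.1, 3.0]),
        )
        wins = lp.make_snp_windows(cohort, rmap, 100)
        span = wins[0].end - wins[0].start
        first_part = 1_000_000 - wins[0].start
        expected = (0.1 * first_part + 3.0 * (span - first_part)) / span
        assert wins[0].mean_recomb_rate == pytest.approx(expected)

    def test_rate_matches_per_bp_oracle(self):
        rng = np.random.default_rng(1)
        positions = np.sort(rng.choice(3_000_000, size=200, replace=False))
        cohort = make_cohort([[(0, 1)]] * 200, positions=list(positions))
        edges = [0, 700_000, 1_500_000, 2_200_000, 3_000_000]
        rates = [0.05, 1.3, 2.8, 0.4]
        rmap = lp.RecombinationMap(
            ["chr1"] * 4, np.array(edges[:-1]), np.array(edges[1:]), np.array(rates)
        )
        per_bp = np.zeros(3_000_000)
        for s, e, r in zip(edges[:-1], edges[1:], rates):
            per_bp[s:e] = r
        for w in lp.make_snp_windows(cohort, rmap, 100):
            assert w.mean_recomb_rate == pytest.approx(per_bp[w.start : w.end].mean())

    def test_window_snps_below_two_rejected(self):
        cohort = make_cohort([[(0, 1)]] * 10)
        with pytest.raises(CohortError):
            lp.make_snp_windows(cohort, uniform_map(), 1)


class TestInferWindowTree:
    def _window(self, cohort):
        return SnpWindow(
            "chr1", 0, cohort.n_sites - 1, 0, int(cohort.positions[-1]) + 1,
            cohort.n_sites, 1.0,
        )

    def test_two_identical_pairs_recover_split(self):
        # haplotypes of S1 match each other, as do S2's; pairs differ at all sites
        gts = [[(0, 0), (1, 1)]] * 30
        cohort = make_cohort(gts)
        tree = lp.infer_window_tree(cohort, self._window(cohort), ["S1", "S2"])
        sides = [
            frozenset(t.name for t in n.tips()) or frozenset([n.name])
            for n in tree.postorder(include_self=False)
        ]
        assert frozenset({"S1_A", "S1_B"}) in sides or frozenset({"S2_A", "S2_B"}) in sides

    def test_identical_haplotypes_collapse_to_star(self):
        gts = [[(0, 0), (0, 0), (0, 0)]] * 20
        cohort = make_cohort(gts)
        tree = lp.infer_window_tree(cohort, self._window(cohort), ["S1", "S2", "S3"])
        internal = [n for n in tree.non_tips(include_self=False)]
        assert internal == []  # star: all six tips attach to the root

    def test_deterministic_across_sample_order(self):
        rng = np.random.default_rng(3)
        gts = rng.integers(0, 2, size=(40, 3, 2)).tolist()
        gts = [[tuple(c) for c in site] for site in gts]
        cohort = make_cohort(gts)
        w = self._window(cohort)
        t1 = lp.infer_window_tree(cohort, w, ["S1", "S2", "S3"])
        t2 = lp.infer_window_tree(cohort, w, ["S3", "S1", "S2"])
        assert t1.compare_rfd(t2) == 0

    def test_all_missing_haplotype_rejected(self):
        gts = [[(0, 1), (-1, -1)]] * 10
        cohort = make_cohort(gts)
        with pytest.raises(CohortError, match="all-missing"):
            lp.infer_window_tree(cohort, self._window(cohort), ["S1", "S2"])


class TestEnumerateTopologies:
    @pytest.mark.parametrize(
        "k, expected", [(3, 1), (4, 3), (5, 15), (6, 105), (7, 945)]
    )
    def test_catalog_size_is_double_factorial(self, k, expected):
        groups = [f"G{i}" for i in range(k)]
        catalog = lp.enumerate_topologies(groups)
        assert len(catalog) == expected
        # no duplicates: all split sets distinct
        assert len({e.splits for e in catalog.entries}) == expected

    def test_k_out_of_range_rejected(self):
        with pytest.raises(CohortError):
            lp.enumerate_topologies(["A", "B"])
        with pytest.raises(CohortError):
            lp.enumerate_topologies([f"G{i}" for i in range(8)])

    def test_newicks_parse_and_have_one_tip_per_group(self):
        catalog = lp.enumerate_topologies(["A", "B", "C", "D", "E"])
        for e in catalog.entries:
            t = tree_of(e.newick)
            assert sorted(x.name for x in t.tips()) == ["A", "B", "C", "D", "E"]


class TestWeightTopologies:
    def test_one_tip_per_group_gives_unit_weight(self):
        catalog = lp.enumerate_topologies(["A", "B", "C", "D"])
        tree = tree_of("((a1:1,b1:1):1,(c1:1,d1:1):1);")
        groups = {"a1": "A", "b1": "B", "c1": "C", "d1": "D"}
        w = lp.weight_topologies(tree, groups, catalog)
        assert w.sum() == pytest.approx(1.0)
        assert w.max() == pytest.approx(1.0)
        idx = int(np.argmax(w))
        assert catalog.entries[idx].splits == frozenset({frozenset({"C", "D"})})

    def test_concordant_monophyletic_groups(self):
        newick = (
            "(((a1:1,a2:1):1,a3:1):2,((b1:1,b2:1):1,b3:1):2,"
            "(((c1:1,c2:1):1,c3:1):2,((d1:1,d2:1):1,d3:1):2):1);"
        )
        tree = tree_of(newick)
        groups = {f"{g}{i}": g.upper() for g in "abcd" for i in (1, 2, 3)}
        catalog = lp.enumerate_topologies(["A", "B", "C", "D"])
        w = lp.weight_topologies(tree, groups, catalog)
        assert w.max() == pytest.approx(1.0)

    def test_matches_exhaustive_dendropy_oracle(self):
        rng = random.Random(99)
        catalog = lp.enumerate_topologies(["A", "B", "C", "D"])
        tips = [f"{g}{i}" for g in "abcd" for i in (1, 2, 3)]
        groups = {t: t[0].upper() for t in tips}
        for _ in range(6):
            newick = random_binary_newick(tips, rng)
            mine = lp.weight_topologies(tree_of(newick), groups, catalog)
            theirs = oracle_weights(newick, groups, catalog)
            np.testing.assert_allclose(mine, theirs, atol=1e-12)

    def test_five_group_oracle_agreement(self):
        rng = random.Random(7)
        catalog = lp.enumerate_topologies(["A", "B", "C", "D", "E"])
        tips = [f"{g}{i}" for g in "abcde" for i in (1, 2)]
        groups = {t: t[0].upper() for t in tips}
        newick = random_binary_newick(tips, rng)
        mine = lp.weight_topologies(tree_of(newick), groups, catalog)
        theirs = oracle_weights(newick, groups, catalog)
        np.testing.assert_allclose(mine, theirs, atol=1e-12)

    def test_invariant_under_group_preserving_relabeling(self):
        rng = random.Random(5)
        catalog = lp.enumerate_topologies(["A", "B", "C", "D"])
        tips = [f"{g}{i}" for g in "abcd" for i in (1, 2)]
        groups = {t: t[0].upper() for t in tips}
        newick = random_binary_newick(tips, rng)
        w1 = lp.weight_topologies(tree_of(newick), groups, catalog)
        # swap the names of two tips in the same group
        swapped = newick.replace("a1", "tmp").replace("a2", "a1").replace("tmp", "a2")
        w2 = lp.weight_topologies(tree_of(swapped), groups, catalog)
        np.testing.assert_allclose(w1, w2, atol=1e-12)

    def test_multifurcation_distributes_over_compatible_topologies(self):
        catalog = lp.enumerate_topologies(["A", "B", "C", "D"])
        star = tree_of("(a1:1,b1:1,c1:1,d1:1);")
        groups = {"a1": "A", "b1": "B", "c1": "C", "d1": "D"}
        w = lp.weight_topologies(star, groups, catalog)
        np.testing.assert_allclose(w, [1 / 3] * 3)

    def test_combination_cap_enforced(self):
        catalog = lp.enumerate_topologies(["A", "B", "C", "D"])
        tips = [f"{g}{i}" for g in "abcd" for i in range(3)]
        groups = {t: t[0].upper() for t in tips}
        newick = random_binary_newick(tips, random.Random(1))
        with pytest.raises(CohortError, match="cap"):
            lp.weight_topologies(tree_of(newick), groups, catalog, max_combinations=10)


class TestStratifyWeights:
    def _windows(self, rates):
        return [SnpWindow("chr1", 0, 99, i * 10_000, (i + 1) * 10_000, 100, r)
                for i, r in enumerate(rates)]

    def test_boundaries_assigned_to_medium(self):
        cfg = StratificationConfig()
        assert cfg.stratum_of(0.2) == "medium"
        assert cfg.stratum_of(2.0) == "medium"
        assert cfg.stratum_of(0.19) == "low"
        assert cfg.stratum_of(2.01) == "high"

    def test_single_stratum_partition(self):
        weights = np.array([[0.5, 0.5], [0.2, 0.8]])
        with pytest.warns(UserWarning, match="empty"):
            out = lp.stratify_weights(weights, self._windows([1.0, 1.0]))
        assert out["medium"].n_windows == 2
        assert out["low"].n_windows == 0 and out["low"].mean_weights is None

    def test_singleton_strata_return_their_vectors(self):
        weights = np.eye(3)
        out = lp.stratify_weights(weights, self._windows([0.1, 1.0, 3.0]))
        np.testing.assert_allclose(out["low"].mean_weights, [1, 0, 0])
        np.testing.assert_allclose(out["medium"].mean_weights, [0, 1, 0])
        np.testing.assert_allclose(out["high"].mean_weights, [0, 0, 1])

    def test_matches_group_by_oracle(self):
        rng = np.random.default_rng(11)
        rates = rng.uniform(0, 4, size=30)
        weights = rng.dirichlet(np.ones(5), size=30)
        out = lp.stratify_weights(weights, self._windows(rates))
        cfg = StratificationConfig()
        for name in ("low", "medium", "high"):
            mask = np.array([cfg.stratum_of(r) == name for r in rates])
            if mask.any():
                np.testing.assert_allclose(out[name].mean_weights, weights[mask].mean(axis=0))
                assert out[name].n_windows == mask.sum()

    def test_window_weights_sum_to_one_on_simulated_data(self, small_wolf_sim):
        c, pm, rmap = small_wolf_sim.cohort, small_wolf_sim.popmap, small_wolf_sim.recomb_map
        catalog = lp.enumerate_topologies(["Indian", "SWAsia", "Central", "Outgroup1"])
        windows = lp.make_snp_windows(c, rmap, 100)[:20]
        samples = ["Indian_1", "SWAsia_1", "Central_1", "Outgroup1_1"]
        w = lp.window_weights(c, pm, windows, catalog, samples)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)
        assert (w >= 0).all()
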