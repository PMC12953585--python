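"""Folded joint SFS, simulated expectations, composite likelihood, AIC."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lupus_popgen as lp
from lupus_popgen.cohort import CohortError
from lupus_popgen.sfsfit import canonical_polymorphic_mask, fold_array

from conftest import make_cohort

sizes_strategy = st.lists(st.integers(2, 8), min_size=1, max_size=3).map(tuple)


class TestFolding:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(sizes_strategy, st.randoms(use_true_random=False))
    def test_fold_cell_is_idempotent_and_pairs_complements(self, sizes, rnd):
        cell = tuple(rnd.randint(0, n) for n in sizes)
        comp = tuple(n - c for c, n in zip(cell, sizes))
        canon = lp.fold_cell(cell, sizes)
        assert lp.fold_cell(canon, sizes) == canon
        assert lp.fold_cell(comp, sizes) == canon
        assert sum(canon) <= sum(sizes) - sum(canon) or canon == min(cell, comp)

    def test_fold_array_conserves_mass(self):
        rng = np.random.default_rng(2)
        raw = rng.integers(0, 20, size=(5, 7)).astype(float)
        folded, mono = fold_array(raw)
        assert folded.sum() + mono == pytest.approx(raw.sum())
        sizes = (4, 6)
        # no mass outside canonical cells, none in the zero cell
        mask = canonical_polymorphic_mask(sizes)
        assert folded[~mask].sum() == 0.0

    def test_half_frequency_ties_key_lexicographically_smaller(self):
        assert lp.fold_cell((2, 1), (4, 2)) == (2, 1)
        assert lp.fold_cell((3, 0), (4, 2)) == (1, 2)  # complement is smaller


class TestBuildFoldedSfs:
    def _cohort_with_missingness(self):
        rng = np.random.default_rng(8)
        gts = []
        for i in range(60):
            site = [tuple(rng.integers(0, 2, 2)) for _ in range(6)]
            if i % 5 == 0:
                site[rng.integers(0, 6)] = (-1, -1)
            gts.append(site)
        positions = list(range(0, 60 * 40_000, 40_000))  # spans 2.4 Mb
        return make_cohort(gts, positions=positions)

    def _popmap(self):
        return lp.PopulationMap(
            {"S1": "A", "S2": "A", "S3": "B", "S4": "B", "S5": "C", "S6": "C"}
        )

    def test_retained_snps_match_per_block_oracle(self):
        cohort, pm = self._cohort_with_missingness(), self._popmap()
        obs, _ = lp.build_folded_sfs(cohort, pm, ["A", "B", "C"], [1, 1, 1],
                                     block_bp=1_000_000, seed=0)
        # brute-force re-selection: per block, per pop, the least-missing sample
        total = 0
        for b in range(3):
            in_b = (cohort.positions >= b * 1_000_000) & (cohort.positions < (b + 1) * 1_000_000)
            chosen = []
            for pop in ("A", "B", "C"):
                members = [cohort.sample_index(s) for s in pm.samples_of(pop)]
                miss = [cohort.missing_mask()[in_b, j].sum() for j in members]
                chosen.append(members[int(np.argmin(miss))])
            rows = np.flatnonzero(in_b)
            total += sum(
                1 for r in rows if not (cohort.gt[r, chosen, :] < 0).any()
            )
        assert obs.n_polymorphic + obs.monomorphic == total

    def test_monomorphic_subsample_sites_counted_separately(self):
        gts = [[(0, 0), (0, 0), (0, 0)], [(1, 1), (1, 1), (1, 1)], [(0, 1), (0, 0), (0, 0)]]
        cohort = make_cohort(gts)
        pm = lp.PopulationMap({"S1": "A", "S2": "B", "S3": "C"})
        obs, _ = lp.build_folded_sfs(cohort, pm, ["A", "B", "C"], [1, 1, 1],
                                     block_bp=10_000, seed=0)
        assert obs.monomorphic == 2  # all-ref and all-alt fold to the zero cell
        assert obs.n_polymorphic == 1

    def test_full_panel_subsampling_is_identity(self, panmictic_sim):
        c = panmictic_sim.cohort.take_sites(np.arange(400))
        pm = panmictic_sim.popmap
        obs, _ = lp.build_folded_sfs(c, pm, ["Pop"], [12], block_bp=10**9, seed=0)
        # direct whole-cohort folded SFS
        alt, called = c.allele_counts(np.arange(c.n_samples))
        direct = np.zeros(25)
        mono = 0
        for a in alt:
            canon = lp.fold_cell((int(a),), (24,))
            if sum(canon) == 0:
                mono += 1
            else:
                direct[canon[0]] += 1
        np.testing.assert_allclose(obs.counts, direct)
        assert obs.monomorphic == mono

    def test_text_round_trip(self, tmp_path):
        counts = np.zeros((3, 3))
        counts[1, 0] = 4
        counts[0, 1] = 2
        sfs = lp.FoldedSFS((2, 2), counts, monomorphic=7, provenance="all_snps")
        path = tmp_path / "sfs.txt"
        sfs.to_text(str(path))
        back = lp.FoldedSFS.from_text(str(path))
        np.testing.assert_allclose(back.counts, sfs.counts)
        assert back.monomorphic == 7 and back.sizes == (2, 2)

    def test_undersized_population_rejected(self, panmictic_sim):
        with pytest.raises(CohortError, match="samples"):
            lp.build_folded_sfs(
                panmictic_sim.cohort, panmictic_sim.popmap, ["Pop"], [40],
                block_bp=10**6, seed=0,
            )


class TestExpectedSfs:
    def test_deterministic_given_seed(self):
        spec = lp.single_population_spec(5_000, 4)
        a = lp.expected_sfs(spec, {}, n_loci=200, seed=3, mode="branch")
        b = lp.expected_sfs(spec, {}, n_loci=200, seed=3, mode="branch")
        np.testing.assert_array_equal(a, b)

    def test_probabilities_normalized_with_pseudocounts(self):
        spec = lp.single_population_spec(5_000, 4)
        p = lp.expected_sfs(spec, {}, n_loci=100, seed=1, mode="site")
        mask = canonical_polymorphic_mask((8,))
        assert p[mask].sum() == pytest.approx(1.0)
        assert (p[mask] > 0).all()  # pseudocount fills empty cells

    def test_vanishing_admixture_approaches_bifurcating_model(self):
        sizes = {"Indian": 2, "SWAsia": 2, "Central": 2}
        free_a = {"T_SPLIT_SW": 2341.0}
        free_b = {"T_SPLIT_SW": 2341.0, "ALPHA": 0.0, "T_INTRO": 1000.0}
        spec_b = lp.wolf_model_spec("B", sizes)
        spec_b.free["ALPHA"] = (0.0, 0.6)  # admit the degenerate nested case
        pa = lp.expected_sfs(lp.wolf_model_spec("A", sizes), free_a, 30_000, seed=9, mode="branch")
        pb = lp.expected_sfs(spec_b, free_b, 30_000, seed=9, mode="branch")
        assert 0.5 * np.abs(pa - pb).sum() < 0.02  # total-variation distance

    def test_invalid_parameter_combination_rejected(self):
        spec = lp.wolf_model_spec("B")
        with pytest.raises(CohortError):
            lp.expected_sfs(spec, {"T_SPLIT_SW": 1000.0, "ALPHA": 0.1, "T_INTRO": 5000.0},
                            n_loci=10, seed=1)


class TestCompositeLoglik:
    def _sfs(self, counts):
        arr = np.zeros(5)
        arr[1 : 1 + len(counts)] = counts
        return lp.FoldedSFS((4,), arr)

    def test_unit_probability_gives_zero(self):
        obs = self._sfs([3])
        p = np.zeros(5)
        p[1] = 1.0
        assert lp.composite_loglik(obs, p) == pytest.approx(0.0)

    def test_direct_formula(self):
        obs = self._sfs([2, 1])
        p = np.zeros(5)
        p[1], p[2] = 0.5, 0.5
        assert lp.composite_loglik(obs, p) == pytest.approx(3 * np.log(0.5))

    def test_matches_per_site_oracle(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 10, size=2).astype(float)
        probs = rng.dirichlet([1, 1])
        obs = self._sfs(counts)
        p = np.zeros(5)
        p[1], p[2] = probs
        expected = sum(
            np.log(p[i]) for i in (1, 2) for _ in range(int(obs.counts[i]))
        )
        assert lp.composite_loglik(obs, p) == pytest.approx(expected)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_additive_over_cell_partitions(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 8, size=4).astype(float)
        probs = rng.dirichlet(np.ones(4))
        obs = self._sfs(counts)
        p = np.zeros(5)
        p[1:5] = probs
        total = lp.composite_loglik(obs, p)
        parts = 0.0
        for i in range(1, 5):
            single = np.zeros(5)
            single[i] = obs.counts[i]
            parts += lp.composite_loglik(lp.FoldedSFS((4,), single), p)
        assert total == pytest.approx(parts)

    def test_zero_probability_at_occupied_cell_is_error(self):
        obs = self._sfs([1])
        with pytest.raises(CohortError, match="probability 0"):
            lp.composite_loglik(obs, np.zeros(5))


class TestFitAndCompare:
    def test_single_point_grid_returns_that_point(self):
        spec = lp.wolf_model_spec("A", {"Indian": 2, "SWAsia": 2, "Central": 2})
        counts, _ = lp.simulate_folded_counts(spec, {"T_SPLIT_SW": 2341.0}, 300, seed=2)
        obs = lp.FoldedSFS((4, 4, 4), counts)
        lo, hi = spec.free["T_SPLIT_SW"]
        spec.free["T_SPLIT_SW"] = (2000.0, 2000.0)
        fit = lp.fit_model(obs, spec, lp.SearchConfig(grid_points=1, nm_maxfev=0, n_loci=100),
                           seed=5)
        assert fit.params["T_SPLIT_SW"] == pytest.approx(2000.0)
        assert fit.k == 1
        assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.lnl_unlinked)

    def test_fit_deterministic_given_seed(self):
        spec = lp.wolf_model_spec("A", {"Indian": 2, "SWAsia": 2, "Central": 2})
        counts, _ = lp.simulate_folded_counts(spec, {"T_SPLIT_SW": 2341.0}, 300, seed=2)
        obs = lp.FoldedSFS((4, 4, 4), counts)
        cfg = lp.SearchConfig(grid_points=3, nm_maxfev=10, n_loci=150)
        f1 = lp.fit_model(obs, spec, cfg, seed=4)
        f2 = lp.fit_model(obs, spec, cfg, seed=4)
        assert f1.params == f2.params and f1.lnl_all == f2.lnl_all

    def test_equal_aic_gives_equal_weights(self):
        a = lp.FitResult("A", {}, -10, -10, 1, 22.0, 1, 1.0)
        b = lp.FitResult("B", {}, -10, -10, 1, 22.0, 1, 1.0)
        fits = lp.compare_models([a, b])
        assert fits[0].akaike_weight == pytest.approx(0.5)
        assert fits[1].delta_aic == pytest.approx(0.0)

    def test_two_point_aic_closed_form(self):
        a = lp.FitResult("A", {}, 0, -4.0, 1, 10.0, 1, 1.0)
        b = lp.FitResult("B", {}, 0, -4.0, 2, 12.0, 1, 1.0)
        fits = lp.compare_models([a, b])
        assert fits[0].delta_aic == 0.0 and fits[1].delta_aic == pytest.approx(2.0)
        assert fits[0].akaike_weight == pytest.approx(0.7311, abs=1e-4)
        assert fits[1].akaike_weight == pytest.approx(0.2689, abs=1e-4)

    def test_three_model_weights_sum_to_one(self):
        fits = [
            lp.FitResult(m, {}, 0, lnl, 1, 2 - 2 * lnl, 1, 1.0)
            for m, lnl in (("A", -5.0), ("B", -4.0), ("C", -7.0))
        ]
        out = lp.compare_models(fits)
        assert sum(f.akaike_weight for f in out) == pytest.approx(1.0)
        assert out[0].model_id == "B"

    def test_mismatched_data_provenance_rejected(self):
        a = lp.FitResult("A", {}, 0, -4.0, 1, 10.0, 1, data_signature=1.0)
        b = lp.FitResult("B", {}, 0, -4.0, 2, 12.0, 1, data_signature=2.0)
        with pytest.raises(CohortError, match="different observed data"):
            lp.compare_models([a, b])
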