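import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from f2map import binmap, simcross
from f2map.binmap import (
    Bin,
    average_interval,
    build_map,
    collapse_bins,
    estimate_rf,
    group_bins,
    kosambi,
    kosambi_inverse,
    map_statistics,
    order_bins,
    pairwise_linkages,
    segregation_filter,
    two_locus_probs,
)
from f2map.genotyping import SYM_AA, SYM_BB, SYM_H, SYM_MISS


def _loci(n, scaffold="sc01"):
    return pd.DataFrame({"scaffold": scaffold, "pos": np.arange(1, n + 1) * 1000})


class TestCollapse:
    def test_identical_adjacent_loci_one_bin(self):
        vec = np.array([[0, 1, 2], [0, 1, 2]], dtype=np.int8)
        bins = collapse_bins(vec, _loci(2))
        assert len(bins) == 1
        assert bins[0].n_markers == 2

    def test_single_progeny_difference_splits(self):
        vec = np.array([[0, 1, 2], [0, 1, 1]], dtype=np.int8)
        bins = collapse_bins(vec, _loci(2))
        assert len(bins) == 2

    def test_scaffold_boundary_splits(self):
        vec = np.zeros((4, 3), dtype=np.int8)
        loci = pd.DataFrame(
            {"scaffold": ["a", "a", "b", "b"], "pos": [1, 2, 1, 2]}
        )
        bins = collapse_bins(vec, loci)
        assert len(bins) == 2

    def test_bins_partition_loci(self):
        rng = np.random.default_rng(3)
        vec = rng.integers(0, 3, size=(50, 8)).astype(np.int8)
        bins = collapse_bins(vec, _loci(50))
        all_indices = np.concatenate([b.locus_indices for b in bins])
        assert sorted(all_indices) == list(range(50))
        assert sum(b.n_markers for b in bins) == 50

    def test_boundaries_match_crossover_intervals(self):
        """On error-free truth data, bin boundaries are exactly the
        inter-locus intervals where a crossover changes the state vector.

        The expected boundaries are derived from the recorded crossover
        events, not from the state matrix."""
        config = simcross.SimConfig(
            scaffolds=[simcross.Scaffold("chr1", 1_000_000, 80.0)],
            n_progeny=40,
            snp_density=1e-4,
            seed=77,
        )
        founders = simcross.simulate_founders(config)
        truth = simcross.simulate_f2(founders, config)
        bins = collapse_bins(truth.states, truth.loci)
        observed = {int(b.locus_indices[0]) for b in bins if b.locus_indices[0] != 0}

        # oracle: rebuild every genotype from the recorded crossover events
        # and gamete start haplotypes, never touching truth.states
        pos = truth.loci["pos"].to_numpy()
        rebuilt = np.zeros((len(pos), config.n_progeny), dtype=np.int8)
        for j, name in enumerate(truth.progeny):
            for gamete in (0, 1):
                bps = sorted(
                    bp for scaf, bp, g in truth.crossovers[name] if g == gamete
                )
                start = truth.gamete_starts[(name, "chr1", gamete)]
                hap = (start + np.searchsorted(bps, pos)) % 2
                rebuilt[:, j] += hap.astype(np.int8)
        np.testing.assert_array_equal(rebuilt, truth.states)
        expected = set((np.flatnonzero(np.any(rebuilt[1:] != rebuilt[:-1], axis=1)) + 1).tolist())
        assert observed == expected


class TestSegregation:
    def _bin(self, n_aa, n_h, n_bb, n_missing=0):
        vec = np.array(
            [SYM_AA] * n_aa + [SYM_H] * n_h + [SYM_BB] * n_bb + [SYM_MISS] * n_missing,
            dtype=np.int8,
        )
        return Bin(0, "sc01", 1, 1, np.array([0]), vec, n_aa, n_h, n_bb, n_missing)

    def test_exact_fit_retained(self):
        retained, _ = segregation_filter([self._bin(30, 60, 30)])
        assert len(retained) == 1
        assert retained[0].chi2 == 0.0

    def test_distorted_discarded(self):
        # direct formula: E=(30,60,30); 30^2/30 + 20^2/60 + 10^2/30 = 40.0
        b = self._bin(60, 40, 20)
        retained, report = segregation_filter([b])
        assert b.chi2 == pytest.approx(40.0)
        assert len(retained) == 0
        assert report["discarded_distorted"] == 1

    def test_moderate_deviation_retained(self):
        # E=(30,60,30); 25/30 + 100/60 + 25/30 = 3.333 < 5.99
        b = self._bin(25, 70, 25)
        retained, _ = segregation_filter([b])
        assert b.chi2 == pytest.approx(10.0 / 3.0)
        assert len(retained) == 1

    def test_all_missing_reported(self):
        _, report = segregation_filter([self._bin(0, 0, 0, 10)])
        assert report["discarded_all_missing"] == 1


def grid_search_rf(vec_a, vec_b):
    """Independent ML oracle: profile the multinomial likelihood on a grid."""
    mask = (vec_a <= 2) & (vec_b <= 2)
    counts = np.zeros((3, 3))
    np.add.at(counts, (vec_a[mask].astype(int), vec_b[mask].astype(int)), 1.0)
    grid = np.linspace(0.0, 0.5, 5001)
    best_r, best_ll = 0.25, -np.inf
    for r in grid:
        probs = np.clip(two_locus_probs(r), 1e-300, None)
        ll = (counts * np.log(probs)).sum()
        if ll > best_ll:
            best_r, best_ll = r, ll
    return best_r


class TestRecombination:
    def test_identical_vectors_r_zero(self):
        vec = np.array([0] * 12 + [1] * 26 + [2] * 12, dtype=np.int8)
        link = estimate_rf(vec, vec)
        assert link.r == pytest.approx(0.0, abs=1e-8)
        assert link.lod > 8

    def test_independent_bins_r_half(self):
        rng = np.random.default_rng(10)
        a = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=400).astype(np.int8)
        b = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=400).astype(np.int8)
        link = estimate_rf(a, b)
        assert link.r == pytest.approx(0.5, abs=0.05)
        assert link.lod < 1.0

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(4)
        for true_r in (0.05, 0.15, 0.3):
            probs = two_locus_probs(true_r).ravel()
            draws = rng.multinomial(150, probs)
            vec_a, vec_b = [], []
            for idx, n in enumerate(draws):
                vec_a += [idx // 3] * n
                vec_b += [idx % 3] * n
            vec_a = np.array(vec_a, dtype=np.int8)
            vec_b = np.array(vec_b, dtype=np.int8)
            link = estimate_rf(vec_a, vec_b)
            assert link.r == pytest.approx(grid_search_rf(vec_a, vec_b), abs=2e-4)

    def test_insufficient_overlap_flagged(self):
        a = np.array([0, 5, 5, 5], dtype=np.int8)
        b = np.array([5, 5, 5, 0], dtype=np.int8)
        link = estimate_rf(a, b)
        assert not link.informative

    def test_error_free_adjacent_rf_equals_count(self):
        # oracle equivalence: with fully informative vectors the MLE equals
        # the directly countable recombinant-gamete fraction
        config = simcross.SimConfig(
            scaffolds=[simcross.Scaffold("chr1", 1_000_000, 100.0)],
            n_progeny=80,
            snp_density=2e-5,
            seed=5,
        )
        founders = simcross.simulate_founders(config)
        truth = simcross.simulate_f2(founders, config)
        for k in range(len(truth.loci) - 1):
            link = estimate_rf(truth.states[k], truth.states[k + 1])
            oracle = grid_search_rf(truth.states[k], truth.states[k + 1])
            assert link.r == pytest.approx(oracle, abs=2e-4)

    def test_probs_sum_to_one(self):
        for r in (0.0, 0.1, 0.25, 0.5):
            assert two_locus_probs(r).sum() == pytest.approx(1.0)


class TestGrouping:
    def _chain_bins(self, n, r_adj, n_prog=100, seed=0):
        rng = np.random.default_rng(seed)
        vecs = [rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=n_prog).astype(np.int8)]
        gametes = None
        # simple chain: each vector derived from previous by per-gamete flips
        config = simcross.SimConfig(
            scaffolds=[simcross.Scaffold("c", 1_000_000, 100.0)],
            n_progeny=n_prog,
            snp_density=n / 1_000_000,
            seed=seed,
        )
        founders = simcross.simulate_founders(config)
        truth = simcross.simulate_f2(founders, config)
        bins = collapse_bins(truth.states, truth.loci)
        return bins

    def test_chain_connects(self):
        bins = self._chain_bins(8, 0.1)[:5]
        linkages = pairwise_linkages(bins)
        kept, _ = group_bins(bins, linkages, min_lod=3.0, max_rf=0.35, min_group_size=0)
        # adjacent bins on one simulated chromosome are tightly linked
        assert len(kept) >= 1

    def test_unlinked_clusters_split(self):
        rng = np.random.default_rng(2)
        vec1 = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=200).astype(np.int8)
        vec2 = rng.choice([0, 1, 2], p=[0.25, 0.5, 0.25], size=200).astype(np.int8)
        bins = [
            Bin(0, "a", 1, 1, np.array([0]), vec1),
            Bin(1, "a", 2, 2, np.array([1]), vec1.copy()),
            Bin(2, "b", 1, 1, np.array([2]), vec2),
            Bin(3, "b", 2, 2, np.array([3]), vec2.copy()),
        ]
        linkages = pairwise_linkages(bins)
        kept, _ = group_bins(bins, linkages, min_lod=8.0, max_rf=0.35, min_group_size=1)
        assert sorted(map(sorted, kept)) == [[0, 1], [2, 3]]

    def test_lod_threshold_semantics(self):
        from f2map.binmap import PairLinkage

        bins = [
            Bin(0, "a", 1, 1, np.array([0]), np.zeros(4, dtype=np.int8)),
            Bin(1, "a", 2, 2, np.array([1]), np.zeros(4, dtype=np.int8)),
        ]
        linkages = {(0, 1): PairLinkage(r=0.1, lod=7.9, n_informative=4)}
        kept, discarded = group_bins(bins, linkages, min_lod=8.0, max_rf=0.35, min_group_size=0)
        assert sorted(map(sorted, kept)) == [[0], [1]]

    def test_small_groups_discarded(self):
        bins = self._chain_bins(30, 0.05)
        linkages = pairwise_linkages(bins)
        kept, discarded = group_bins(
            bins, linkages, min_lod=3.0, max_rf=0.35, min_group_size=len(bins)
        )
        assert kept == []
        assert sum(len(d) for d in discarded) == len(bins)


def brute_force_order(members, linkages, lod_floor=3.0):
    """Exhaustive minimizer of the ordering stress (oracle for <= 7 bins)."""
    from f2map.binmap import _OrderScorer

    scorer = _OrderScorer(members, linkages, lod_floor)
    best = None
    for perm in itertools.permutations(members):
        if perm[0] > perm[-1]:
            continue  # orientation symmetry
        s = scorer.score(list(perm))
        if best is None or s < best[0] - 1e-12:
            best = (s, list(perm))
    return best


class TestOrdering:
    def _line_bins(self, n, n_prog=150, seed=1, length_cm=60.0):
        config = simcross.SimConfig(
            scaffolds=[simcross.Scaffold("c", 1_000_000, length_cm)],
            n_progeny=n_prog,
            snp_density=3e-5,
            seed=seed,
        )
        founders = simcross.simulate_founders(config)
        truth = simcross.simulate_f2(founders, config)
        bins = collapse_bins(truth.states, truth.loci)
        # keep bins spanning >=2 loci apart for distinct positions
        return bins[:n] if len(bins) >= n else bins

    def test_two_bins(self):
        bins = self._line_bins(2)
        linkages = pairwise_linkages(bins)
        order, positions = order_bins([b.bin_id for b in bins], linkages)
        assert len(order) == 2
        link = linkages[tuple(sorted(order))]
        assert positions[-1] == pytest.approx(kosambi(min(link.r, 0.499999)))

    def test_matches_brute_force(self):
        for seed in (1, 2, 3):
            bins = self._line_bins(6, seed=seed)
            members = [b.bin_id for b in bins]
            linkages = pairwise_linkages(bins)
            order, _ = order_bins(members, linkages)
            from f2map.binmap import _OrderScorer

            scorer = _OrderScorer(members, linkages, 3.0)
            best_score, best_order = brute_force_order(members, linkages)
            assert scorer.score(order) == pytest.approx(best_score, rel=1e-9)

    def test_recovers_true_order(self):
        bins = self._line_bins(25, n_prog=120, seed=9, length_cm=80.0)
        members = [b.bin_id for b in bins]
        linkages = pairwise_linkages(bins)
        order, _ = order_bins(members, linkages)
        from scipy.stats import kendalltau

        tau = kendalltau(order, sorted(order)).statistic
        assert abs(tau) >= 0.95


class TestKosambi:
    def test_zero(self):
        assert kosambi(0.0) == 0.0

    def test_closed_forms(self):
        assert kosambi(0.25) == pytest.approx(25 * math.log(3))
        assert round(kosambi(0.25), 2) == 27.47
        assert kosambi(0.49) == pytest.approx(25 * math.log(99))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            kosambi(0.5)
        with pytest.raises(ValueError):
            kosambi(-0.01)

    @given(st.floats(min_value=0.0, max_value=0.4999))
    def test_round_trip(self, r):
        assert kosambi_inverse(kosambi(r)) == pytest.approx(r, abs=1e-10)

    def test_monotone_convex(self):
        r = np.linspace(0, 0.49, 200)
        d = kosambi(r)
        assert (np.diff(d) > 0).all()
        assert (np.diff(d, 2) > -1e-9).all()


class TestStatistics:
    def test_published_arithmetic(self):
        assert average_interval(152.35, 94) == 1.62
        assert average_interval(245.85, 4482) == 0.05

    def test_map_statistics_table(self):
        config = simcross.SimConfig(
            scaffolds=[simcross.Scaffold("c", 1_000_000, 50.0)],
            n_progeny=80,
            snp_density=4e-5,
            seed=6,
        )
        founders = simcross.simulate_founders(config)
        truth = simcross.simulate_f2(founders, config)
        bins = collapse_bins(truth.states, truth.loci)
        retained, _ = segregation_filter(bins)
        gmap = build_map(retained, min_lod=3.0, min_group_size=1)
        stats = map_statistics(gmap)
        total = stats[stats["lg"] == "Total"].iloc[0]
        per_lg = stats[stats["lg"] != "Total"]
        assert total["bins"] == per_lg["bins"].sum()
        assert total["markers"] == per_lg["markers"].sum()
        # conservation: mapped markers equal the retained locus count
        mapped_bins = {b for g in gmap.groups for b in g.bin_ids}
        by_id = {b.bin_id: b for b in retained}
        assert total["markers"] == sum(by_id[b].n_markers for b in mapped_bins)
        for _, row in per_lg.iterrows():
            assert row["avg_bin_interval_cm"] == average_interval(
                row["length_cm"], row["bins"]
            )

    def test_reversal_invariance(self):
        from f2map.binmap import GeneticMap, LinkageGroup

        vec = np.zeros(4, dtype=np.int8)
        bins = [Bin(i, "c", i, i, np.array([i]), vec) for i in range(4)]
        positions = np.array([0.0, 3.0, 10.0, 12.0])
        fwd = GeneticMap(
            [LinkageGroup(1, [0, 1, 2, 3], positions)], bins
        )
        rev = GeneticMap(
            [LinkageGroup(1, [3, 2, 1, 0], positions[-1] - positions[::-1])], bins
        )
        sf = map_statistics(fwd)
        sr = map_statistics(rev)
        assert sf.iloc[0]["length_cm"] == sr.iloc[0]["length_cm"]
        assert sf.iloc[0]["gaps_gt_threshold"] == sr.iloc[0]["gaps_gt_threshold"]

    def test_single_bin_group(self):
        from f2map.binmap import GeneticMap, LinkageGroup

        vec = np.zeros(4, dtype=np.int8)
        bins = [Bin(0, "c", 1, 1, np.array([0]), vec)]
        gmap = GeneticMap([LinkageGroup(1, [0], np.zeros(1))], bins)
        stats = map_statistics(gmap)
        assert stats.iloc[0]["length_cm"] == 0.0
        assert stats.iloc[0]["gaps_gt_threshold"] == 0
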