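import itertools

import numpy as np
import pytest

from hapblocks import (
    PanelError,
    detect_blocks,
    enumerate_haplotypes,
    select_tag_snps,
    simulate_panel,
    summarize_blocks,
    aggregate_block_summary,
    wheat_like_scenario,
    with_tags,
)
from hapblocks.blocks import Block, _spine_blocks_from_dprime
from hapblocks.panel import CALL_MISSING

from conftest import make_panel


def oracle_spine_blocks(dp, threshold):
    """Brute-force reference: enumerate every valid interval by definition,
    then walk left to right taking the longest contiguous run of valid
    intervals from each start."""
    s = dp.shape[0]
    valid = set()
    for i in range(s):
        for j in range(i + 1, s):
            conditions = [dp[i, j]]
            for k in range(i + 1, j):
                conditions += [dp[i, k], dp[k, j]]
            if all(np.isfinite(c) and c > threshold for c in conditions):
                valid.add((i, j))
    out, i = [], 0
    while i < s - 1:
        j = i
        while (i, j + 1) in valid:
            j += 1
        if j > i:
            out.append((i, j))
            i = j + 1
        else:
            i += 1
    return out


def random_dprime(rng, s, p_nan=0.1):
    dp = rng.random((s, s))
    dp[rng.random((s, s)) < p_nan] = np.nan
    dp = np.triu(dp, 1)
    dp = dp + dp.T
    np.fill_diagonal(dp, np.nan)
    return dp


class TestSpineDetection:
    def test_two_snps_in_complete_ld_form_a_block(self):
        col = np.array([0, 0, 1, 1, 0, 1] * 2, dtype=np.int8)
        panel = make_panel(np.column_stack([col, col]))
        blocks = detect_blocks(panel, "1A")
        assert len(blocks) == 1
        assert blocks[0].snp_ids == ("s1", "s2")
        assert blocks[0].block_id == "HapB-1A-1"

    def test_weak_ld_pair_yields_no_block(self):
        # haplotype counts 40/10/10/40 -> D' = 0.6, below the 0.8 spine rule
        rows = [[0, 0]] * 40 + [[0, 1]] * 10 + [[1, 0]] * 10 + [[1, 1]] * 40
        panel = make_panel(np.array(rows, dtype=np.int8))
        assert detect_blocks(panel, "1A") == []

    def test_strict_inequality_at_threshold(self):
        dp = np.array([[np.nan, 0.8], [0.8, np.nan]])
        assert _spine_blocks_from_dprime(dp, 0.8) == []
        dp[0, 1] = dp[1, 0] = 0.8000001
        assert _spine_blocks_from_dprime(dp, 0.8) == [(0, 1)]

    def test_interior_rule_allows_weak_interior_pairs(self):
        # outer pair and outer-to-interior pairs strong, interior-interior weak
        dp = np.full((3, 3), np.nan)
        dp[0, 1] = dp[1, 0] = 0.9
        dp[1, 2] = dp[2, 1] = 0.9
        dp[0, 2] = dp[2, 0] = 0.95
        assert _spine_blocks_from_dprime(dp, 0.8) == [(0, 2)]

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            s = int(rng.integers(2, 9))
            dp = random_dprime(rng, s)
            assert _spine_blocks_from_dprime(dp, 0.8) == oracle_spine_blocks(dp, 0.8)

    def test_emitted_blocks_are_disjoint_ordered_and_revalidated(self, sim_panel):
        panel, _, _ = sim_panel
        from hapblocks.ld import dprime_matrix

        snp_ids, dp, _, _ = dprime_matrix(panel, "1A")
        blocks = detect_blocks(panel, "1A")
        last_end = -1
        for b in blocks:
            assert b.first > last_end
            last_end = b.last
            assert b.span_cm >= 0
            assert b.n_snps >= 2
            for k in range(b.first + 1, b.last):
                assert dp[b.first, k] > 0.8 and dp[k, b.last] > 0.8
            assert dp[b.first, b.last] > 0.8

    def test_missing_chromosome_raises(self, sim_panel):
        panel, _, _ = sim_panel
        with pytest.raises(PanelError):
            detect_blocks(panel, "9Z")

    def test_planted_block_boundaries_recovered(self):
        config = wheat_like_scenario(21, snps_per_chrom=40, n_landrace=150, n_modern=100)
        panel, _, truth = simulate_panel(config)
        kept = panel.filter_maf(0.05)
        kept_snps = set(kept.snp_ids)
        detected = {}
        for chrom in kept.chromosomes:
            for b in detect_blocks(kept, chrom):
                detected[frozenset(b.snp_ids)] = b
        scored = hits = 0
        for planted in truth["blocks"]:
            survivors = frozenset(s for s in planted["snp_ids"] if s in kept_snps)
            if len(survivors) < 2:
                continue
            scored += 1
            hits += survivors in detected
        assert scored >= 8
        assert hits / scored >= 0.9


class TestHaplotypes:
    def test_direct_count_and_ordering(self):
        calls = np.array([[0, 0], [0, 0], [1, 1]], dtype=np.int8)
        panel = make_panel(calls)
        block = Block("HapB-1A-1", "1A", 0, 1, ("s1", "s2"), 1.0)
        table = enumerate_haplotypes(panel, [block])["HapB-1A-1"]
        assert table.haplotypes == ("00", "11")
        np.testing.assert_allclose(table.frequencies, [2 / 3, 1 / 3])
        assert table.haplotype_label(2) == "HapB-1A-1-2"
        np.testing.assert_array_equal(table.assignments, [1, 1, 2])

    def test_monomorphic_block_single_haplotype(self):
        panel = make_panel(np.zeros((4, 2), np.int8))
        block = Block("HapB-1A-1", "1A", 0, 1, ("s1", "s2"), 0.0)
        table = enumerate_haplotypes(panel, [block])["HapB-1A-1"]
        assert table.n_haplotypes == 1
        assert table.frequencies[0] == pytest.approx(1.0)

    def test_missing_member_call_leaves_line_unassigned(self):
        calls = np.array([[0, 0], [0, CALL_MISSING], [1, 1]], dtype=np.int8)
        panel = make_panel(calls)
        block = Block("HapB-1A-1", "1A", 0, 1, ("s1", "s2"), 1.0)
        table = enumerate_haplotypes(panel, [block])["HapB-1A-1"]
        assert table.n_haplotypes == 2
        assert table.assignments[1] == 0
        assert table.frequencies.sum() == pytest.approx(1.0)

    def test_frequency_ties_broken_lexicographically(self):
        calls = np.array([[0, 0], [1, 1]], dtype=np.int8)
        panel = make_panel(calls)
        block = Block("HapB-1A-1", "1A", 0, 1, ("s1", "s2"), 1.0)
        table = enumerate_haplotypes(panel, [block])["HapB-1A-1"]
        assert table.haplotypes == ("00", "11")


class TestTagSnps:
    def _table(self, haplotypes, freqs):
        from hapblocks.blocks import BlockHaplotypes

        n = len(haplotypes[0])
        block = Block("HapB-1A-1", "1A", 0, n - 1, tuple(f"s{i+1}" for i in range(n)), 1.0)
        table = BlockHaplotypes(
            "HapB-1A-1", tuple(haplotypes), np.array(freqs), np.array([]), 100
        )
        return table, block

    def test_single_discriminating_snp_suffices(self):
        table, block = self._table(["000", "010"], [0.6, 0.4])
        assert select_tag_snps(table, block) == ("s2",)

    def test_full_factorial_needs_both_snps(self):
        table, block = self._table(["00", "01", "10", "11"], [0.25] * 4)
        assert set(select_tag_snps(table, block)) == {"s1", "s2"}

    def test_rare_haplotypes_ignored(self):
        table, block = self._table(["000", "100", "001"], [0.55, 0.42, 0.03])
        assert select_tag_snps(table, block) == ("s1",)

    def test_fewer_than_two_common_haplotypes_gives_empty_set(self):
        table, block = self._table(["000", "111"], [0.97, 0.03])
        assert select_tag_snps(table, block) == ()

    def test_greedy_matches_minimal_set_cover_on_constructed_block(self):
        haps = ["".join(bits) for bits in itertools.product("01", repeat=3)]
        table, block = self._table(haps, [1 / 8] * 8)
        tags = select_tag_snps(table, block)

        def distinguishes(subset):
            seen = {tuple(h[s] for s in subset) for h in haps}
            return len(seen) == len(haps)

        minimal = min(
            (
                size
                for size in range(1, 4)
                for subset in itertools.combinations(range(3), size)
                if distinguishes(subset)
            ),
        )
        assert len(tags) == minimal == 3


class TestSummaries:
    def test_single_block_chromosome_summary(self, sim_panel):
        panel, _, _ = sim_panel
        blocks = detect_blocks(panel, "1A")[:1]
        haps = enumerate_haplotypes(panel, blocks)
        blocks = with_tags(panel, blocks, haps)
        table = summarize_blocks({"1A": blocks}, haps, panel)
        row = table.iloc[0]
        b = blocks[0]
        assert row["n_blocks"] == 1
        assert row["mean_span_cm"] == pytest.approx(b.span_cm)
        assert row["snps_in_blocks"] == b.n_snps
        assert row["total_haplotypes"] == haps[b.block_id].n_haplotypes

    def test_aggregate_weighted_vs_unweighted_means(self):
        import pandas as pd

        per_chrom = pd.DataFrame(
            {
                "chrom": ["1A", "1B"],
                "total_snps": [100, 100],
                "snps_in_blocks": [90, 80],
                "tag_snps": [50, 40],
                "n_blocks": [10, 30],
                "mean_span_cm": [2.0, 1.0],
                "total_haplotypes": [40, 120],
            }
        )
        agg = aggregate_block_summary(per_chrom)
        assert agg["total_blocks"] == 40
        assert agg["mean_span_cm_unweighted"] == pytest.approx(1.5)
        assert agg["mean_span_cm_weighted"] == pytest.approx((20 + 30) / 40)
        assert agg["per_genome"]["A"]["total_blocks"] == 10
        assert agg["mean_haplotypes_weighted"] == pytest.approx(4.0)
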