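"""Anchor chaining, the permutation null, and hit-rank labelling."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyretain.collinearity import (
    Anchor,
    CollinearBlock,
    CollinearityParams,
    best_chain_score,
    block_pvalue,
    chain_anchors,
    colinear_gene_set,
    rank_hit_classes,
)


def _anchors(pairs):
    return [Anchor(f"a{ra}", f"b{rb}", ra, rb) for ra, rb in pairs]


class TestChaining:
    def test_perfect_diagonal_is_one_same_block(self):
        blocks = chain_anchors(_anchors([(i, i) for i in range(5)]))
        assert len(blocks) == 1
        assert blocks[0].orientation == "same"
        assert blocks[0].score == 5

    def test_gap_over_fifty_breaks_the_chain(self):
        # two anchors 51 intervening genes apart cannot be chained, and each
        # fragment alone is below min_anchors
        blocks = chain_anchors(_anchors([(0, 0), (52, 52)]))
        assert blocks == []

    def test_antidiagonal_is_reverse_orientation(self):
        blocks = chain_anchors(_anchors([(i, 9 - i) for i in range(5)]))
        assert len(blocks) == 1
        assert blocks[0].orientation == "reverse"

    def test_gap_at_exactly_fifty_is_allowed(self):
        params = CollinearityParams(min_anchors=2)
        blocks = chain_anchors(_anchors([(0, 0), (51, 51)]), params)
        assert len(blocks) == 1

    def test_relabeling_gene_ids_changes_nothing(self):
        pairs = [(0, 3), (2, 4), (5, 9), (6, 2), (8, 11)]
        params = CollinearityParams(min_anchors=2, max_gap=10)
        b1 = chain_anchors(_anchors(pairs), params)
        renamed = [Anchor(f"X{a.rank_a}", f"Y{a.rank_b}", a.rank_a, a.rank_b) for a in _anchors(pairs)]
        b2 = chain_anchors(renamed, params)
        assert [[(a.rank_a, a.rank_b) for a in b.anchors] for b in b1] == [
            [(a.rank_a, a.rank_b) for a in b.anchors] for b in b2
        ]

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        pairs=st.sets(
            st.tuples(st.integers(0, 15), st.integers(0, 15)), min_size=1, max_size=10
        ),
        max_gap=st.sampled_from([1, 3, 50]),
        min_anchors=st.sampled_from([2, 3]),
    )
    def test_matches_bruteforce_on_small_instances(
        self, chain_oracle, pairs, max_gap, min_anchors
    ):
        anchors = _anchors(sorted(pairs))
        params = CollinearityParams(max_gap=max_gap, min_anchors=min_anchors)
        got = [
            [(a.rank_a, a.rank_b) for a in b.anchors]
            for b in chain_anchors(anchors, params)
        ]
        expected = [
            [(a.rank_a, a.rank_b) for a in chain]
            for chain in chain_oracle(anchors, max_gap, min_anchors)
        ]
        assert got == expected


class TestPValue:
    def test_bounds_of_add_one_estimator(self):
        block = CollinearBlock("c1", "c2", "same", _anchors([(i, i) for i in range(5)]), 5)
        params = CollinearityParams(n_permutations=49, seed=1)
        p = block_pvalue(block, 8, 60, 60, params)
        assert 1 / 50 <= p <= 1.0

    def test_long_diagonal_on_large_grid_is_minimal(self):
        anchors = _anchors([(i, i) for i in range(20)])
        block = CollinearBlock("c1", "c2", "same", anchors, 20)
        params = CollinearityParams(n_permutations=200, seed=0)
        p = block_pvalue(block, 20, 500, 500, params)
        assert p == pytest.approx(1 / 201)

    def test_p_matches_null_exceedance_at_matched_density(self):
        # calibration: for a block scored at the null median, the permutation
        # p must match the independently simulated exceedance probability
        rng = np.random.default_rng(5)
        scores = np.array(
            [
                best_chain_score(
                    rng.integers(0, 100, 30), rng.integers(0, 100, 30), 50
                )
                for _ in range(400)
            ]
        )
        median_score = int(np.median(scores))
        exceedance = float((scores >= median_score).mean())
        block = CollinearBlock("c1", "c2", "same", _anchors([(0, 0)]), median_score)
        params = CollinearityParams(n_permutations=400, seed=7)
        p = block_pvalue(block, 30, 100, 100, params)
        assert p == pytest.approx(exceedance, abs=0.1)
        assert 0.05 < p < 0.95  # a typical score is far from significance

    def test_deterministic_per_seed(self):
        block = CollinearBlock("c1", "c2", "same", _anchors([(i, i) for i in range(6)]), 6)
        params = CollinearityParams(n_permutations=99, seed=11)
        assert block_pvalue(block, 12, 80, 80, params) == block_pvalue(
            block, 12, 80, 80, params
        )

    def test_bad_lengths_rejected(self):
        block = CollinearBlock("c1", "c2", "same", _anchors([(0, 0)]), 1)
        with pytest.raises(ValueError):
            block_pvalue(block, 3, 0, 10)


class TestColinearGeneSet:
    def test_empty_without_significant_blocks(self):
        b = CollinearBlock("c1", "c2", "same", _anchors([(0, 0)]), 1, p_value=0.5)
        assert colinear_gene_set([b], 0.05) == set()

    def test_five_anchor_block_gives_ten_genes(self):
        b = CollinearBlock(
            "c1", "c2", "same", _anchors([(i, i) for i in range(5)]), 5, p_value=0.001
        )
        assert len(colinear_gene_set([b], 0.05)) == 10

    def test_gene_in_two_blocks_counted_once(self):
        b1 = CollinearBlock("c1", "c2", "same", [Anchor("g", "h", 0, 0)], 1, p_value=0.001)
        b2 = CollinearBlock("c1", "c3", "same", [Anchor("g", "k", 0, 5)], 1, p_value=0.001)
        assert colinear_gene_set([b1, b2], 0.05) == {"g", "h", "k"}


class TestRankHitClasses:
    def test_single_hit_is_best(self, sim_row):
        assert rank_hit_classes([sim_row("q", "s")]) == {("q", "s"): "best"}

    def test_three_hits_ordered_by_evalue(self, sim_row):
        rows = [
            sim_row("q", "s1", evalue=1e-30),
            sim_row("q", "s2", evalue=1e-20),
            sim_row("q", "s3", evalue=1e-10),
        ]
        labels = rank_hit_classes(rows)
        assert labels == {
            ("q", "s1"): "best",
            ("q", "s2"): "second",
            ("q", "s3"): "other",
        }

    def test_equal_evalues_broken_by_bitscore(self, sim_row):
        rows = [
            sim_row("q", "s1", evalue=1e-20, bitscore=50),
            sim_row("q", "s2", evalue=1e-20, bitscore=200),
        ]
        labels = rank_hit_classes(rows)
        assert labels[("q", "s2")] == "best"
        assert labels[("q", "s1")] == "second"
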