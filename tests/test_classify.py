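"""Five-way duplication typing: precedence rules and summaries."""

from __future__ import annotations

import pytest

from polyretain.classify import (
    ClassifierParams,
    classify_duplicates,
    summarize_types,
)
from polyretain.collinearity import Anchor, CollinearBlock
from polyretain.io import GeneRecord, assign_ranks


def _genes(spec):
    """spec: list of (gene_id, chromosome, rank_position)."""
    return assign_ranks(
        [
            GeneRecord(g, c, pos * 1000 + 1, pos * 1000 + 600)
            for g, c, pos in spec
        ]
    )


def _block(pairs, p=0.001):
    anchors = [Anchor(a, b, i, i) for i, (a, b) in enumerate(pairs)]
    return CollinearBlock("c1", "c2", "same", anchors, len(anchors), p_value=p)


class TestPrecedence:
    def test_gene_without_hits_is_singleton(self, sim_row):
        genes = _genes([("g1", "c1", 0), ("g2", "c1", 1)])
        out = classify_duplicates(genes, [], [])
        assert out == {"g1": "singleton", "g2": "singleton"}

    def test_adjacent_homologs_are_tandem(self, sim_row):
        genes = _genes([("g1", "c1", 7), ("g2", "c1", 8)])
        out = classify_duplicates(genes, [sim_row("g1", "g2")], [])
        assert out == {"g1": "tandem", "g2": "tandem"}

    def test_four_intervening_genes_are_proximal(self, sim_row):
        spec = [(f"f{i}", "c1", i) for i in range(8, 12)]
        genes = _genes([("g1", "c1", 7), ("g2", "c1", 12)] + spec)
        out = classify_duplicates(genes, [sim_row("g1", "g2")], [])
        assert out["g1"] == "proximal"
        assert out["g2"] == "proximal"

    def test_block_membership_beats_adjacency(self, sim_row):
        genes = _genes([("g1", "c1", 0), ("g2", "c1", 1), ("h1", "c2", 0)])
        blocks = [_block([("g1", "h1")])]
        out = classify_duplicates(genes, [sim_row("g1", "g2"), sim_row("g1", "h1")], blocks)
        assert out["g1"] == "wgd"
        assert out["g2"] == "tandem"

    def test_distant_homolog_is_dispersed(self, sim_row):
        genes = _genes([("g1", "c1", 0), ("g2", "c2", 40)])
        out = classify_duplicates(genes, [sim_row("g1", "g2")], [])
        assert out == {"g1": "dispersed", "g2": "dispersed"}

    def test_unknown_anchor_gene_is_an_error(self, sim_row):
        genes = _genes([("g1", "c1", 0)])
        with pytest.raises(KeyError, match="ghost"):
            classify_duplicates(genes, [sim_row("g1", "ghost")], [])

    def test_twenty_gene_toy_matches_hand_worked_table(self, sim_row):
        # chromosome c1: t1 t2 (adjacent) . p1 .... p2 (4 intervening) rest
        # chromosome c2: w1' anchors a 5-gene significant block with c1 w1-w5
        spec = (
            [("t1", "c1", 0), ("t2", "c1", 1), ("p1", "c1", 3), ("p2", "c1", 8)]
            + [(f"f{i}", "c1", 3 + i) for i in range(1, 5)]  # the 4 intervening genes
            + [(f"w{i}", "c1", 10 + i) for i in range(1, 6)]
            + [(f"v{i}", "c2", i) for i in range(1, 6)]
            + [("d1", "c1", 20), ("d2", "c2", 20), ("s1", "c1", 21), ("s2", "c2", 21)]
            + [(f"x{i}", "c1", 30 + i) for i in range(2)]
        )
        genes = _genes(spec)
        hits = (
            [sim_row("t1", "t2"), sim_row("p1", "p2"), sim_row("d1", "d2")]
            + [sim_row(f"w{i}", f"v{i}") for i in range(1, 6)]
        )
        blocks = [_block([(f"w{i}", f"v{i}") for i in range(1, 6)])]
        out = classify_duplicates(genes, hits, blocks)
        expected = {
            "t1": "tandem", "t2": "tandem",
            "p1": "proximal", "p2": "proximal",
            "d1": "dispersed", "d2": "dispersed",
            "s1": "singleton", "s2": "singleton",
            "x0": "singleton", "x1": "singleton",
        }
        expected.update({f"f{i}": "singleton" for i in range(1, 5)})
        expected.update({f"w{i}": "wgd" for i in range(1, 6)})
        expected.update({f"v{i}": "wgd" for i in range(1, 6)})
        assert out == expected

    def test_partition_property(self, sim_row):
        genes = _genes([(f"g{i}", "c1", i) for i in range(10)])
        out = classify_duplicates(genes, [sim_row("g0", "g5")], [])
        assert set(out) == {g.gene_id for g in genes}
        assert all(v in ("singleton", "dispersed", "proximal", "tandem", "wgd") for v in out.values())


class TestSummary:
    def test_published_style_counts_round_to_expected_percentages(self):
        type_map = (
            {f"s{i}": "singleton" for i in range(5)}
            | {f"d{i}": "dispersed" for i in range(42)}
            | {f"p{i}": "proximal" for i in range(3)}
            | {f"t{i}": "tandem" for i in range(17)}
            | {f"w{i}": "wgd" for i in range(353)}
        )
        summary = summarize_types(type_map, type_map.keys())
        assert summary.counts == {
            "singleton": 5, "dispersed": 42, "proximal": 3, "tandem": 17, "wgd": 353
        }
        assert summary.percents == {
            "singleton": "1.19",
            "dispersed": "10.00",
            "proximal": "0.71",
            "tandem": "4.05",
            "wgd": "84.05",
        }

    def test_single_gene_universe(self):
        s = summarize_types({"g": "singleton"}, ["g"])
        assert s.percents["singleton"] == "100.00"

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            summarize_types({}, [])

    def test_bad_window_params_rejected(self):
        with pytest.raises(ValueError):
            ClassifierParams(tandem_max_gap=10, proximal_max_gap=5)
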