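"""Family library construction, membership thresholds, anchors, RBH."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyretain.homology import (
    FamilyLibrary,
    FamilyThresholds,
    build_library,
    filter_anchors,
    identify_family_members,
    rbh_orthologs,
)


class TestBuildLibrary:
    def test_top_ranked_hit_added(self, sim_row):
        hits = [
            sim_row("s1", "r1", evalue=1e-12),
            sim_row("s1", "r2", evalue=1e-20),
        ]
        lib = build_library(["s1"], hits)
        assert lib.augmented_ids == {"s1", "r2"}

    def test_seed_with_no_passing_hit_unchanged(self, sim_row):
        lib = build_library(["s1"], [sim_row("s1", "r1", evalue=1e-4)])
        assert lib.augmented_ids == {"s1"}

    def test_shared_subject_added_once(self, sim_row):
        hits = [sim_row("s1", "r1"), sim_row("s2", "r1")]
        lib = build_library(["s1", "s2"], hits)
        assert lib.augmented_ids == {"s1", "s2", "r1"}

    def test_seed_subset_invariant(self):
        with pytest.raises(ValueError):
            FamilyLibrary(frozenset({"a"}), frozenset({"b"}))


class TestFamilyMembers:
    @pytest.mark.parametrize(
        "evalue,identity,expected",
        [
            (1e-12, 75.0, True),  # passes both strict thresholds
            (1e-5, 90.0, False),  # fails the E-value bound
            (1e-20, 60.0, False),  # identity exactly 60 fails strict >
        ],
    )
    def test_threshold_gates(self, sim_row, evalue, identity, expected):
        lib = FamilyLibrary(frozenset({"s1"}), frozenset({"s1"}))
        members = identify_family_members(
            lib, [sim_row("s1", "x", identity=identity, evalue=evalue)]
        )
        assert ("x" in members) is expected

    def test_self_hits_ignored(self, sim_row):
        lib = FamilyLibrary(frozenset({"s1"}), frozenset({"s1"}))
        assert identify_family_members(lib, [sim_row("s1", "s1")]) == set()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        evalue_max=st.floats(1e-30, 1e-5),
        identity_min=st.floats(0, 99),
        hits=st.lists(
            st.tuples(st.floats(1e-40, 1), st.floats(0, 100)), max_size=15
        ),
    )
    def test_loosening_thresholds_is_monotone(self, sim_row, evalue_max, identity_min, hits):
        lib = FamilyLibrary(frozenset({"s"}), frozenset({"s"}))
        rows = [
            sim_row("s", f"x{i}", identity=ident, evalue=ev)
            for i, (ev, ident) in enumerate(hits)
        ]
        strict = identify_family_members(
            lib, rows, FamilyThresholds(evalue_max, identity_min)
        )
        loose = identify_family_members(
            lib, rows, FamilyThresholds(evalue_max * 10, identity_min / 2)
        )
        assert strict <= loose


class TestFilterAnchors:
    def test_top_five_survive(self, sim_row):
        hits = [sim_row("q", f"s{i}", evalue=10 ** -(20 + i)) for i in range(8)]
        kept = filter_anchors(hits)
        assert len(kept) == 5
        assert {r.subject_id for r in kept} == {"s3", "s4", "s5", "s6", "s7"}

    def test_failing_query_contributes_nothing(self, sim_row):
        assert filter_anchors([sim_row("q", "s", evalue=1e-3)]) == []

    def test_self_hit_never_counted(self, sim_row):
        hits = [sim_row("q", "q", evalue=0.0)] + [
            sim_row("q", f"s{i}", evalue=1e-10) for i in range(5)
        ]
        kept = filter_anchors(hits)
        assert len(kept) == 5
        assert all(not r.is_self_hit for r in kept)

    def test_output_bounded_by_topk_times_queries(self, sim_row):
        hits = [
            sim_row(f"q{j}", f"s{i}", evalue=1e-12) for j in range(3) for i in range(9)
        ]
        assert len(filter_anchors(hits, top_k=5)) <= 5 * 3


class TestRBH:
    def test_symmetric_best_hits_pair(self, sim_row):
        rbh, _ = rbh_orthologs([sim_row("a", "b")], [sim_row("b", "a")])
        assert rbh == {"a": "b"}

    def test_asymmetric_best_hits_rejected(self, sim_row):
        rbh, _ = rbh_orthologs(
            [sim_row("a", "b", bitscore=100)],
            [sim_row("b", "a2", bitscore=90), sim_row("b", "a", bitscore=50)],
        )
        assert rbh == {}

    def test_three_by_three_matches_hand_enumeration(self, sim_row):
        # bitscores chosen so a1<->b1 and a3<->b3 are reciprocal best while
        # a2's best (b1) prefers a1; co-orthologs within 0.9x of the best
        ab = [
            sim_row("a1", "b1", evalue=1e-30, bitscore=300),
            sim_row("a1", "b2", evalue=1e-20, bitscore=280),
            sim_row("a2", "b1", evalue=1e-25, bitscore=250),
            sim_row("a2", "b3", evalue=1e-10, bitscore=100),
            sim_row("a3", "b3", evalue=1e-28, bitscore=290),
            sim_row("a3", "b1", evalue=1e-5, bitscore=50),
        ]
        ba = [
            sim_row("b1", "a1", evalue=1e-30, bitscore=300),
            sim_row("b1", "a2", evalue=1e-25, bitscore=250),
            sim_row("b2", "a1", evalue=1e-20, bitscore=280),
            sim_row("b3", "a3", evalue=1e-28, bitscore=290),
            sim_row("b3", "a2", evalue=1e-10, bitscore=100),
        ]
        rbh, co = rbh_orthologs(ab, ba)
        # a2's best is b1 but b1's best is a1, so only two reciprocal pairs
        assert rbh == {"a1": "b1", "a3": "b3"}
        assert co["a1"] == {"b1", "b2"}  # 280 >= 0.9*300
        assert co["a2"] == {"b1"}
        assert co["a3"] == {"b3"}
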