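"""Generative model: bookkeeping, determinism, retention bias, Ks peaks."""

from __future__ import annotations

import numpy as np
import pytest

from polyretain.simulate import (
    EventSpec,
    SimParams,
    default_events,
    emit_reference_network,
    emit_similarity_table,
    simulate_genome,
)


def _params(**kw):
    base = dict(
        n_genes=200,
        n_chroms=2,
        focal_fraction=0.3,
        tandem_rate=0.0,
        proximal_rate=0.0,
        dispersed_rate=0.0,
        seed=1,
    )
    base.update(kw)
    return SimParams(**base)


def test_no_events_no_rates_means_all_singletons():
    genes, truth = simulate_genome(_params(), [])
    assert len(genes) == 200
    assert set(truth.genes.dup_type_truth) == {"singleton"}
    assert truth.pairs.empty


def test_full_retention_triplication_gives_three_copies_each():
    ev = EventSpec("theta", 3, 0.2, 1.0, 1.0)
    genes, truth = simulate_genome(_params(), [ev])
    assert len(genes) == 600
    assert set(truth.genes.dup_type_truth) == {"wgd"}
    by_family = truth.genes.groupby("ancestral_id").size()
    assert (by_family == 3).all()


def test_gene_count_conservation():
    genes, truth = simulate_genome(
        _params(tandem_rate=0.05, dispersed_rate=0.05), default_events()
    )
    # every emitted gene has exactly one truth record and vice versa
    assert sorted(g.gene_id for g in genes) == sorted(truth.genes.gene_id)
    n_copies = (truth.genes.origin_event != "ancestral").sum() + truth.genes.gene_id.str.contains(
        r"\.(?:t|p|d)$"
    ).sum()
    assert len(genes) == 200 + n_copies


def test_determinism_byte_identical():
    p = _params(tandem_rate=0.02, dispersed_rate=0.02, inversion_count=5)
    g1, t1 = simulate_genome(p, default_events())
    g2, t2 = simulate_genome(p, default_events())
    assert g1 == g2
    assert t1.genes.equals(t2.genes)
    assert t1.pairs.equals(t2.pairs)
    s1 = emit_similarity_table(g1, t1, seed=3)
    s2 = emit_similarity_table(g2, t2, seed=3)
    assert s1 == s2


def test_invalid_configurations_rejected():
    with pytest.raises(ValueError, match="multiplicity"):
        EventSpec("x", 4, 0.5, 0.5, 0.5)
    with pytest.raises(ValueError, match="retention"):
        EventSpec("x", 2, 0.5, 1.5, 0.5)
    with pytest.raises(ValueError, match="decreasing"):
        simulate_genome(_params(), [EventSpec("a", 2, 0.2, 1, 1), EventSpec("b", 2, 0.8, 1, 1)])
    with pytest.raises(ValueError):
        SimParams(n_genes=2, n_chroms=5)


def test_ranks_consecutive_per_chromosome():
    genes, _ = simulate_genome(
        _params(tandem_rate=0.05, proximal_rate=0.05, inversion_count=3),
        default_events(),
    )
    by_chrom: dict[str, list[int]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g.rank)
    for ranks in by_chrom.values():
        assert sorted(ranks) == list(range(len(ranks)))


def test_retention_bias_shows_in_truth_over_seeds():
    """With 3:1 retention odds the focal class ends up with a higher
    polyploidy-derived proportion than the background in nearly every run."""
    wins = trials = 0
    for seed in range(60):
        _, truth = simulate_genome(
            _params(n_genes=400, seed=seed),
            [EventSpec("alpha", 2, 0.3, 0.3, 0.9)],
        )
        df = truth.genes
        focal = df[df.class_tag == "focal"]
        back = df[df.class_tag == "background"]
        pf = (focal.dup_type_truth == "wgd").mean()
        pb = (back.dup_type_truth == "wgd").mean()
        trials += 1
        wins += pf > pb
    assert wins / trials >= 0.95


def test_ks_modes_recoverable_by_nearest_age():
    _, truth = simulate_genome(_params(n_genes=500, ks_noise_sd=0.05), default_events())
    ages = {"gamma": 1.6, "beta": 0.8, "alpha": 0.2}
    pairs = truth.pairs[truth.pairs.split.isin(ages)]
    assert len(pairs) > 100
    correct = 0
    for rec in pairs.itertuples(index=False):
        nearest = min(ages, key=lambda e: abs(ages[e] - rec.ks))
        correct += nearest == rec.split
    assert correct / len(pairs) >= 0.90


def test_similarity_identity_monotone_in_age_and_self_hits_first():
    genes, truth = simulate_genome(_params(n_genes=300, ks_noise_sd=0.0), default_events())
    rows = emit_similarity_table(genes, truth, identity_noise=0.0, seed=0)
    ids = {g.gene_id for g in genes}
    self_hits = [r for r in rows if r.is_self_hit]
    assert {r.query_id for r in self_hits} == ids
    assert all(r.pct_identity == 100.0 and r.evalue == 0.0 for r in self_hits)
    by_split = {}
    for rec, row in zip(truth.pairs.itertuples(index=False), rows[len(self_hits) :: 2]):
        by_split.setdefault(rec.split, []).append(row.pct_identity)
    if "gamma" in by_split and "alpha" in by_split:
        assert max(by_split["gamma"]) < min(by_split["alpha"])
    # E-value decreases with identity
    ordered = sorted((r for r in rows if not r.is_self_hit), key=lambda r: r.pct_identity)
    evs = [r.evalue for r in ordered]
    assert all(e1 >= e2 for e1, e2 in zip(evs, evs[1:]))


def test_no_duplication_emits_only_self_hits():
    genes, truth = simulate_genome(_params(), [])
    rows = emit_similarity_table(genes, truth)
    assert all(r.is_self_hit for r in rows)
    assert len(rows) == len(genes)


def test_reference_network_contract():
    _, truth = simulate_genome(_params(n_genes=400, focal_fraction=0.5), [])
    assert emit_reference_network(truth, 0.0) == []
    e1 = emit_reference_network(truth, 4.0, seed=5)
    e2 = emit_reference_network(truth, 4.0, seed=5)
    assert e1 == e2
    nodes = set(truth.ancestral_focal)
    assert all(a in nodes and b in nodes and a != b for a, b in e1)


def test_reference_network_edge_count_near_expectation():
    """100 nodes at mean degree 4: about 200 edges (preferential attachment
    with m = 2 gives m*(n - m))."""
    params = _params(n_genes=250, focal_fraction=0.4, seed=11)
    _, truth = simulate_genome(params, [])
    nodes = truth.ancestral_focal
    assert 80 <= len(nodes) <= 120
    edges = emit_reference_network(truth, 4.0, seed=2)
    assert 150 <= len(edges) <= 250
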