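"""End-to-end orchestration: simulate/ingest -> family -> anchors -> blocks
-> duplication typing -> event attribution -> enrichment -> network
projection -> robustness -> Ka/Ks.

The simulated study is the primary entry point: it runs every stage on a
genome with known ground truth and reports both the published-table-shaped
outputs and recovery metrics against the truth.  A file-based variant covers
externally supplied inputs.  One master seed fans out to stable per-stage
child seeds, so identical configuration yields byte-identical reports.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierParams, classify_duplicates, summarize_types
from .collinearity import (
    CollinearityParams,
    colinear_gene_set,
    find_blocks,
)
from .enrichment import (
    EnrichmentParams,
    enrichment_row,
    type_enrichment_table,
)
from .events import (
    EventAssignment,
    assign_block_events,
    gene_event_participation,
    ks_from_similarity,
    windows_from_ages,
)
from .homology import FamilyThresholds, filter_anchors, identify_family_members, FamilyLibrary
from .io import (
    GeneRecord,
    write_block_report,
    write_gene_positions,
    write_similarity_table,
)
from .kaks import CodonAlignment, SaturationError, kaks_pair, simulate_codon_pair
from .network import Network, event_specific_nodes, network_stats, project_network
from .robustness import RobustnessParams, robustness_profile
from .simulate import (
    EventSpec,
    SimParams,
    TruthTable,
    default_events,
    emit_reference_network,
    emit_similarity_table,
    simulate_genome,
)
from .util import child_seed, format_percent

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "RunReport", "run_simulated_study"]


@dataclass
class StudyConfig:
    """Configuration of one simulated study run."""

    sim: SimParams = field(default_factory=SimParams)
    events: list[EventSpec] = field(default_factory=default_events)
    family: FamilyThresholds = field(default_factory=FamilyThresholds)
    collinearity: CollinearityParams = field(default_factory=CollinearityParams)
    classifier: ClassifierParams = field(default_factory=ClassifierParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    robustness: RobustnessParams = field(default_factory=RobustnessParams)
    network_mean_degree: float = 4.0
    kaks_sample: int = 40
    kaks_codons: int = 200
    kaks_omega_sim: float = 0.2  # purifying constraint of the simulated CDS pairs


@dataclass
class RunReport:
    """All stage outputs of one pipeline run plus truth-recovery metrics."""

    enrichment: pd.DataFrame
    type_summary: pd.DataFrame
    type_enrichment: pd.DataFrame
    event_table: pd.DataFrame
    venn: dict
    network: pd.DataFrame
    robustness: pd.DataFrame
    kaks: pd.DataFrame
    metrics: dict
    provenance: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in (
            ("enrichment.tsv", self.enrichment),
            ("type_summary.tsv", self.type_summary),
            ("type_enrichment.tsv", self.type_enrichment),
            ("event_table.tsv", self.event_table),
            ("network_stats.tsv", self.network),
            ("robustness.tsv", self.robustness),
            ("kaks.tsv", self.kaks),
        ):
            df.to_csv(out / name, sep="\t", index=False)
        venn_json = {
            ",".join(sorted(k)): v for k, v in sorted(self.venn.items(), key=lambda kv: sorted(kv[0]))
        }
        with open(out / "report.json", "w", encoding="utf-8") as fh:
            json.dump(
                {"venn": venn_json, "metrics": self.metrics, "provenance": self.provenance},
                fh,
                indent=2,
                sort_keys=True,
            )
            fh.write("\n")


def _stage(name: str, t0: float, **sizes) -> None:
    info = " ".join(f"{k}={v}" for k, v in sizes.items())
    logger.info("stage=%s elapsed=%.2fs %s", name, time.perf_counter() - t0, info)


def ortholog_map_from_similarity(
    seeds: Sequence[str], rows, thresholds: FamilyThresholds
) -> dict[str, set[str]]:
    """Equivalent-replacement map: each seed to itself plus every gene it
    hits above the family thresholds (many-to-many after polyploidy)."""
    orth: dict[str, set[str]] = {s: {s} for s in seeds}
    seed_set = set(seeds)
    for r in rows:
        if r.is_self_hit or r.query_id not in seed_set:
            continue
        if r.evalue < thresholds.evalue_max and r.pct_identity > thresholds.identity_min:
            orth[r.query_id].add(r.subject_id)
    return orth


def _true_block_label(block, truth_pairs: Mapping[tuple[str, str], str]) -> str | None:
    """Majority true split event among a block's anchor pairs (None if the
    majority of anchors are not event-born)."""
    votes: dict[str, int] = {}
    for a in block.anchors:
        key = (a.gene_a, a.gene_b) if a.gene_a <= a.gene_b else (a.gene_b, a.gene_a)
        split = truth_pairs.get(key)
        if split is not None:
            votes[split] = votes.get(split, 0) + 1
    if not votes:
        return None
    return max(sorted(votes), key=lambda k: votes[k])


def run_simulated_study(
    config: StudyConfig | None = None,
    out_dir: str | Path | None = None,
) -> RunReport:
    """Run every stage on one simulated genome; optionally write all
    intermediates and report tables under ``out_dir``."""
    cfg = config or StudyConfig()
    seed = cfg.sim.seed
    t0 = time.perf_counter()

    genes, truth = simulate_genome(cfg.sim, cfg.events)
    _stage("simulate", t0, genes=len(genes))

    similarity = emit_similarity_table(
        genes,
        truth,
        identity_decay=cfg.sim.identity_decay,
        seed=child_seed(seed, "similarity"),
    )
    _stage("similarity", t0, rows=len(similarity))

    # family identification from the ancestral focal seeds
    seeds = sorted(truth.ancestral_focal)
    library = FamilyLibrary(frozenset(seeds), frozenset(seeds))
    members = identify_family_members(library, similarity, cfg.family)
    focal_set = set(seeds) | members
    _stage("family", t0, seeds=len(seeds), members=len(focal_set))

    anchors = filter_anchors(similarity)
    coll = CollinearityParams(
        max_gap=cfg.collinearity.max_gap,
        min_anchors=cfg.collinearity.min_anchors,
        p_max=cfg.collinearity.p_max,
        n_permutations=cfg.collinearity.n_permutations,
        seed=child_seed(seed, "permutation"),
    )
    blocks = find_blocks(genes, anchors, coll)
    significant = [b for b in blocks if b.p_value is not None and b.p_value < coll.p_max]
    colinear = colinear_gene_set(blocks, coll.p_max)
    _stage("blocks", t0, blocks=len(blocks), significant=len(significant))

    universe = [g.gene_id for g in genes]
    dup_map = classify_duplicates(genes, anchors, significant, cfg.classifier)
    summary = summarize_types(dup_map, universe)
    _stage("classify", t0)

    # event attribution via Ks windows at midpoints between the known ages
    pair_ks = ks_from_similarity(similarity, cfg.sim.identity_decay)
    windows = windows_from_ages({e.name: e.age_ks for e in cfg.events})
    assignment = assign_block_events(significant, pair_ks, windows)
    event_counts, venn = gene_event_participation(assignment)
    focal_event_counts = {
        e.name: sum(
            1
            for g, evs in assignment.gene_events.items()
            if e.name in evs and g in focal_set
        )
        for e in cfg.events
    }
    event_rows = [
        {
            "event": e.name,
            "multiplicity": "WGT" if e.multiplicity == 3 else "WGD",
            "age_ks": e.age_ks,
            "focal_count": focal_event_counts[e.name],
            "focal_percent": format_percent(focal_event_counts[e.name], len(focal_set)),
            "all_count": event_counts.get(e.name, 0),
        }
        for e in cfg.events
    ]
    event_table = pd.DataFrame(
        event_rows,
        columns=["event", "multiplicity", "age_ks", "focal_count", "focal_percent", "all_count"],
    )
    _stage("events", t0)

    enr = enrichment_row(focal_set, colinear, universe, cfg.enrichment)
    enrichment_df = pd.DataFrame(
        [
            {
                "dataset": "simulated",
                "all_colinear": len(colinear),
                "all_total": len(universe),
                "all_percent": format_percent(len(colinear), len(universe)),
                "focal_colinear": enr.a,
                "focal_total": enr.a + enr.b,
                "focal_percent": format_percent(enr.a, enr.a + enr.b),
                "chi2": round(enr.chi2, 4),
                "p_value": enr.p,
                "status": enr.status,
            }
        ]
    )
    type_enr = type_enrichment_table(dup_map, focal_set, universe, cfg.enrichment)
    type_enrichment_df = pd.DataFrame(
        [
            {
                "type": t,
                "focal_in": r.a,
                "focal_out": r.b,
                "background_in": r.c,
                "background_out": r.d,
                "chi2": round(r.chi2, 4),
                "p_value": r.p,
                "status": r.status,
            }
            for t, r in type_enr.items()
        ]
    )
    type_summary_df = pd.DataFrame(
        [
            {"type": t, "count": summary.counts[t], "percent": summary.percents[t]}
            for t in summary.counts
        ]
    )
    _stage("enrichment", t0, status=enr.status)

    # ortholog-projected interaction network over the focal class
    ref_edges = emit_reference_network(
        truth, cfg.network_mean_degree, seed=child_seed(seed, "network")
    )
    orth = ortholog_map_from_similarity(seeds, similarity, cfg.family)
    annotations = {
        g: {"event_set": sorted(evs), "focal": g in focal_set}
        for g, evs in assignment.gene_events.items()
    }
    projected = project_network(ref_edges, orth, annotations)
    reference = Network.from_edges(ref_edges)
    stats_rows = []
    for name, net in (("reference", reference), ("projected", projected)):
        st = network_stats(net)
        stats_rows.append(
            {
                "network": name,
                "n_nodes": st.n_nodes,
                "n_edges": st.n_edges,
                "max_degree": st.max_degree,
                "max_degree_node": st.max_degree_node or ".",
                "edge_node_ratio": st.edge_node_ratio,
            }
        )
    network_df = pd.DataFrame(stats_rows)
    node_venn = event_specific_nodes(projected)
    _stage("network", t0, edges=len(projected.edges))

    rob_params = RobustnessParams(
        removal_counts=cfg.robustness.removal_counts,
        removal_fractions=cfg.robustness.removal_fractions,
        reps=cfg.robustness.reps,
        seed=child_seed(seed, "robustness"),
    )
    rob_df = robustness_profile(
        {"reference": reference.to_networkx(), "projected": projected.to_networkx()},
        rob_params,
    )
    _stage("robustness", t0)

    # Ka/Ks screen over a sample of significant anchor pairs
    rng = np.random.default_rng(child_seed(seed, "kaks"))
    anchor_pairs = sorted(
        {
            (a.gene_a, a.gene_b) if a.gene_a <= a.gene_b else (a.gene_b, a.gene_a)
            for b in significant
            for a in b.anchors
        }
    )
    if len(anchor_pairs) > cfg.kaks_sample:
        idx = rng.choice(len(anchor_pairs), size=cfg.kaks_sample, replace=False)
        anchor_pairs = [anchor_pairs[i] for i in sorted(idx)]
    kaks_rows = []
    for ga, gb in anchor_pairs:
        ks_latent = min(pair_ks.get((ga, gb), 0.3), 0.8)
        aln = simulate_codon_pair(cfg.kaks_codons, ks_latent, rng, omega=cfg.kaks_omega_sim)
        try:
            res = kaks_pair(aln)
        except SaturationError:
            continue
        kaks_rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "ka": round(res.ka, 4),
                "ks": round(res.ks, 4),
                "omega": "." if res.omega is None else round(res.omega, 4),
                "positive_selection": res.positive_selection,
            }
        )
    kaks_df = pd.DataFrame(
        kaks_rows,
        columns=["gene_a", "gene_b", "ka", "ks", "omega", "positive_selection"],
    )
    _stage("kaks", t0, pairs=len(kaks_df))

    # truth-recovery metrics
    truth_types = dict(zip(truth.genes.gene_id, truth.genes.dup_type_truth))
    agreement = sum(1 for g in universe if dup_map[g] == truth_types[g]) / len(universe)
    truth_focal = set(truth.genes.gene_id[truth.genes.class_tag == "focal"])
    tp = len(focal_set & truth_focal)
    precision = tp / len(focal_set) if focal_set else 0.0
    recall = tp / len(truth_focal) if truth_focal else 0.0
    truth_pairs = {
        (r.gene_a, r.gene_b) if r.gene_a <= r.gene_b else (r.gene_b, r.gene_a): r.split
        for r in truth.pairs.itertuples(index=False)
    }
    event_names = {e.name for e in cfg.events}
    wgd_blocks = [
        b
        for b in significant
        if (_true_block_label(b, truth_pairs) in event_names)
    ]
    correct = sum(
        1 for b in wgd_blocks if b.event_label == _true_block_label(b, truth_pairs)
    )
    event_accuracy = correct / len(wgd_blocks) if wgd_blocks else float("nan")
    wgd_truth_genes = {g for g, t in truth_types.items() if t == "wgd"}
    wgd_recall = (
        len(wgd_truth_genes & colinear) / len(wgd_truth_genes)
        if wgd_truth_genes
        else float("nan")
    )
    metrics = {
        "classifier_agreement": agreement,
        "family_precision": precision,
        "family_recall": recall,
        "event_label_accuracy": event_accuracy,
        "colinear_recall_of_wgd_truth": wgd_recall,
        "n_genes": len(universe),
        "n_focal_detected": len(focal_set),
        "n_significant_blocks": len(significant),
    }

    provenance = {
        "seed": seed,
        "version": __version__,
        "n_events": len(cfg.events),
        "sim": asdict(cfg.sim),
    }
    report = RunReport(
        enrichment=enrichment_df,
        type_summary=type_summary_df,
        type_enrichment=type_enrichment_df,
        event_table=event_table,
        venn={k: v for k, v in node_venn.items()},
        network=network_df,
        robustness=rob_df,
        kaks=kaks_df,
        metrics=metrics,
        provenance=provenance,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_gene_positions(genes, out / "gene_positions.tsv")
        write_similarity_table(similarity, out / "similarity.tsv")
        truth.to_tsv(out / "truth.tsv")
        write_block_report(blocks, out / "blocks.tsv")
        pd.DataFrame(
            sorted(dup_map.items()), columns=["gene_id", "dup_type"]
        ).to_csv(out / "dup_types.tsv", sep="\t", index=False)
        with open(out / "network_edges.tsv", "w", encoding="utf-8") as fh:
            for a, b in sorted(projected.edges):
                fh.write(f"{a}\t{b}\n")
        report.write(out)
    return report
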