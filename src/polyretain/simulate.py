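"""Simulator for polyploid genomes with a known duplication history.

The model: an ancestral genome of single-copy genes, a fraction of which are
tagged as the focal class (e.g. cold-related genes), experiences an ordered
series of whole-genome duplications (tetraploidy, multiplicity 2) and
triplications (hexaploidy, multiplicity 3), oldest first.  Each event copies
every chromosome; each *new* copy of a gene survives fractionation with a
class-dependent retention probability (``retention_focal`` vs
``retention_background``), while the pre-existing copy always survives, so no
gene ever goes extinct.  Whole-genome copies are appended as new chromosomes
with lost genes removed, which preserves within-copy gene order exactly as
paleo-duplicated blocks do.

After all events, single-gene duplication modes are applied per gene
(tandem: insert at the adjacent rank; proximal: at a uniform rank offset in
[2, 10]; dispersed: on a random other chromosome), followed by a configurable
number of random segment inversions that erode collinearity.

Every surviving duplicate pair carries a latent synonymous distance (Ks)
drawn from a Normal centred on the age of the event (or single-gene mode)
that separated the pair, truncated at zero — so the Ks histogram of
polyploidy-derived pairs is multimodal with one mode per event.  A similarity
table is emitted from these latent distances with percent identity decaying
exponentially in Ks, and a preferential-attachment reference interaction
network can be generated over the ancestral focal genes.

All randomness flows from the single integer seed in :class:`SimParams`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io import GeneRecord, SimilarityRow, assign_ranks

__all__ = [
    "EventSpec",
    "SimParams",
    "TruthTable",
    "simulate_genome",
    "emit_similarity_table",
    "emit_reference_network",
    "default_events",
]

DUP_TYPES = ("singleton", "dispersed", "proximal", "tandem", "wgd")


@dataclass(frozen=True)
class EventSpec:
    """One paleopolyploidy event.

    multiplicity 2 is a whole-genome duplication (tetraploidy), 3 a
    triplication (hexaploidy).  ``age_ks`` is the mean synonymous distance of
    duplicate pairs born at the event; retention probabilities govern
    class-biased survival of the new copies.
    """

    name: str
    multiplicity: int
    age_ks: float
    retention_background: float
    retention_focal: float

    def __post_init__(self) -> None:
        if self.multiplicity not in (2, 3):
            raise ValueError(f"event {self.name}: multiplicity must be 2 or 3")
        if self.age_ks < 0:
            raise ValueError(f"event {self.name}: negative age_ks")
        for r in (self.retention_background, self.retention_focal):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"event {self.name}: retention {r} outside [0, 1]")


@dataclass(frozen=True)
class SimParams:
    """Knobs of the simulated study; the seed fixes all randomness."""

    n_genes: int = 2000
    n_chroms: int = 5
    focal_fraction: float = 0.3
    tandem_rate: float = 0.01
    proximal_rate: float = 0.01
    dispersed_rate: float = 0.02
    inversion_count: int = 0
    ks_noise_sd: float = 0.05
    single_dup_ks: float = 0.1
    identity_decay: float = 0.12
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (
            self.focal_fraction,
            self.tandem_rate,
            self.proximal_rate,
            self.dispersed_rate,
        ):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        if self.tandem_rate + self.proximal_rate + self.dispersed_rate > 1.0:
            raise ValueError("single-gene duplication rates sum to > 1")
        if self.n_chroms < 1 or self.n_genes < self.n_chroms:
            raise ValueError("need n_genes >= n_chroms >= 1")
        if self.inversion_count < 0:
            raise ValueError("negative inversion_count")


def _validate_events(events: Sequence[EventSpec]) -> None:
    ages = [e.age_ks for e in events]
    if any(a2 >= a1 for a1, a2 in zip(ages, ages[1:])):
        raise ValueError("event ages must be strictly decreasing (oldest first)")


class _Gene:
    """Internal mutable gene node carrying its duplication genealogy."""

    __slots__ = ("uid", "ancestral", "focal", "birth", "lineage", "sg_parent", "sg_mode")

    def __init__(self, uid, ancestral, focal, birth, lineage, sg_parent=None, sg_mode=None):
        self.uid = uid
        self.ancestral = ancestral
        self.focal = focal
        self.birth = birth  # event name, mode name, or "ancestral"
        self.lineage = lineage  # tuple of (event_name, branch_index)
        self.sg_parent = sg_parent  # uid of source for single-gene copies
        self.sg_mode = sg_mode


@dataclass
class TruthTable:
    """Per-gene simulated ground truth plus pair-level latent distances.

    ``genes`` has one row per emitted gene (gene_id, class_tag,
    dup_type_truth, origin_event, ancestral_id).  ``pairs`` has one row per
    surviving duplicate pair (gene_a, gene_b, ks, split — the event name or
    single-gene mode that separated the pair).  ``ancestral_focal`` lists the
    focal-tagged ancestral gene IDs (reference-network node universe).
    """

    genes: pd.DataFrame
    pairs: pd.DataFrame
    ancestral_focal: list[str]

    def dup_type(self, gene_id: str) -> str:
        return self._type_map()[gene_id]

    def _type_map(self) -> dict[str, str]:
        if not hasattr(self, "_types"):
            self._types = dict(zip(self.genes.gene_id, self.genes.dup_type_truth))
        return self._types

    def to_tsv(self, path) -> None:
        self.genes.to_csv(path, sep="\t", index=False)


def _split_event(g1: _Gene, g2: _Gene, event_order: dict[str, int]) -> str | None:
    """Name of the polyploidy event at which two family members diverged."""
    for (e1, b1), (e2, b2) in zip(g1.lineage, g2.lineage):
        assert e1 == e2
        if b1 != b2:
            return e1
    return None  # same event lineage: related through a single-gene copy


def simulate_genome(
    params: SimParams, events: Sequence[EventSpec]
) -> tuple[list[GeneRecord], TruthTable]:
    """Run the generative model; return gene position records and ground truth.

    Deterministic per ``params.seed``; gene ranks are consecutive per
    chromosome and coordinates are derived from ranks (1 kb per gene slot).
    """
    _validate_events(events)
    rng = np.random.default_rng(params.seed)
    id_width = max(5, len(str(params.n_genes)))

    # ancestral genome: contiguous blocks of genes per chromosome
    chroms: dict[str, list[_Gene]] = {}
    per = [params.n_genes // params.n_chroms] * params.n_chroms
    for i in range(params.n_genes % params.n_chroms):
        per[i] += 1
    focal_draw = rng.random(params.n_genes) < params.focal_fraction
    gi = 0
    ancestral_focal: list[str] = []
    for c in range(params.n_chroms):
        name = f"chr{c + 1}"
        chroms[name] = []
        for _ in range(per[c]):
            uid = f"g{gi:0{id_width}d}"
            if focal_draw[gi]:
                ancestral_focal.append(uid)
            chroms[name].append(_Gene(uid, uid, bool(focal_draw[gi]), "ancestral", ()))
            gi += 1

    # recursive polyploidies, oldest first
    for event in events:
        new_chroms: dict[str, list[_Gene]] = {}
        for cname in list(chroms):
            genes = chroms[cname]
            for g in genes:
                g.lineage = g.lineage + ((event.name, 0),)
            for k in range(1, event.multiplicity):
                copy_name = f"{cname}-{event.name}{k}"
                copy: list[_Gene] = []
                for g in genes:
                    p = event.retention_focal if g.focal else event.retention_background
                    if rng.random() < p:
                        uid = f"{g.uid}.{event.name}{k}"
                        copy.append(
                            _Gene(
                                uid,
                                g.ancestral,
                                g.focal,
                                event.name,
                                g.lineage[:-1] + ((event.name, k),),
                            )
                        )
                if copy:
                    new_chroms[copy_name] = copy
        chroms.update(new_chroms)

    # single-gene duplication modes, applied to a snapshot of the final set
    t, p, d = params.tandem_rate, params.proximal_rate, params.dispersed_rate
    chrom_names = sorted(chroms)
    snapshot = [(cname, g) for cname in chrom_names for g in list(chroms[cname])]
    for cname, g in snapshot:
        u = rng.random()
        if u < t:
            mode = "tandem"
        elif u < t + p:
            mode = "proximal"
        elif u < t + p + d:
            mode = "dispersed"
        else:
            continue
        uid = f"{g.uid}.{mode[0]}"
        copy = _Gene(uid, g.ancestral, g.focal, mode, g.lineage, g.uid, mode)
        if mode == "tandem":
            pos = chroms[cname].index(g) + 1
            chroms[cname].insert(pos, copy)
        elif mode == "proximal":
            offset = int(rng.integers(2, 11))
            pos = min(chroms[cname].index(g) + offset, len(chroms[cname]))
            chroms[cname].insert(pos, copy)
        else:
            others = [c for c in sorted(chroms) if c != cname] or [cname]
            target = others[int(rng.integers(len(others)))]
            pos = int(rng.integers(len(chroms[target]) + 1))
            chroms[target].insert(pos, copy)

    # collinearity erosion: random segment inversions
    strands: dict[str, str] = {}
    cnames = sorted(chroms)
    for _ in range(params.inversion_count):
        cname = cnames[int(rng.integers(len(cnames)))]
        genes = chroms[cname]
        if len(genes) < 2:
            continue
        i, j = sorted(rng.choice(len(genes), size=2, replace=False))
        chroms[cname][i : j + 1] = genes[i : j + 1][::-1]
        for g in chroms[cname][i : j + 1]:
            strands[g.uid] = "-" if strands.get(g.uid, "+") == "+" else "+"

    # emit position records: 1 kb slot per rank
    records: list[GeneRecord] = []
    all_genes: list[_Gene] = []
    for cname in sorted(chroms):
        for r, g in enumerate(chroms[cname]):
            start = r * 1000 + 1
            records.append(
                GeneRecord(
                    gene_id=g.uid,
                    chromosome=cname,
                    start=start,
                    end=start + 599,
                    strand=strands.get(g.uid, "+"),
                    class_tag="focal" if g.focal else "background",
                )
            )
            all_genes.append(g)
    records = assign_ranks(records)

    # pair-level latent Ks and per-gene truth types
    event_order = {e.name: i for i, e in enumerate(events)}
    age = {e.name: e.age_ks for e in events}
    by_family: dict[str, list[_Gene]] = {}
    for g in all_genes:
        by_family.setdefault(g.ancestral, []).append(g)

    by_uid = {g.uid: g for g in all_genes}

    def _sg_root(g: _Gene) -> _Gene:
        while g.sg_parent is not None:
            g = by_uid[g.sg_parent]
        return g

    pair_rows = []
    gene_rows = []
    for fam in sorted(by_family):
        members = sorted(by_family[fam], key=lambda g: g.uid)
        mode_of: dict[str, set[str]] = {}
        event_pair_of: dict[str, bool] = {g.uid: False for g in members}
        for g1, g2 in itertools.combinations(members, 2):
            r1, r2 = _sg_root(g1), _sg_root(g2)
            if r1 is r2:
                split = g2.sg_mode or g1.sg_mode  # related via a single-gene copy
                mean = params.single_dup_ks
            else:
                split = _split_event(r1, r2, event_order)
                if split is None:
                    split = g2.sg_mode or g1.sg_mode
                    mean = params.single_dup_ks
                else:
                    mean = age[split]
            if split in event_order:
                event_pair_of[g1.uid] = True
                event_pair_of[g2.uid] = True
            else:
                mode_of.setdefault(g1.uid, set()).add(split)
                mode_of.setdefault(g2.uid, set()).add(split)
            ks = max(0.0, float(rng.normal(mean, params.ks_noise_sd)))
            pair_rows.append((g1.uid, g2.uid, ks, split))
        for g in members:
            # a single-gene-born copy is typed by its mode: it was not created
            # by a polyploidy even if its family carries event-born relatives
            if g.sg_mode is not None:
                dup = g.sg_mode
            elif event_pair_of[g.uid]:
                dup = "wgd"
            elif g.uid in mode_of:
                for m in ("tandem", "proximal", "dispersed"):
                    if m in mode_of[g.uid]:
                        dup = m
                        break
            else:
                dup = "singleton"
            origin = g.birth if g.birth in event_order else "ancestral"
            gene_rows.append(
                (g.uid, "focal" if g.focal else "background", dup, origin, g.ancestral)
            )

    genes_df = (
        pd.DataFrame(
            gene_rows,
            columns=["gene_id", "class_tag", "dup_type_truth", "origin_event", "ancestral_id"],
        )
        .sort_values("gene_id")
        .reset_index(drop=True)
    )
    pairs_df = pd.DataFrame(pair_rows, columns=["gene_a", "gene_b", "ks", "split"])
    truth = TruthTable(genes=genes_df, pairs=pairs_df, ancestral_focal=ancestral_focal)
    return records, truth


def emit_similarity_table(
    genome: Sequence[GeneRecord],
    truth: TruthTable,
    identity_decay: float = 0.12,
    identity_noise: float = 0.5,
    seed: int = 0,
) -> list[SimilarityRow]:
    """Emit an all-vs-all-style similarity table from the latent pair Ks.

    Percent identity decays as ``100*exp(-k*Ks)`` (bounded uniform noise
    added); E-values decrease monotonically with identity; every gene gets a
    first-ranked self-hit (identity 100, E = 0).  Every duplicate pair appears
    in both query/subject orientations.
    """
    rng = np.random.default_rng(seed)
    aln_len = 450
    rows: list[SimilarityRow] = []
    for g in sorted(genome, key=lambda g: g.gene_id):
        rows.append(
            SimilarityRow(
                g.gene_id, g.gene_id, 100.0, aln_len, 0, 0, 1, aln_len, 1, aln_len,
                0.0, float(aln_len * 2),
            )
        )
    for rec in truth.pairs.itertuples(index=False):
        ident = 100.0 * math.exp(-identity_decay * rec.ks)
        if identity_noise > 0:
            ident += float(rng.uniform(-identity_noise, identity_noise))
        ident = min(99.9, max(0.1, ident))
        evalue = 10.0 ** (-ident / 3.0)
        bits = round(ident * aln_len / 25.0, 1)
        mism = int(round(aln_len * (1 - ident / 100.0)))
        for q, s in ((rec.gene_a, rec.gene_b), (rec.gene_b, rec.gene_a)):
            rows.append(
                SimilarityRow(
                    q, s, round(ident, 2), aln_len, mism, 0, 1, aln_len, 1, aln_len,
                    evalue, bits,
                )
            )
    return rows


def emit_reference_network(
    truth: TruthTable, mean_degree: float, seed: int = 0
) -> list[tuple[str, str]]:
    """Preferential-attachment interaction network over ancestral focal genes.

    Emulates a curated reference interactome (hub-dominated degree
    distribution).  ``mean_degree`` 0 yields an empty edge list; the result is
    deterministic per seed.
    """
    nodes = sorted(truth.ancestral_focal)
    n = len(nodes)
    if mean_degree < 0 or (n > 1 and mean_degree > n - 1):
        raise ValueError(f"mean_degree {mean_degree} infeasible for {n} nodes")
    if mean_degree == 0 or n < 2:
        return []
    m = max(1, int(round(mean_degree / 2)))
    g = nx.barabasi_albert_graph(n, min(m, n - 1), seed=seed)
    return sorted(
        (min(nodes[u], nodes[v]), max(nodes[u], nodes[v])) for u, v in g.edges()
    )


def default_events(
    retention_focal: float = 0.9, retention_background: float = 0.3
) -> list[EventSpec]:
    """Canonical three-event history: an old hexaploidy followed by two
    tetraploidies (ages 1.6 / 0.8 / 0.2 Ks), with class-biased retention."""
    return [
        EventSpec("gamma", 3, 1.6, retention_background, retention_focal),
        EventSpec("beta", 2, 0.8, retention_background, retention_focal),
        EventSpec("alpha", 2, 0.2, retention_background, retention_focal),
    ]
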