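"""Collinear (synteny) block detection by anchor chaining on gene ranks.

Anchors — homologous gene pairs — are chained along a chromosome pair by
dynamic programming.  A chain must be strictly monotone in both genomes
(increasing/increasing for same orientation, increasing/decreasing for
reverse) with at most ``max_gap`` intervening genes between consecutive
anchors on *each* genome.  Chain score is the anchor count; blocks are
extracted greedily (best chain first, its anchors removed, repeat) until no
chain reaches ``min_anchors``.  Ties between equal-score chains are broken by
smaller total gap, then by lexicographically smallest anchor-rank sequence,
making extraction fully deterministic and equal to exhaustive enumeration.

Block significance uses a permutation null: the same number of anchors is
redrawn uniformly on the rank grid of the chromosome pair and the best
attainable chain score recomputed; the add-one estimator
``p = (1 + #better) / (1 + n_permutations)`` gates blocks at ``p_max``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .io import GeneRecord, SimilarityRow

__all__ = [
    "Anchor",
    "CollinearityParams",
    "CollinearBlock",
    "chain_anchors",
    "best_chain_score",
    "block_pvalue",
    "colinear_gene_set",
    "rank_hit_classes",
    "anchors_by_chrom_pair",
    "find_blocks",
]


class Anchor(NamedTuple):
    gene_a: str
    gene_b: str
    rank_a: int
    rank_b: int


@dataclass(frozen=True)
class CollinearityParams:
    max_gap: int = 50
    min_anchors: int = 5
    p_max: float = 0.05
    n_permutations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_anchors < 2:
            raise ValueError("min_anchors must be >= 2")
        if not 0 < self.p_max <= 1:
            raise ValueError("p_max outside (0, 1]")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "reverse"
    anchors: list[Anchor]
    score: int
    p_value: float | None = None
    event_label: str | None = None

    def gene_set(self) -> set[str]:
        out: set[str] = set()
        for a in self.anchors:
            out.add(a.gene_a)
            out.add(a.gene_b)
        return out


def _best_chain_oriented(
    anchors: Sequence[Anchor], max_gap: int, sign: int
) -> tuple[tuple, list[Anchor]] | None:
    """Best chain under one orientation (sign=+1 same, -1 reverse) by DP.

    DP state per anchor: (score, total_gap, rank-sequence) of the best chain
    ending there; lexicographic prefix comparison is valid because tied
    candidates always have equal length.
    """
    if not anchors:
        return None
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, sign * anchors[i].rank_b))
    n = len(order)
    ra = [anchors[i].rank_a for i in order]
    rb = [sign * anchors[i].rank_b for i in order]
    step = max_gap + 1
    score = [1] * n
    gap = [0] * n
    seq: list[tuple] = [((anchors[order[i]].rank_a, anchors[order[i]].rank_b),) for i in range(n)]
    for i in range(n):
        best_j = -1
        for j in range(i):
            da = ra[i] - ra[j]
            db = rb[i] - rb[j]
            if da <= 0 or db <= 0 or da > step or db > step:
                continue
            cs = score[j] + 1
            cg = gap[j] + (da - 1) + (db - 1)
            if cs > score[i]:
                take = True
            elif cs == score[i]:
                if cg < gap[i]:
                    take = True
                elif cg == gap[i]:
                    prev = seq[best_j] if best_j >= 0 else None
                    take = prev is not None and seq[j] < prev
                else:
                    take = False
            else:
                take = False
            if take:
                score[i] = cs
                gap[i] = cg
                best_j = j
        if best_j >= 0:
            seq[i] = seq[best_j] + ((anchors[order[i]].rank_a, anchors[order[i]].rank_b),)
    # pick globally best endpoint
    best_i = min(range(n), key=lambda i: (-score[i], gap[i], seq[i]))
    # reconstruct via the stored sequence
    chain_ranks = set(seq[best_i])
    chain = [a for a in anchors if (a.rank_a, a.rank_b) in chain_ranks]
    chain.sort(key=lambda a: a.rank_a)
    key = (-score[best_i], gap[best_i], seq[best_i])
    return key, chain


def _best_chain(anchors: Sequence[Anchor], max_gap: int) -> tuple[str, list[Anchor]] | None:
    """Best chain over both orientations; returns (orientation, anchors)."""
    cands = []
    for name, sign in (("same", 1), ("reverse", -1)):
        res = _best_chain_oriented(anchors, max_gap, sign)
        if res is not None:
            cands.append((res[0], name, res[1]))
    if not cands:
        return None
    cands.sort(key=lambda c: (c[0], c[1]))  # "reverse" < "same" never ties on >=2 anchors
    key, name, chain = cands[0]
    return name, chain


def chain_anchors(
    anchors: Sequence[Anchor],
    params: CollinearityParams = CollinearityParams(),
    chrom_a: str = ".",
    chrom_b: str = ".",
) -> list[CollinearBlock]:
    """Greedy best-chain-first block extraction on one chromosome pair."""
    remaining = list(dict.fromkeys(anchors))
    blocks: list[CollinearBlock] = []
    while remaining:
        res = _best_chain(remaining, params.max_gap)
        if res is None:
            break
        orientation, chain = res
        if len(chain) < params.min_anchors:
            break
        blocks.append(
            CollinearBlock(chrom_a, chrom_b, orientation, chain, score=len(chain))
        )
        used = set(chain)
        remaining = [a for a in remaining if a not in used]
    return blocks


def best_chain_score(rank_a: np.ndarray, rank_b: np.ndarray, max_gap: int) -> int:
    """Maximum chain score over both orientations (score-only fast path)."""
    n = len(rank_a)
    if n == 0:
        return 0
    best = 1
    step = max_gap + 1
    for sign in (1, -1):
        rb = sign * rank_b
        order = np.lexsort((rb, rank_a))
        r1 = rank_a[order].astype(np.int64)
        r2 = rb[order].astype(np.int64)
        dp = np.ones(n, dtype=np.int64)
        for i in range(1, n):
            da = r1[i] - r1[:i]
            db = r2[i] - r2[:i]
            ok = (da > 0) & (da <= step) & (db > 0) & (db <= step)
            if ok.any():
                dp[i] = 1 + dp[:i][ok].max()
        best = max(best, int(dp.max()))
    return best


def block_pvalue(
    block: CollinearBlock,
    n_anchors_on_pair: int,
    len_a: int,
    len_b: int,
    params: CollinearityParams = CollinearityParams(),
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation p-value: redraw the pair's anchors uniformly on the
    len_a x len_b rank grid and compare best chain scores (add-one estimator)."""
    if len_a <= 0 or len_b <= 0:
        raise ValueError("chromosome lengths must be positive")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    hits = 0
    for _ in range(params.n_permutations):
        ra = rng.integers(0, len_a, size=n_anchors_on_pair)
        rb = rng.integers(0, len_b, size=n_anchors_on_pair)
        if best_chain_score(ra, rb, params.max_gap) >= block.score:
            hits += 1
    return (1 + hits) / (1 + params.n_permutations)


def colinear_gene_set(blocks: Iterable[CollinearBlock], p_max: float = 0.05) -> set[str]:
    """Union of genes appearing in at least one significant block."""
    out: set[str] = set()
    for b in blocks:
        if b.p_value is not None and b.p_value < p_max:
            out |= b.gene_set()
    return out


def rank_hit_classes(rows: Iterable[SimilarityRow]) -> dict[tuple[str, str], str]:
    """Label each query's non-self hits best / second / other (dot-plot legend)."""
    by_q: dict[str, list[SimilarityRow]] = {}
    for r in rows:
        if not r.is_self_hit:
            by_q.setdefault(r.query_id, []).append(r)
    labels: dict[tuple[str, str], str] = {}
    for q, hits in by_q.items():
        hits.sort(key=lambda r: (r.evalue, -r.bitscore, r.subject_id))
        for i, r in enumerate(hits):
            labels[(q, r.subject_id)] = (
                "best" if i == 0 else "second" if i == 1 else "other"
            )
    return labels


def anchors_by_chrom_pair(
    rows: Iterable[SimilarityRow],
    genes: Sequence[GeneRecord],
) -> dict[tuple[str, str], list[Anchor]]:
    """Group filtered similarity hits into deduplicated anchors per
    chromosome pair.

    Pairs are canonicalised (chrom_a <= chrom_b; within a self-comparison the
    lower-rank gene is side a).  On self-comparisons, anchors adjacent to the
    main diagonal (rank difference <= 1) are excluded so tandem arrays cannot
    masquerade as blocks.
    """
    idx = {g.gene_id: g for g in genes}
    groups: dict[tuple[str, str], dict[tuple[str, str], Anchor]] = {}
    for r in rows:
        if r.is_self_hit:
            continue
        try:
            gq, gs = idx[r.query_id], idx[r.subject_id]
        except KeyError as exc:
            raise KeyError(f"similarity row references unknown gene {exc}") from exc
        if gq.chromosome == gs.chromosome:
            if abs(gq.rank - gs.rank) <= 1:
                continue
            a, b = (gq, gs) if gq.rank <= gs.rank else (gs, gq)
        elif gq.chromosome < gs.chromosome:
            a, b = gq, gs
        else:
            a, b = gs, gq
        key = (a.chromosome, b.chromosome)
        groups.setdefault(key, {})[(a.gene_id, b.gene_id)] = Anchor(
            a.gene_id, b.gene_id, a.rank, b.rank
        )
    return {k: sorted(v.values()) for k, v in sorted(groups.items())}


def find_blocks(
    genes: Sequence[GeneRecord],
    anchor_rows: Iterable[SimilarityRow],
    params: CollinearityParams = CollinearityParams(),
) -> list[CollinearBlock]:
    """Chain anchors on every chromosome pair and score block significance.

    ``anchor_rows`` should already have passed :func:`homology.filter_anchors`.
    Deterministic for a given ``params.seed``.
    """
    chrom_len: dict[str, int] = {}
    for g in genes:
        chrom_len[g.chromosome] = max(chrom_len.get(g.chromosome, 0), g.rank + 1)
    groups = anchors_by_chrom_pair(anchor_rows, genes)
    rng = np.random.default_rng(params.seed)
    blocks: list[CollinearBlock] = []
    for (ca, cb), anchors in groups.items():
        pair_blocks = chain_anchors(anchors, params, ca, cb)
        for b in pair_blocks:
            b.p_value = block_pvalue(
                b, len(anchors), chrom_len[ca], chrom_len[cb], params, rng
            )
        blocks.extend(pair_blocks)
    return blocks
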