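"""Family libraries, family membership, anchor filtering, and RBH orthology.

Thresholds follow the conventional strict inequalities: family membership
requires E-value strictly below 1e-10 *and* percent identity strictly above
60; candidate collinearity anchors keep, per query, the top five non-self
hits with E-value below 1e-5.  "Top-ranked" is always resolved by
(E-value ascending, bitscore descending, subject ID lexicographic) so output
is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import SimilarityRow

__all__ = [
    "FamilyLibrary",
    "FamilyThresholds",
    "build_library",
    "identify_family_members",
    "filter_anchors",
    "rbh_orthologs",
]


@dataclass(frozen=True)
class FamilyThresholds:
    evalue_max: float = 1e-10
    identity_min: float = 60.0  # strict greater-than

    def __post_init__(self) -> None:
        if self.evalue_max <= 0:
            raise ValueError("evalue_max must be positive")
        if not 0.0 <= self.identity_min <= 100.0:
            raise ValueError("identity_min outside [0, 100]")


@dataclass(frozen=True)
class FamilyLibrary:
    """Curated seed genes plus their top-ranked cross-species hits."""

    seed_ids: frozenset[str]
    augmented_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not self.seed_ids <= self.augmented_ids:
            raise ValueError("seed_ids must be a subset of augmented_ids")


def _hit_rank_key(r: SimilarityRow) -> tuple:
    return (r.evalue, -r.bitscore, r.subject_id)


def build_library(
    seed_ids: Iterable[str],
    cross_species_hits: Iterable[SimilarityRow],
    evalue_max: float = 1e-10,
) -> FamilyLibrary:
    """Augment each seed with its single top-ranked passing cross-species hit.

    Only the E-value bound is applied to library construction (the identity
    filter enters at the membership step).
    """
    seeds = frozenset(seed_ids)
    best: dict[str, SimilarityRow] = {}
    for r in cross_species_hits:
        if r.is_self_hit or r.evalue >= evalue_max:
            continue
        cur = best.get(r.query_id)
        if cur is None or _hit_rank_key(r) < _hit_rank_key(cur):
            best[r.query_id] = r
    added = {best[q].subject_id for q in best if q in seeds}
    return FamilyLibrary(seed_ids=seeds, augmented_ids=seeds | added)


def identify_family_members(
    library: FamilyLibrary,
    hits: Iterable[SimilarityRow],
    thresholds: FamilyThresholds = FamilyThresholds(),
) -> set[str]:
    """Genes hit by any library gene below the E-value bound and above the
    identity bound (both strict); self-hits ignored."""
    members: set[str] = set()
    for r in hits:
        if r.is_self_hit or r.query_id not in library.augmented_ids:
            continue
        if r.evalue < thresholds.evalue_max and r.pct_identity > thresholds.identity_min:
            members.add(r.subject_id)
    return members


def filter_anchors(
    hits: Iterable[SimilarityRow],
    evalue_max: float = 1e-5,
    top_k: int = 5,
) -> list[SimilarityRow]:
    """Per query, keep the <= top_k best non-self hits with evalue < evalue_max."""
    by_query: dict[str, list[SimilarityRow]] = {}
    for r in hits:
        if r.is_self_hit or r.evalue >= evalue_max:
            continue
        by_query.setdefault(r.query_id, []).append(r)
    out: list[SimilarityRow] = []
    for q in sorted(by_query):
        out.extend(sorted(by_query[q], key=_hit_rank_key)[:top_k])
    return out


def rbh_orthologs(
    hits_a_to_b: Iterable[SimilarityRow],
    hits_b_to_a: Iterable[SimilarityRow],
    co_ortholog_factor: float = 0.9,
) -> tuple[dict[str, str], dict[str, set[str]]]:
    """Reciprocal-best-hit orthologs plus a many-to-many co-ortholog map.

    (a, b) is an RBH pair iff b is a's best hit and a is b's best hit.  The
    co-ortholog map additionally links a to every subject whose bitscore is
    within ``co_ortholog_factor`` of a's best hit — a desk-scale surrogate
    for orthogroup expansion, enabling many-to-many network projection.
    """

    def _best_and_near(hits: Iterable[SimilarityRow]):
        by_q: dict[str, list[SimilarityRow]] = {}
        for r in hits:
            if not r.is_self_hit:
                by_q.setdefault(r.query_id, []).append(r)
        best = {}
        near: dict[str, set[str]] = {}
        for q, rows in by_q.items():
            rows.sort(key=_hit_rank_key)
            best[q] = rows[0].subject_id
            cutoff = rows[0].bitscore * co_ortholog_factor
            near[q] = {r.subject_id for r in rows if r.bitscore >= cutoff}
        return best, near

    best_ab, near_ab = _best_and_near(hits_a_to_b)
    best_ba, _ = _best_and_near(hits_b_to_a)
    rbh = {
        a: b for a, b in best_ab.items() if best_ba.get(b) == a
    }
    return rbh, near_ab
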