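"""Five-way duplication typing of every gene in a genome.

Each gene receives exactly one of singleton / dispersed / proximal / tandem /
wgd with precedence wgd > tandem > proximal > dispersed > singleton:

* **wgd** — the gene appears as an anchor in a significant collinear block
  (polyploidy- or segmental-duplication-derived; the two are not separated);
* **tandem** — it has a same-chromosome homolog within ``tandem_max_gap``
  intervening genes (default 0, i.e. adjacent ranks);
* **proximal** — within ``proximal_max_gap`` intervening genes (default 10);
* **dispersed** — any homolog elsewhere;
* **singleton** — no non-self homolog at all.

"Homolog" means a pair surviving the loose anchor filter (E < 1e-5, top
five), not the stricter family thresholds: typing is genome-wide.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .collinearity import CollinearBlock
from .io import GeneRecord, SimilarityRow
from .util import format_percent

__all__ = [
    "ClassifierParams",
    "DupTypeSummary",
    "classify_duplicates",
    "summarize_types",
]

TYPE_ORDER = ("singleton", "dispersed", "proximal", "tandem", "wgd")


@dataclass(frozen=True)
class ClassifierParams:
    tandem_max_gap: int = 0
    proximal_max_gap: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.tandem_max_gap < self.proximal_max_gap:
            raise ValueError("need 0 <= tandem_max_gap < proximal_max_gap")


@dataclass(frozen=True)
class DupTypeSummary:
    """Counts and round-half-up percentages per duplication type."""

    counts: Mapping[str, int]
    percents: Mapping[str, str]
    total: int


def classify_duplicates(
    genes: Sequence[GeneRecord],
    filtered_anchors: Iterable[SimilarityRow],
    significant_blocks: Iterable[CollinearBlock],
    params: ClassifierParams = ClassifierParams(),
) -> dict[str, str]:
    """Assign one duplication type per gene (partition of the universe)."""
    idx = {g.gene_id: g for g in genes}
    homologs: dict[str, set[str]] = {g.gene_id: set() for g in genes}
    for r in filtered_anchors:
        if r.is_self_hit:
            continue
        for a, b in ((r.query_id, r.subject_id), (r.subject_id, r.query_id)):
            if a not in idx:
                raise KeyError(f"anchor references gene {a!r} absent from positions")
            homologs[a].add(b)

    wgd_genes: set[str] = set()
    for b in significant_blocks:
        wgd_genes |= b.gene_set()

    out: dict[str, str] = {}
    for g in genes:
        if g.gene_id in wgd_genes:
            out[g.gene_id] = "wgd"
            continue
        partners = homologs[g.gene_id]
        if not partners:
            out[g.gene_id] = "singleton"
            continue
        best_gap: int | None = None
        for h in partners:
            hg = idx.get(h)
            if hg is None or hg.chromosome != g.chromosome:
                continue
            gap = abs(hg.rank - g.rank) - 1
            if best_gap is None or gap < best_gap:
                best_gap = gap
        if best_gap is not None and best_gap <= params.tandem_max_gap:
            out[g.gene_id] = "tandem"
        elif best_gap is not None and best_gap <= params.proximal_max_gap:
            out[g.gene_id] = "proximal"
        else:
            out[g.gene_id] = "dispersed"
    return out


def summarize_types(
    type_map: Mapping[str, str], universe: Iterable[str]
) -> DupTypeSummary:
    """Five-way counts over a gene universe with 2-decimal percentages."""
    uni = list(universe)
    if not uni:
        raise ValueError("empty gene universe")
    missing = [g for g in uni if g not in type_map]
    if missing:
        raise KeyError(f"{len(missing)} universe genes missing from type map")
    counts = {t: 0 for t in TYPE_ORDER}
    for g in uni:
        counts[type_map[g]] += 1
    percents = {t: format_percent(c, len(uni)) for t, c in counts.items()}
    return DupTypeSummary(counts=counts, percents=percents, total=len(uni))
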