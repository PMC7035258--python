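"""Readers and writers for the plain-text dialects the pipeline exchanges.

Gene positions are stored 1-based inclusive (the genomic-file convention);
in memory every gene additionally carries a 0-based order ``rank`` within its
chromosome, which is what all collinearity arithmetic uses.  Similarity hits
use the 12-column tabular BLAST dialect (``outfmt 6``).  Readers reject
malformed input with a :class:`ParseError` naming the offending line rather
than silently repairing it; every writer's output is accepted by its paired
reader.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ParseError",
    "GeneRecord",
    "SimilarityRow",
    "read_gene_positions",
    "write_gene_positions",
    "read_similarity_table",
    "write_similarity_table",
    "read_id_list",
    "write_id_list",
    "read_edge_list",
    "write_edge_list",
    "write_block_report",
    "read_block_report",
]


class ParseError(ValueError):
    """Raised when an input file violates its dialect contract."""


@dataclass(frozen=True)
class GeneRecord:
    """A gene with genomic coordinates and its order rank on its chromosome.

    ``start``/``end`` are 1-based inclusive base-pair positions; ``rank`` is
    the 0-based index of the gene when the chromosome's genes are sorted by
    ``start`` (ties broken by ``gene_id``).  ``class_tag`` marks membership in
    the focal gene class under study (e.g. cold-related genes) and is
    ``"untagged"`` for genes read from plain 5-column files.
    """

    gene_id: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1
    class_tag: str = "untagged"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass(frozen=True)
class SimilarityRow:
    """One pairwise similarity hit (tabular BLAST, ``outfmt 6``)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gapopens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative evalue {self.evalue}")

    @property
    def is_self_hit(self) -> bool:
        return self.query_id == self.subject_id


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line


def assign_ranks(genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Sort by (chromosome, start, gene_id) and assign per-chromosome ranks."""
    ordered = sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id))
    out: list[GeneRecord] = []
    counters: dict[str, int] = {}
    for g in ordered:
        r = counters.get(g.chromosome, 0)
        counters[g.chromosome] = r + 1
        out.append(replace(g, rank=r))
    return out


def read_gene_positions(path: str | Path) -> list[GeneRecord]:
    """Read a ≥5-column gene position table and compute order ranks.

    Columns: chromosome, gene_id, start, end, strand, [class_tag].
    Lines starting with ``#`` are comments.  Duplicate gene IDs are an error.
    """
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) < 5:
            raise ParseError(
                f"{path}: line {lineno}: expected >=5 tab-separated columns, "
                f"got {len(cols)}"
            )
        chrom, gene_id, start_s, end_s, strand = cols[:5]
        class_tag = cols[5] if len(cols) > 5 else "untagged"
        if gene_id in seen:
            raise ParseError(f"{path}: line {lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: non-integer coordinate") from exc
        try:
            genes.append(
                GeneRecord(gene_id, chrom, start, end, strand, class_tag=class_tag)
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return assign_ranks(genes)


def write_gene_positions(genes: Iterable[GeneRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start, g.gene_id)):
            fh.write(
                f"{g.chromosome}\t{g.gene_id}\t{g.start}\t{g.end}\t{g.strand}"
                f"\t{g.class_tag}\n"
            )


def read_similarity_table(path: str | Path) -> list[SimilarityRow]:
    """Read a 12-column tabular similarity file (scientific notation accepted)."""
    rows: list[SimilarityRow] = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 12:
            raise ParseError(
                f"{path}: line {lineno}: expected 12 columns, got {len(cols)}"
            )
        try:
            rows.append(
                SimilarityRow(
                    query_id=cols[0],
                    subject_id=cols[1],
                    pct_identity=float(cols[2]),
                    aln_len=int(cols[3]),
                    mismatches=int(cols[4]),
                    gapopens=int(cols[5]),
                    qstart=int(cols[6]),
                    qend=int(cols[7]),
                    sstart=int(cols[8]),
                    send=int(cols[9]),
                    evalue=float(cols[10]),
                    bitscore=float(cols[11]),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from exc
    return rows


def write_similarity_table(rows: Iterable[SimilarityRow], path: str | Path) -> None:
    # str() round-trips Python floats exactly, preserving read->write->read.
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for r in rows:
            fh.write(
                "\t".join(
                    [
                        r.query_id,
                        r.subject_id,
                        str(r.pct_identity),
                        str(r.aln_len),
                        str(r.mismatches),
                        str(r.gapopens),
                        str(r.qstart),
                        str(r.qend),
                        str(r.sstart),
                        str(r.send),
                        str(r.evalue),
                        str(r.bitscore),
                    ]
                )
                + "\n"
            )


def read_id_list(path: str | Path) -> list[str]:
    return [line.strip() for _, line in _data_lines(path)]


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i in ids:
            fh.write(f"{i}\n")


def read_edge_list(path: str | Path) -> list[tuple[str, str]]:
    edges = []
    for lineno, line in _data_lines(path):
        cols = line.split("\t")
        if len(cols) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        edges.append((cols[0], cols[1]))
    return edges


def write_edge_list(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")


# --- collinear block reports -------------------------------------------------

_BLOCK_HEADER = (
    "#chrom_a\tchrom_b\torientation\tn_anchors\tscore\tp_value\tevent"
)


def write_block_report(blocks, path: str | Path) -> None:
    """Write blocks as one ``>`` header line each followed by anchor lines.

    p-values are printed with three significant digits; an unassigned event
    label is written as ``.``.
    """
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(_BLOCK_HEADER + "\n")
        for b in blocks:
            p = "." if b.p_value is None else f"{b.p_value:.3g}"
            event = b.event_label if b.event_label else "."
            fh.write(
                f">{b.chrom_a}\t{b.chrom_b}\t{b.orientation}\t{len(b.anchors)}"
                f"\t{b.score}\t{p}\t{event}\n"
            )
            for a in b.anchors:
                fh.write(f"{a.gene_a}\t{a.gene_b}\t{a.rank_a}\t{a.rank_b}\n")


def read_block_report(path: str | Path):
    """Inverse of :func:`write_block_report` (p-values at printed precision)."""
    from .collinearity import Anchor, CollinearBlock  # avoid import cycle

    blocks = []
    current = None
    for lineno, line in _data_lines(path):
        if line.startswith(">"):
            cols = line[1:].split("\t")
            if len(cols) != 7:
                raise ParseError(f"{path}: line {lineno}: bad block header")
            current = CollinearBlock(
                chrom_a=cols[0],
                chrom_b=cols[1],
                orientation=cols[2],
                anchors=[],
                score=int(cols[4]),
                p_value=None if cols[5] == "." else float(cols[5]),
                event_label=None if cols[6] == "." else cols[6],
            )
            blocks.append(current)
        else:
            if current is None:
                raise ParseError(f"{path}: line {lineno}: anchor before block header")
            cols = line.split("\t")
            if len(cols) != 4:
                raise ParseError(f"{path}: line {lineno}: bad anchor line")
            current.anchors.append(
                Anchor(cols[0], cols[1], int(cols[2]), int(cols[3]))
            )
    return blocks
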