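"""Attribution of collinear blocks (and their genes) to named polyploidies.

Each significant block is labelled with the polyploidy event whose Ks window
contains the median synonymous distance of the block's anchor pairs; a median
outside every window leaves the block unassigned.  A gene participates in
every event whose labelled blocks contain it — the recounting rule: a gene
associated with an older event is counted again if it was reduplicated in a
younger one — and Venn-style region counts over exact event sets are
computed for reporting.

Windows are half-open ``[ks_min, ks_max)``, must not overlap, and are
supplied by the caller; :func:`windows_from_ages` derives midpoint-bounded
windows from known event ages but is never applied silently.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .collinearity import CollinearBlock
from .io import SimilarityRow

__all__ = [
    "EventWindow",
    "EventAssignment",
    "assign_block_events",
    "gene_event_participation",
    "windows_from_ages",
    "ks_from_similarity",
]


@dataclass(frozen=True)
class EventWindow:
    name: str
    ks_min: float
    ks_max: float  # half-open [ks_min, ks_max)

    def __post_init__(self) -> None:
        if not self.ks_min < self.ks_max:
            raise ValueError(f"window {self.name}: ks_min must be < ks_max")

    def contains(self, ks: float) -> bool:
        return self.ks_min <= ks < self.ks_max


def _validate_windows(windows: Sequence[EventWindow]) -> None:
    ordered = sorted(windows, key=lambda w: w.ks_min)
    for w1, w2 in zip(ordered, ordered[1:]):
        if w2.ks_min < w1.ks_max:
            raise ValueError(f"windows {w1.name} and {w2.name} overlap")


@dataclass
class EventAssignment:
    """Per-block event labels and the induced per-gene event sets."""

    block_labels: list[str | None]
    gene_events: dict[str, set[str]]


def _pair_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def assign_block_events(
    blocks: Sequence[CollinearBlock],
    pair_ks: Mapping[tuple[str, str], float],
    windows: Sequence[EventWindow],
) -> EventAssignment:
    """Label blocks by the window containing their median anchor Ks.

    ``pair_ks`` is keyed by sorted gene-ID pairs; a missing anchor pair is an
    error naming the pair.  Block ``event_label`` fields are filled in place
    as well.
    """
    _validate_windows(windows)
    labels: list[str | None] = []
    gene_events: dict[str, set[str]] = {}
    for b in blocks:
        ks_values = []
        for a in b.anchors:
            key = _pair_key(a.gene_a, a.gene_b)
            if key not in pair_ks:
                raise KeyError(f"no Ks value for anchor pair {key[0]}--{key[1]}")
            ks_values.append(pair_ks[key])
        med = statistics.median(ks_values)
        label = next((w.name for w in windows if w.contains(med)), None)
        b.event_label = label
        labels.append(label)
        if label is not None:
            for g in b.gene_set():
                gene_events.setdefault(g, set()).add(label)
    return EventAssignment(block_labels=labels, gene_events=gene_events)


def gene_event_participation(
    assignment: EventAssignment,
) -> tuple[dict[str, int], dict[frozenset[str], int]]:
    """Per-event gene counts (with recounting) and Venn region counts.

    A gene contributes to the count of *every* event whose labelled blocks
    contain it; the Venn dictionary partitions event-assigned genes by their
    exact event set, so region counts sum to the number of assigned genes.
    """
    event_counts: dict[str, int] = {}
    venn: dict[frozenset[str], int] = {}
    for g, evs in assignment.gene_events.items():
        for e in evs:
            event_counts[e] = event_counts.get(e, 0) + 1
        key = frozenset(evs)
        venn[key] = venn.get(key, 0) + 1
    return event_counts, venn


def windows_from_ages(
    ages: Mapping[str, float], half_width: float | None = None
) -> list[EventWindow]:
    """Ks windows centred on known event ages.

    With ``half_width`` None, boundaries fall at midpoints between adjacent
    ages (outermost windows extend to 0 and +inf); otherwise each window is
    ``[age - half_width, age + half_width)``.
    """
    items = sorted(ages.items(), key=lambda kv: kv[1])
    if not items:
        return []
    windows = []
    if half_width is not None:
        for name, a in items:
            windows.append(EventWindow(name, max(0.0, a - half_width), a + half_width))
        _validate_windows(windows)
        return windows
    for i, (name, a) in enumerate(items):
        lo = 0.0 if i == 0 else (items[i - 1][1] + a) / 2
        hi = math.inf if i == len(items) - 1 else (a + items[i + 1][1]) / 2
        windows.append(EventWindow(name, lo, hi))
    return windows


def ks_from_similarity(
    rows: Iterable[SimilarityRow], identity_decay: float = 0.12
) -> dict[tuple[str, str], float]:
    """Approximate pairwise Ks by inverting the identity-decay model
    ``identity = 100*exp(-k*Ks)`` (per-pair, non-self hits only)."""
    out: dict[tuple[str, str], float] = {}
    for r in rows:
        if r.is_self_hit or r.pct_identity <= 0:
            continue
        key = _pair_key(r.query_id, r.subject_id)
        out[key] = -math.log(min(r.pct_identity, 100.0) / 100.0) / identity_decay
    return out
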