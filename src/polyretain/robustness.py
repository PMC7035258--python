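"""Network robustness under random node removal.

The robustness statistic is R = C / (N - Nr): N is the node count of the
network, Nr the number of removed nodes, and C the size of the largest
connected component of the induced subgraph after removal.  Removal is
uniform without replacement (no degree-targeted attack); the Monte-Carlo
estimate averages R over ``reps`` independent draws from a single seeded
stream, so profiles are reproducible.  Percentage schemes resolve to
``Nr = round-half-up(f * N)`` clamped into [1, N-1]; a scheme that would
remove every node is reported not-applicable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RobustnessParams",
    "robustness_after_removal",
    "robustness_R",
    "robustness_profile",
    "resolve_removal_count",
]


@dataclass(frozen=True)
class RobustnessParams:
    removal_counts: tuple[int, ...] = (5, 10)
    removal_fractions: tuple[float, ...] = (0.05, 0.10, 0.20, 0.50)
    reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c < 1 for c in self.removal_counts):
            raise ValueError("removal counts must be >= 1")
        if any(not 0 < f < 1 for f in self.removal_fractions):
            raise ValueError("removal fractions must lie in (0, 1)")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


def _largest_component(g: nx.Graph) -> int:
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(g))


def robustness_after_removal(g: nx.Graph, removed: Iterable[str]) -> float:
    """R for one explicit removal set (isolated survivors count as size-1
    components)."""
    removed = set(removed)
    n = g.number_of_nodes()
    unknown = removed - set(g.nodes)
    if unknown:
        raise ValueError(f"removed nodes not in network: {sorted(unknown)[:3]}")
    if len(removed) >= n:
        raise ValueError("cannot remove every node")
    sub = g.subgraph(set(g.nodes) - removed)
    return _largest_component(sub) / (n - len(removed))


def resolve_removal_count(n: int, nr_or_fraction: int | float) -> int:
    """Absolute counts pass through; fractions round half-up, clamped to
    [1, N-1]."""
    if isinstance(nr_or_fraction, int):
        return nr_or_fraction
    nr = int(math.floor(nr_or_fraction * n + 0.5))
    return min(max(nr, 1), n - 1)


def robustness_R(
    g: nx.Graph,
    nr_or_fraction: int | float,
    reps: int = 100,
    seed: int = 0,
) -> float:
    """Mean R over ``reps`` uniform random removals of Nr distinct nodes."""
    n = g.number_of_nodes()
    if n <= 1:
        raise ValueError("network must have more than one node")
    nr = resolve_removal_count(n, nr_or_fraction)
    if not 1 <= nr < n:
        raise ValueError(f"resolved removal count {nr} outside [1, {n - 1}]")
    rng = np.random.default_rng(seed)
    nodes = sorted(g.nodes)
    total = 0.0
    for _ in range(reps):
        removed = rng.choice(len(nodes), size=nr, replace=False)
        total += robustness_after_removal(g, {nodes[i] for i in removed})
    return total / reps


def robustness_profile(
    networks: dict[str, nx.Graph],
    params: RobustnessParams = RobustnessParams(),
) -> pd.DataFrame:
    """Mean R per removal scheme for each named network.

    Columns follow the conventional schedule order (absolute counts, then
    percentages); infeasible schemes yield NaN.  Values are rounded to three
    decimals.
    """
    schemes: list[tuple[str, int | float]] = [
        (str(c), c) for c in params.removal_counts
    ] + [(f"{int(round(f * 100))}%", f) for f in params.removal_fractions]
    rows = []
    for name in networks:
        g = networks[name]
        n = g.number_of_nodes()
        row: dict[str, object] = {"network": name, "N": n}
        for label, scheme in schemes:
            nr = resolve_removal_count(n, scheme) if n > 1 else n
            if not 1 <= nr < n:
                row[label] = float("nan")
            else:
                row[label] = round(
                    robustness_R(g, scheme, reps=params.reps, seed=params.seed), 3
                )
        rows.append(row)
    return pd.DataFrame(rows, columns=["network", "N"] + [s[0] for s in schemes])
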