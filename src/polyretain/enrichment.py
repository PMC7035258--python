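"""Chi-squared enrichment of a focal gene class with I/U/D status calls.

Each test is a Pearson chi-squared on a 2x2 contingency table at 1 df:
focal vs background rows, in-category vs not-in-category columns (the
category being collinearity status, or membership in one duplication type).
Status is **I** (significant increase) when p < alpha and the focal in-
category proportion exceeds the background's, **D** for a significant
decrease, **U** otherwise.

``background_mode="all_genes"`` compares the focal row against the whole-
genome row exactly as published collinearity tables print both rows; since
the focal class is a subset of all genes the two rows overlap and the
statistic is conservative.  ``"non_focal"`` uses the disjoint complement and
is the properly calibrated variant.  No continuity correction and no
multiple-testing adjustment are applied by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from scipy import stats

from .classify import TYPE_ORDER

__all__ = [
    "EnrichmentParams",
    "ContingencyResult",
    "chisq_2x2",
    "enrichment_row",
    "type_enrichment_table",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentParams:
    alpha: float = 0.05
    background_mode: str = "all_genes"  # or "non_focal"
    yates: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha outside (0, 1)")
        if self.background_mode not in ("all_genes", "non_focal"):
            raise ValueError(f"unknown background_mode {self.background_mode!r}")


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 counts (a,b: focal in/out; c,d: background in/out), the Pearson
    statistic, its upper-tail p at 1 df, and the I/U/D status call."""

    a: int
    b: int
    c: int
    d: int
    chi2: float
    p: float
    status: str

    @property
    def focal_proportion(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def background_proportion(self) -> float:
        return self.c / (self.c + self.d)


def chisq_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared for a 2x2 table, 1 df, upper-tail p.

    A zero row or column marginal leaves the test undefined and raises.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero marginal: chi-squared test undefined")
    chi2 = 0.0
    for obs, er, ec in ((a, r1, c1), (b, r1, c2), (c, r2, c1), (d, r2, c2)):
        exp = er * ec / n
        dev = abs(obs - exp)
        if yates:
            dev = max(0.0, dev - 0.5)
        chi2 += dev * dev / exp
    return chi2, float(stats.chi2.sf(chi2, df=1))


def enrichment_row(
    focal_set: set[str],
    colinear_set: set[str],
    universe: Iterable[str],
    params: EnrichmentParams = EnrichmentParams(),
) -> ContingencyResult:
    """Collinearity enrichment of the focal class over a gene universe."""
    uni = set(universe)
    focal = focal_set & uni
    if not focal:
        raise ValueError("empty focal set")
    background = uni if params.background_mode == "all_genes" else uni - focal
    col = colinear_set & uni
    a = len(focal & col)
    b = len(focal - col)
    c = len(background & col)
    d = len(background - col)
    chi2, p = chisq_2x2(a, b, c, d, yates=params.yates)
    return _call_status(a, b, c, d, chi2, p, params.alpha)


def _call_status(a, b, c, d, chi2, p, alpha) -> ContingencyResult:
    fp = a / (a + b)
    bp = c / (c + d)
    if p < alpha and fp > bp:
        status = "I"
    elif p < alpha and fp < bp:
        status = "D"
    else:
        status = "U"
    return ContingencyResult(a, b, c, d, chi2, p, status)


def type_enrichment_table(
    dup_map: Mapping[str, str],
    focal_set: set[str],
    universe: Iterable[str],
    params: EnrichmentParams = EnrichmentParams(),
) -> dict[str, ContingencyResult]:
    """One 2x2 per duplication type (in-type vs not-in-type columns).

    Degenerate tables (a zero marginal, e.g. every gene in one type) are
    reported with status U, chi2 0, p 1 and a logged warning rather than
    aborting the whole table.
    """
    uni = list(universe)
    focal = focal_set & set(uni)
    if not focal:
        raise ValueError("empty focal set")
    background = (
        set(uni) if params.background_mode == "all_genes" else set(uni) - focal
    )
    out: dict[str, ContingencyResult] = {}
    for t in TYPE_ORDER:
        in_type = {g for g in uni if dup_map[g] == t}
        a = len(focal & in_type)
        b = len(focal) - a
        c = len(background & in_type)
        d = len(background) - c
        try:
            chi2, p = chisq_2x2(a, b, c, d, yates=params.yates)
        except ValueError:
            logger.warning("type %s: degenerate 2x2 table, reporting status U", t)
            out[t] = ContingencyResult(a, b, c, d, 0.0, 1.0, "U")
            continue
        out[t] = _call_status(a, b, c, d, chi2, p, params.alpha)
    return out
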