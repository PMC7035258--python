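"""Nei–Gojobori (NG86) Ka/Ks on paired codon alignments.

Synonymous and nonsynonymous *sites* are counted per codon as the fraction
of the nine possible single-nucleotide changes that preserve the encoded
amino acid (changes creating a stop codon count as nonsynonymous); pair-level
site totals are the average over the two sequences.  *Differences* between a
codon pair with two or three substitutions are averaged over all minimal
mutational pathways with equal weights; pathways passing through a stop
codon are excluded and the rest reweighted (if every pathway is blocked, all
are kept with stop-creating steps counted as nonsynonymous).  The raw
proportions pS = Sd/S and pN = Nd/N are corrected for multiple hits with the
Jukes–Cantor formula d = -(3/4) ln(1 - 4p/3), and omega = Ka/Ks flags
positive selection when it exceeds 1.  Only the standard genetic code is
supported (all study taxa are plants using it).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "SaturationError",
    "ng86_codon_sites",
    "ng86_sites",
    "ng86_differences",
    "jukes_cantor",
    "kaks_pair",
    "kaks_batch",
    "simulate_codon_pair",
]

_NT = "ACGT"
_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = frozenset(_STANDARD.stop_codons)


def _aa(codon: str) -> str | None:
    """Amino acid for a codon, None for a stop."""
    if codon in _STOPS:
        return None
    return _STANDARD.forward_table[codon]


class SaturationError(ValueError):
    """Raised when a difference proportion reaches the Jukes–Cantor pole."""


@dataclass(frozen=True)
class CodonAlignment:
    """Two aligned coding sequences over {A,C,G,T,-}, length a multiple of 3.

    Codon columns containing a gap in either sequence are dropped pairwise
    before any computation.
    """

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)
        if len(a) != len(b):
            raise ValueError("aligned sequences differ in length")
        if len(a) % 3 != 0:
            raise ValueError("alignment length is not a multiple of 3")
        bad = set(a + b) - set("ACGT-")
        if bad:
            raise ValueError(f"unexpected characters {sorted(bad)}")

    def codon_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(0, len(self.seq_a), 3):
            ca, cb = self.seq_a[i : i + 3], self.seq_b[i : i + 3]
            if "-" in ca or "-" in cb:
                continue
            for idx, c in ((i // 3, ca), (i // 3, cb)):
                if c in _STOPS:
                    raise ValueError(f"stop codon {c} at codon index {idx}")
            out.append((ca, cb))
        if not out:
            raise ValueError("no ungapped codon columns to compare")
        return out


@dataclass(frozen=True)
class KaKsResult:
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ks: float
    ka: float
    omega: float | None  # None when Ks = 0 (undefined, not infinity)
    positive_selection: bool


def ng86_codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one codon; they sum to 3."""
    codon = codon.upper()
    if codon in _STOPS:
        raise ValueError(f"stop codon {codon}")
    aa = _aa(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if _aa(alt) == aa:  # stop -> None, never equal: nonsynonymous
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def ng86_sites(seq: str) -> tuple[float, float]:
    """Total (S, N) site counts over an ungapped codon sequence."""
    seq = seq.upper().replace("-", "")
    if len(seq) % 3 != 0:
        raise ValueError("sequence length is not a multiple of 3")
    s_tot = n_tot = 0.0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in _STOPS:
            raise ValueError(f"stop codon at codon index {i // 3}")
        s, n = ng86_codon_sites(codon)
        s_tot += s
        n_tot += n
    return s_tot, n_tot


def _classify_step(c1: str, c2: str) -> tuple[float, float]:
    """(sd, nd) of a single-nucleotide step; a step onto a stop is
    nonsynonymous (used only in the all-pathways-blocked fallback)."""
    a1, a2 = _aa(c1), _aa(c2)
    if a1 is not None and a1 == a2:
        return 1.0, 0.0
    return 0.0, 1.0


def ng86_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences of a codon
    pair; sd + nd equals the number of differing positions."""
    ca, cb = codon_a.upper(), codon_b.upper()
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    if len(diff) == 1:
        return _classify_step(ca, cb)
    pathways = []
    for order in itertools.permutations(diff):
        cur = ca
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in _STOPS and nxt != cb:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        pathways.append((blocked, steps))
    usable = [steps for blocked, steps in pathways if not blocked]
    if not usable:
        usable = [steps for _, steps in pathways]
    sd = nd = 0.0
    for steps in usable:
        for c1, c2 in steps:
            s, n = _classify_step(c1, c2)
            sd += s
            nd += n
    return sd / len(usable), nd / len(usable)


def jukes_cantor(p: float) -> float:
    """Multiple-hit correction d = -(3/4) ln(1 - 4p/3); domain 0 <= p < 0.75."""
    if p < 0:
        raise ValueError("negative difference proportion")
    if p >= 0.75:
        raise SaturationError(f"difference proportion {p} is saturated (>= 0.75)")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def kaks_pair(alignment: CodonAlignment) -> KaKsResult:
    """Full NG86 estimate for one aligned pair.

    Ks = 0 makes omega undefined (None); positive selection is flagged only
    when both distances are defined and Ka/Ks > 1.
    """
    pairs = alignment.codon_pairs()
    sa = na = sb = nb = 0.0
    sd = nd = 0.0
    for ca, cb in pairs:
        s1, n1 = ng86_codon_sites(ca)
        s2, n2 = ng86_codon_sites(cb)
        sa += s1
        na += n1
        sb += s2
        nb += n2
        ds, dn = ng86_differences(ca, cb)
        sd += ds
        nd += dn
    s_sites = (sa + sb) / 2.0
    n_sites = (na + nb) / 2.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    omega = None if ks == 0.0 else ka / ks
    return KaKsResult(
        s_sites=s_sites,
        n_sites=n_sites,
        sd=sd,
        nd=nd,
        ps=ps,
        pn=pn,
        ks=ks,
        ka=ka,
        omega=omega,
        positive_selection=omega is not None and omega > 1.0,
    )


def kaks_batch(
    pairs: Iterable[tuple[str, str]], sequences: dict[str, str]
) -> list[tuple[str, str, KaKsResult]]:
    """Ka/Ks for a list of gene-ID pairs given a dict of aligned CDS."""
    out = []
    for a, b in pairs:
        res = kaks_pair(CodonAlignment(sequences[a], sequences[b]))
        out.append((a, b, res))
    return out


_SAFE_CODONS = [
    c
    for c in ("".join(t) for t in itertools.product(_NT, repeat=3))
    if c not in _STOPS
]


def simulate_codon_pair(
    n_codons: int,
    distance: float,
    rng: np.random.Generator,
    omega: float = 1.0,
) -> CodonAlignment:
    """Test fixture: a random stop-free coding sequence and a diverged copy.

    Sites mutate at the per-site substitution probability implied by a
    Jukes–Cantor distance; a change that alters the amino acid is accepted
    with probability ``omega`` (1 = neutral, < 1 = purifying selection,
    > 1 is not modelled).  Codons that would become stops are left intact.
    """
    if distance < 0:
        raise ValueError("negative distance")
    if not 0.0 <= omega <= 1.0:
        raise ValueError("omega outside [0, 1]")
    q = 0.75 * (1.0 - math.exp(-4.0 * distance / 3.0))
    seq_a = "".join(_SAFE_CODONS[i] for i in rng.integers(len(_SAFE_CODONS), size=n_codons))
    codons_b = []
    for i in range(n_codons):
        codon = seq_a[3 * i : 3 * i + 3]
        current = codon
        for pos in range(3):
            if rng.random() >= q:
                continue
            nt = rng.choice([n for n in _NT if n != current[pos]])
            mutated = current[:pos] + nt + current[pos + 1 :]
            if mutated in _STOPS:
                continue
            if _aa(mutated) != _aa(current) and rng.random() >= omega:
                continue
            current = mutated
        codons_b.append(current)
    return CodonAlignment(seq_a, "".join(codons_b))
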